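"""End-to-end orchestration: quantify -> rank -> enrichment -> map.

Runs the whole workflow from a single configuration: normalize the count
matrix (length correction, lowess), rank each requested stage with the
signed KS score, test the size-filtered gene-set collection with the
permutation-calibrated enrichment statistic, and build the one- or
two-stage Enrichment Map. A manifest records parameters, the master seed,
package versions and input checksums so any run can be reproduced; all
numeric outputs are deterministic given the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from . import emap, genesets, gsea, io, rank
from .quantify import (
    CountMatrix,
    DigestionParams,
    InputError,
    length_normalize,
    lowess_normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    counts: str
    design: str
    gmt: str
    fasta: str | None = None
    expected_peptides: str | None = None  # two-column TSV fallback for FASTA
    obo: str | None = None
    annotations: str | None = None
    orthology: str | None = None
    stages: list[str] = field(default_factory=list)  # empty = all, max 2
    min_peptide_length: int = 6
    max_peptide_length: int = 35
    missed_cleavages: int = 0
    lowess_span: float = 0.4
    alpha: float = 0.05
    min_set_size_excl: int = 15
    max_set_size_incl: int = 500
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    p_threshold: float = 0.01
    fdr_threshold: float = 0.1
    overlap_threshold: float = 0.5
    seed: int = 42
    out_dir: str = "protmap_out"

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _assemble_collection(config: RunConfig, universe: set[str]):
    collection = genesets.parse_gmt(config.gmt)
    if config.obo and config.annotations:
        ontology = genesets.read_obo(config.obo)
        annotations = genesets.read_two_column_table(config.annotations)
        closed = genesets.up_propagate(annotations, ontology)
        go_sets = genesets.sets_from_annotations(closed, ontology, source="ontology")
        collection = genesets.GeneSetCollection(
            sets=list(collection) + list(go_sets)
        )
    if config.orthology:
        omap = genesets.read_two_column_table(config.orthology)
        collection = genesets.map_orthologs(collection, omap)
    collection.universe = universe
    filtered = genesets.filter_by_size(
        collection, config.min_set_size_excl, config.max_set_size_incl, universe
    )
    logger.info("gene sets: %d assembled, %d after size filter",
                len(collection), len(filtered))
    return filtered


def run_all(config: RunConfig) -> dict:
    """Execute the full workflow; returns a summary dict (also written as
    the run manifest)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage_fail(stage_name: str, exc: Exception):
        raise InputError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    counts = io.read_counts(config.counts, config.design)
    logger.info("quantified proteins: %d, samples: %d",
                len(counts.protein_ids), len(counts.sample_ids))

    digestion = DigestionParams(
        config.min_peptide_length, config.max_peptide_length,
        config.missed_cleavages,
    )
    try:
        expected = None
        seqs = None
        if config.expected_peptides:
            table = genesets.read_two_column_table(config.expected_peptides)
            expected = {k: int(next(iter(v))) for k, v in table.items()}
        if config.fasta:
            seqs = io.read_fasta(config.fasta)
        normalized = length_normalize(counts, seqs, digestion, expected)
        normalized = lowess_normalize(normalized, span=config.lowess_span)
    except InputError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        stage_fail("quantify", exc)
    io.write_counts(normalized, out / "normalized_counts.tsv")

    stages = config.stages or counts.stages
    if not 1 <= len(stages) <= 2:
        raise InputError(f"analyze 1 or 2 stages, got {stages}")

    universe = set(counts.protein_ids)
    collection = _assemble_collection(config, universe)
    genesets.write_gmt(collection, out / "genesets_filtered.gmt")

    params = gsea.EnrichmentParams(
        weight_exponent=config.weight_exponent,
        n_permutations=config.n_permutations,
        rng_seed=config.seed,
        p_threshold=config.p_threshold,
        fdr_threshold=config.fdr_threshold,
    )

    results_by_stage = []
    summaries = {}
    for stage in stages:
        ranked = rank.rank_proteins(normalized, stage)
        io.write_rnk(ranked, out / f"ranked_{stage}.rnk")
        scores = [
            rank.DifferentialScore(pid, row.ks_D, row.p_value, int(row.sign),
                                   row.score)
            for pid, row in ranked.table.iterrows()
        ]
        n_total, n_up, n_down = rank.summarize_significant(scores, config.alpha)
        summaries[stage] = {"n_total": n_total, "n_up": n_up, "n_down": n_down}
        logger.info(
            "%s: %d proteins significant at p<%g (%d up, %d down)",
            stage, n_total, config.alpha, n_up, n_down,
        )
        results = gsea.score_collection(ranked, collection, params)
        io.write_results(results, out / f"enrichment_{stage}.tsv")
        results_by_stage.append(results)

    graph = emap.build_map(
        results_by_stage, collection,
        p_threshold=config.p_threshold,
        fdr_threshold=config.fdr_threshold,
        overlap_threshold=config.overlap_threshold,
    )
    logger.info("enrichment map: %d nodes, %d edges",
                graph.graph.number_of_nodes(), graph.graph.number_of_edges())
    positions = (
        emap.layout(graph, seed=config.seed)
        if graph.graph.number_of_nodes() else None
    )
    emap.export_graph(graph, str(out / "emap"), "tables", positions)
    if graph.graph.number_of_nodes():
        emap.export_graph(graph, str(out / "emap"), "graphml", positions)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "stages": list(stages),
        "significance_summaries": summaries,
        "n_gene_sets_tested": len(collection),
        "emap_nodes": graph.graph.number_of_nodes(),
        "emap_edges": graph.graph.number_of_edges(),
        "input_checksums": {
            key: _sha256(p)
            for key, p in (
                ("counts", config.counts), ("design", config.design),
                ("gmt", config.gmt), ("fasta", config.fasta),
                ("obo", config.obo), ("annotations", config.annotations),
                ("orthology", config.orthology),
            )
            if p
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
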