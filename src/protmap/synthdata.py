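"""Synthetic spectral-count experiments with planted differential gene sets.

The generator emulates the salient features of shotgun-MS spectral counting:
counts are Poisson draws around protein-specific expected rates (the
undersampling regime, with many zeros for low-abundance proteins); the rate
scales with the protein's number of observable tryptic peptides, which
creates the length bias the quantify module corrects; per-sample depth
factors create the residual cross-sample differences lowess removes.
Coordinately regulated gene sets are planted by multiplying the disease-
sample rates of their members by a fold change, optionally in only one of
the disease stages, which exercises the dual-phenotype Enrichment Map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genesets import GeneSet, GeneSetCollection
from .gsea import EnrichmentResult
from .quantify import CountMatrix, DigestionParams, InputError, expected_peptide_count

#: Approximate vertebrate amino-acid frequencies (sums to 1); K and R at
#: their natural ~5.7%/5.5% so tryptic-site density is realistic.
AA_FREQS = {
    "A": 0.070, "R": 0.055, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.044, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.044,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.011, "Y": 0.027, "V": 0.066,
}


@dataclass(frozen=True)
class PlantedSet:
    size: int = 50
    fold_change: float = 2.0
    direction: str = "up"  # "up" or "down" in disease
    stages: tuple[int, ...] = (1,)  # 1-based stage indices affected


def _canonical_planted() -> list[PlantedSet]:
    return [
        PlantedSet(50, 2.0, "up", (1,)),
        PlantedSet(50, 2.0, "down", (1,)),
        PlantedSet(50, 2.0, "up", (2,)),
        PlantedSet(50, 2.0, "down", (2,)),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults are the canonical experiment: 2000 proteins, 4 replicates per
    condition, 2 stages, one up- and one down-regulated 50-member 2-fold
    set planted per stage, 48 null sets.
    """

    n_proteins: int = 2000
    n_replicates_per_condition: int = 4
    n_stages: int = 2
    baseline_log_median: float = np.log(0.4)  # per-peptide count rate
    baseline_log_sigma: float = 1.0
    length_log_median: float = np.log(350.0)  # amino acids
    length_log_sigma: float = 0.5
    sample_depth_sigma: float = 0.15  # log-normal per-sample loading factor
    overdispersion: float = 0.0  # Gamma-mixing variance; 0 = pure Poisson
    planted_sets: list[PlantedSet] = field(default_factory=_canonical_planted)
    n_null_sets: int = 48
    null_set_size_range: tuple[int, int] = (20, 100)
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_replicates_per_condition < 2:
            raise InputError("need >=1 protein and >=2 replicates per condition")
        if self.n_stages < 1:
            raise InputError("need >=1 stage")
        for ps in self.planted_sets:
            if ps.fold_change <= 0:
                raise InputError("planted fold_change must be > 0")
            if not 15 < ps.size <= 500:
                raise InputError(
                    f"planted set size {ps.size} outside the (15, 500] window"
                )
            if ps.direction not in ("up", "down"):
                raise InputError(f"unknown direction {ps.direction!r}")
            if any(not 1 <= s <= self.n_stages for s in ps.stages):
                raise InputError(f"planted stages {ps.stages} out of range")
        if sum(ps.size for ps in self.planted_sets) > self.n_proteins:
            raise InputError("planted sets exceed the protein universe")
        lo, hi = self.null_set_size_range
        if not (15 < lo <= hi <= min(500, self.n_proteins)):
            raise InputError(
                f"null set sizes {self.null_set_size_range} must lie in "
                "(15, min(500, n_proteins)]"
            )

    @property
    def stage_labels(self) -> list[str]:
        return [f"stage{i}" for i in range(1, self.n_stages + 1)]


@dataclass
class GroundTruth:
    """What was planted: per-set membership/direction/stages and the
    per-protein true fold change per stage (proteins x stages)."""

    planted: list[tuple[str, frozenset[str], str, tuple[str, ...]]]
    true_fold: pd.DataFrame

    def planted_for_stage(self, stage: str) -> list[tuple[str, str]]:
        """(set name, direction) of sets planted to affect this stage."""
        return [(n, d) for n, _, d, stages in self.planted if stage in stages]

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"set_name": n, "direction": d, "stages": ",".join(st),
             "members": ",".join(sorted(m))}
            for n, m, d, st in self.planted
        ]
        return pd.DataFrame(rows, columns=["set_name", "direction", "stages", "members"])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list(AA_FREQS))
    probs = np.array(list(AA_FREQS.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(aas, size=length, p=probs))


def generate_experiment(
    config: SimulationConfig | None = None,
) -> tuple[CountMatrix, dict[str, str], GeneSetCollection, GroundTruth]:
    """Draw one full synthetic experiment, deterministic under the seed.

    Returns (counts, sequences, gene-set collection, ground truth). Counts
    are Poisson with mean = baseline rate x expected-peptide count x sample
    depth x fold change (fold applied to disease samples of affected stages
    only).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_proteins
    width = len(str(n))
    protein_ids = [f"P{i:0{width}d}" for i in range(1, n + 1)]

    lengths = np.maximum(
        rng.lognormal(config.length_log_median, config.length_log_sigma, n), 30
    ).astype(int)
    seqs = {pid: _random_sequence(rng, L) for pid, L in zip(protein_ids, lengths)}
    expected = np.array(
        [max(expected_peptide_count(seqs[p], DigestionParams()), 1)
         for p in protein_ids],
        dtype=float,
    )
    baseline = rng.lognormal(config.baseline_log_median, config.baseline_log_sigma, n)
    rates = baseline * expected

    # disjoint planted memberships drawn from a single shuffle
    perm = rng.permutation(n)
    planted_records = []
    fold = pd.DataFrame(1.0, index=protein_ids, columns=config.stage_labels)
    cursor = 0
    gene_sets: list[GeneSet] = []
    for ps in config.planted_sets:
        members = frozenset(protein_ids[i] for i in perm[cursor:cursor + ps.size])
        cursor += ps.size
        stages = tuple(config.stage_labels[s - 1] for s in ps.stages)
        name = f"planted_{ps.direction}_{'_'.join(stages)}"
        if any(name == r[0] for r in planted_records):
            suffix = sum(1 for r in planted_records if r[0].startswith(name))
            name = f"{name}_{suffix + 1}"
        factor = ps.fold_change if ps.direction == "up" else 1.0 / ps.fold_change
        for stage in stages:
            fold.loc[list(members), stage] = factor
        planted_records.append((name, members, ps.direction, stages))
        gene_sets.append(GeneSet(name=name, description=f"planted {ps.direction}",
                                 members=members, source="synthetic"))

    size_lo, size_hi = config.null_set_size_range
    for j in range(1, config.n_null_sets + 1):
        size = int(rng.integers(size_lo, size_hi + 1))
        members = frozenset(
            protein_ids[i] for i in rng.choice(n, size=size, replace=False)
        )
        gene_sets.append(GeneSet(name=f"null_set_{j:03d}", description="null",
                                 members=members, source="synthetic"))

    sample_ids, conditions, stages_col = [], [], []
    cols = {}
    for stage in config.stage_labels:
        for cond in ("disease", "control"):
            for rep in range(1, config.n_replicates_per_condition + 1):
                sid = f"{stage}_{cond}_{rep}"
                depth = rng.lognormal(0.0, config.sample_depth_sigma)
                mean = rates * depth
                if cond == "disease":
                    mean = mean * fold[stage].to_numpy()
                if config.overdispersion > 0:
                    shape = 1.0 / config.overdispersion
                    mean = mean * rng.gamma(shape, 1.0 / shape, n)
                cols[sid] = rng.poisson(mean)
                sample_ids.append(sid)
                conditions.append(cond)
                stages_col.append(stage)

    values = pd.DataFrame(cols, index=pd.Index(protein_ids, name="protein_id"))
    design = pd.DataFrame(
        {"condition": conditions, "stage": stages_col},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    counts = CountMatrix(values=values, design=design)
    collection = GeneSetCollection(sets=gene_sets, universe=set(protein_ids))
    truth = GroundTruth(planted=planted_records, true_fold=fold)
    return counts, seqs, collection, truth


def generate_ontology_fixture(
    depth: int, branching: int, seed: int = 0, diamond_links: int = 0
) -> tuple[nx.DiGraph, dict[str, set[str]], dict[str, set[str]]]:
    """Rooted ontology tree of ``depth`` levels with leaf annotations.

    depth 1 is a lone root. With ``diamond_links`` > 0, that many extra
    child->parent edges are added between existing levels to create
    diamonds. Returns (ontology, gene->leaf-term annotations, ground-truth
    transitive closure of those annotations).
    """
    if depth < 1 or branching < 1:
        raise InputError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    dag = nx.DiGraph()
    dag.add_node("T0", name="root")
    levels = [["T0"]]
    counter = 1
    for _ in range(depth - 1):
        level = []
        for parent in levels[-1]:
            for _ in range(branching):
                term = f"T{counter}"
                counter += 1
                dag.add_node(term, name=f"term {term}")
                dag.add_edge(term, parent)
                level.append(term)
        levels.append(level)
    for _ in range(diamond_links):
        if depth < 3:
            break
        li = int(rng.integers(2, depth))
        child = levels[li][int(rng.integers(len(levels[li])))]
        target_level = levels[li - 1]
        parent = target_level[int(rng.integers(len(target_level)))]
        if not nx.has_path(dag, child, parent):
            dag.add_edge(child, parent)

    leaves = levels[-1]
    annotations = {f"G{i}": {leaf} for i, leaf in enumerate(leaves, start=1)}
    closure = {}
    for gene, terms in annotations.items():
        closed = set(terms)
        for t in terms:
            closed |= nx.descendants(dag, t)
        closure[gene] = closed
    return dag, annotations, closure


def recovery_report(
    truth: GroundTruth,
    results: list[EnrichmentResult],
    stage: str,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.1,
) -> tuple[float, float]:
    """Planted-set recovery of one stage's enrichment results.

    sensitivity = planted sets (for this stage) that pass both thresholds
    with the planted direction / planted sets for this stage.
    observed_fdr = passing sets not planted for this stage / all passing
    sets (0.0 when nothing passes).
    """
    planted = dict(truth.planted_for_stage(stage))
    missing = set(planted) - {r.set_name for r in results}
    if missing:
        raise InputError(f"results do not cover planted sets: {sorted(missing)}")
    passing = [r for r in results if r.is_significant(p_threshold, fdr_threshold)]
    n_true = sum(
        1 for r in passing
        if r.set_name in planted and r.direction == planted[r.set_name]
    )
    n_null_passing = sum(1 for r in passing if r.set_name not in planted)
    sensitivity = n_true / len(planted) if planted else 0.0
    observed_fdr = n_null_passing / len(passing) if passing else 0.0
    return sensitivity, observed_fdr
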