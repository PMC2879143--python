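"""Enrichment Map: a similarity network over significant gene sets.

Pooling gene sets from many databases produces redundant, overlapping sets
that are hard to read as a flat table. The Enrichment Map draws each
statistically significant set as a node and links pairs whose membership
overlap coefficient |A∩B| / min(|A|,|B|) exceeds a threshold (default,
strictly > 0.5), so redundant sets cluster together under a force-directed
layout. Two analyses (e.g. an early and a mid disease stage) can share one
map: each node carries two statistic blocks, rendered as the node's inner
circle (phenotype 1) and border ring (phenotype 2); a phenotype in which the
set is not significant stays neutral (white).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genesets import GeneSetCollection
from .gsea import EnrichmentResult
from .quantify import InputError

EXPORT_FORMATS = ("graphml", "gml", "tables")

_STAT_KEYS = ("p", "fdr", "nes")


@dataclass(frozen=True)
class PhenotypeStats:
    p: float
    fdr: float
    nes: float


@dataclass(frozen=True)
class EMNode:
    set_name: str
    set_size: int
    phenotype1: PhenotypeStats | None
    phenotype2: PhenotypeStats | None
    significant1: bool
    significant2: bool


@dataclass(frozen=True)
class EMEdge:
    set_a: str
    set_b: str
    overlap: float
    n_shared: int


@dataclass
class EnrichmentMapGraph:
    graph: nx.Graph
    params: dict = field(default_factory=dict)

    @property
    def n_phenotypes(self) -> int:
        return int(self.params.get("n_phenotypes", 1))

    def nodes(self) -> list[EMNode]:
        out = []
        for name in sorted(self.graph.nodes):
            d = self.graph.nodes[name]
            out.append(
                EMNode(
                    set_name=name,
                    set_size=d["set_size"],
                    phenotype1=_stats_from_attrs(d, 1),
                    phenotype2=_stats_from_attrs(d, 2),
                    significant1=d["significant1"],
                    significant2=d["significant2"],
                )
            )
        return out

    def edges(self) -> list[EMEdge]:
        out = []
        for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges):
            d = self.graph.edges[a, b]
            out.append(EMEdge(a, b, d["overlap"], d["n_shared"]))
        return out


def _stats_from_attrs(d: dict, phen: int) -> PhenotypeStats | None:
    if f"p{phen}" not in d:
        return None
    return PhenotypeStats(d[f"p{phen}"], d[f"fdr{phen}"], d[f"nes{phen}"])


def overlap_coefficient(a, b) -> float:
    """|a∩b| / min(|a|, |b|); symmetric, 1.0 whenever one set contains the other."""
    a, b = set(a), set(b)
    if not a or not b:
        raise InputError("overlap coefficient undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def build_map(
    results_by_phenotype: list[list[EnrichmentResult]] | list[EnrichmentResult],
    collection: GeneSetCollection,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.1,
    overlap_threshold: float = 0.5,
    restrict_to_universe: bool = True,
) -> EnrichmentMapGraph:
    """Build the gene-set similarity network over significant sets.

    A set becomes a node if it passes p < p_threshold and FDR < fdr_threshold
    in at least one phenotype (so a stage-specific set appears with one
    neutral ring). Edges join node pairs whose overlap coefficient is
    strictly above ``overlap_threshold``, computed by default on memberships
    restricted to the collection's universe so the displayed similarity
    matches what the enrichment test saw.
    """
    if results_by_phenotype and isinstance(results_by_phenotype[0], EnrichmentResult):
        results_by_phenotype = [results_by_phenotype]  # type: ignore[list-item]
    if not 1 <= len(results_by_phenotype) <= 2:
        raise InputError(
            "the inner/outer encoding supports 1 or 2 phenotypes, got "
            f"{len(results_by_phenotype)}"
        )
    for thr, nm in ((p_threshold, "p_threshold"), (fdr_threshold, "fdr_threshold")):
        if not 0 < thr < 1:
            raise InputError(f"{nm} must be in (0, 1), got {thr}")

    known = set(collection.names())
    unresolved = sorted(
        {r.set_name for results in results_by_phenotype for r in results} - known
    )
    if unresolved:
        raise InputError(f"result sets absent from the collection: {unresolved}")

    universe = collection.universe if restrict_to_universe else None
    members = {
        s.name: s.effective_members(universe) for s in collection
    }

    by_phen = [{r.set_name: r for r in results} for results in results_by_phenotype]

    g = nx.Graph()
    for name in sorted(known):
        sigs = []
        for phen in by_phen:
            r = phen.get(name)
            sigs.append(
                r is not None and r.is_significant(p_threshold, fdr_threshold)
            )
        if not any(sigs):
            continue
        attrs: dict = {
            "set_size": len(members[name]),
            "significant1": sigs[0],
            "significant2": sigs[1] if len(sigs) > 1 else False,
        }
        for i, phen in enumerate(by_phen, start=1):
            r = phen.get(name)
            if r is not None:
                attrs[f"p{i}"] = r.p_nominal
                attrs[f"fdr{i}"] = r.fdr_q
                attrs[f"nes{i}"] = r.NES
        g.add_node(name, **attrs)

    node_names = sorted(g.nodes)
    for i, a in enumerate(node_names):
        for b in node_names[i + 1:]:
            ov = overlap_coefficient(members[a], members[b])
            if ov > overlap_threshold:
                g.add_edge(a, b, overlap=ov, n_shared=len(members[a] & members[b]))

    params = {
        "p_threshold": p_threshold,
        "fdr_threshold": fdr_threshold,
        "overlap_threshold": overlap_threshold,
        "similarity": "overlap_coefficient",
        "restrict_to_universe": restrict_to_universe,
        "n_phenotypes": len(by_phen),
    }
    return EnrichmentMapGraph(graph=g, params=params)


def layout(emgraph: EnrichmentMapGraph, seed: int = 42) -> dict[str, tuple[float, float]]:
    """Deterministic force-directed node positions.

    Each connected component is laid out independently with a seeded
    spring embedding, then components are packed left-to-right with a gap
    so their bounding boxes never overlap. A lone node sits at the origin.
    """
    g = emgraph.graph
    if g.number_of_nodes() == 0:
        raise InputError("cannot lay out an empty graph")
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    positions: dict[str, tuple[float, float]] = {}
    x_offset = 0.0
    gap = 1.0
    for comp in components:
        sub = g.subgraph(comp)
        if len(comp) == 1:
            local = {next(iter(comp)): np.array([0.0, 0.0])}
        else:
            local = nx.spring_layout(sub, seed=seed, k=None)
        xs = np.array([p[0] for p in local.values()])
        ys = np.array([p[1] for p in local.values()])
        shift_x = x_offset - xs.min()
        for name, p in local.items():
            positions[name] = (float(p[0] + shift_x), float(p[1] - ys.mean()))
        x_offset += (xs.max() - xs.min()) + gap
    if g.number_of_nodes() == 1:
        only = next(iter(g.nodes))
        positions[only] = (0.0, 0.0)
    return positions


def summarize_cluster_terms(
    texts: list[str], stop_words: set[str] | frozenset[str] = frozenset()
) -> list[tuple[str, int]]:
    """Word frequencies over set names/descriptions, for a term-cloud summary.

    Case-folded, stop-word filtered; ties broken lexicographically so the
    output order is deterministic.
    """
    stop = {w.lower() for w in stop_words}
    freq: dict[str, int] = {}
    for text in texts:
        for word in re.findall(r"[A-Za-z0-9']+", text.lower()):
            if word in stop:
                continue
            freq[word] = freq.get(word, 0) + 1
    return sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))


def export_graph(
    emgraph: EnrichmentMapGraph,
    out_prefix: str,
    fmt: str = "tables",
    positions: dict[str, tuple[float, float]] | None = None,
) -> list[str]:
    """Write the map as GraphML, GML, or node/edge attribute tables.

    Returns the list of files written. The tables format round-trips
    losslessly through :func:`import_tables`.
    """
    if fmt not in EXPORT_FORMATS:
        raise InputError(
            f"unsupported format {fmt!r}; supported: {', '.join(EXPORT_FORMATS)}"
        )
    g = emgraph.graph.copy()
    if positions:
        for name, (x, y) in positions.items():
            g.nodes[name]["x"] = float(x)
            g.nodes[name]["y"] = float(y)

    if fmt in ("graphml", "gml"):
        # plain python scalars only; gml additionally lacks booleans
        attr_dicts = [d for _, d in g.nodes(data=True)]
        attr_dicts += [d for _, _, d in g.edges(data=True)]
        for d in attr_dicts:
            for key, v in list(d.items()):
                if isinstance(v, np.generic):
                    v = v.item()
                if fmt == "gml" and isinstance(v, bool):
                    v = int(v)
                d[key] = v
        path = f"{out_prefix}.{fmt}"
        if fmt == "graphml":
            nx.write_graphml(g, path)
        else:
            nx.write_gml(g, path)
        return [path]

    node_rows = []
    for node in emgraph.nodes():
        row: dict = {"set_name": node.set_name, "set_size": node.set_size,
                     "significant1": node.significant1,
                     "significant2": node.significant2}
        for i, stats in ((1, node.phenotype1), (2, node.phenotype2)):
            for key in _STAT_KEYS:
                row[f"{key}{i}"] = getattr(stats, key) if stats else np.nan
        if positions:
            row["x"], row["y"] = positions[node.set_name]
        node_rows.append(row)
    edge_rows = [
        {"set_a": e.set_a, "set_b": e.set_b,
         "overlap": e.overlap, "n_shared": e.n_shared}
        for e in emgraph.edges()
    ]
    node_cols = ["set_name", "set_size", "significant1", "significant2",
                 "p1", "fdr1", "nes1", "p2", "fdr2", "nes2"]
    if positions:
        node_cols += ["x", "y"]
    nodes_path = f"{out_prefix}.nodes.tsv"
    edges_path = f"{out_prefix}.edges.tsv"
    pd.DataFrame(node_rows, columns=node_cols).to_csv(
        nodes_path, sep="\t", index=False
    )
    pd.DataFrame(
        edge_rows, columns=["set_a", "set_b", "overlap", "n_shared"]
    ).to_csv(edges_path, sep="\t", index=False)
    return [nodes_path, edges_path]


def import_tables(out_prefix: str) -> EnrichmentMapGraph:
    """Rebuild an EnrichmentMapGraph from exported node/edge tables."""
    nodes = pd.read_csv(f"{out_prefix}.nodes.tsv", sep="\t")
    edges = pd.read_csv(f"{out_prefix}.edges.tsv", sep="\t")
    g = nx.Graph()
    has_p2 = "p2" in nodes.columns and nodes["p2"].notna().any()
    for _, row in nodes.iterrows():
        attrs = {
            "set_size": int(row["set_size"]),
            "significant1": bool(row["significant1"]),
            "significant2": bool(row["significant2"]),
        }
        for i in (1, 2):
            if pd.notna(row.get(f"p{i}", np.nan)):
                for key in _STAT_KEYS:
                    attrs[f"{key}{i}"] = float(row[f"{key}{i}"])
        g.add_node(str(row["set_name"]), **attrs)
    for _, row in edges.iterrows():
        g.add_edge(
            str(row["set_a"]), str(row["set_b"]),
            overlap=float(row["overlap"]), n_shared=int(row["n_shared"]),
        )
    return EnrichmentMapGraph(
        graph=g, params={"n_phenotypes": 2 if has_p2 else 1}
    )


def render(
    emgraph: EnrichmentMapGraph,
    positions: dict[str, tuple[float, float]],
    path: str,
    max_nes: float | None = None,
) -> None:
    """Static figure with the dual inner/outer encoding.

    Inner disc = phenotype 1, outer ring = phenotype 2; red up-regulated,
    blue down, white when not significant; intensity scales with |NES|;
    disc area tracks set size; edge width tracks overlap.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    def color(stats: PhenotypeStats | None, sig: bool) -> tuple:
        if stats is None or not sig:
            return (1.0, 1.0, 1.0)
        scale = min(abs(stats.nes) / (max_nes or 3.0), 1.0)
        if stats.nes >= 0:
            return (1.0, 1.0 - scale, 1.0 - scale)
        return (1.0 - scale, 1.0 - scale, 1.0)

    fig, ax = plt.subplots(figsize=(8, 8))
    for e in emgraph.edges():
        xa, ya = positions[e.set_a]
        xb, yb = positions[e.set_b]
        ax.plot([xa, xb], [ya, yb], color="0.6", lw=0.5 + 2.0 * e.overlap,
                zorder=1)
    sizes = [n.set_size for n in emgraph.nodes()] or [1]
    smax = max(sizes)
    for node in emgraph.nodes():
        x, y = positions[node.set_name]
        r = 0.05 + 0.10 * math.sqrt(node.set_size / smax)
        ax.add_patch(plt.Circle(
            (x, y), r, facecolor=color(node.phenotype2, node.significant2),
            edgecolor="black", lw=0.5, zorder=2))
        ax.add_patch(plt.Circle(
            (x, y), 0.6 * r, facecolor=color(node.phenotype1, node.significant1),
            edgecolor="black", lw=0.3, zorder=3))
        ax.annotate(node.set_name, (x, y + r), fontsize=5, ha="center")
    ax.set_aspect("equal")
    ax.autoscale_view()
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
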