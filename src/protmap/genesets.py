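"""Gene-set collection assembly: GMT I/O, ontology up-propagation,
orthology cross-mapping, and size filtering.

A gene set is a named, a-priori-defined group of gene/protein identifiers
(a pathway, a GO term's annotated genes, a protein complex). Collections
pooled from several databases are harmonized here: GO annotations are
up-propagated along the ontology DAG (true-path rule), human-only pathway
memberships are cross-mapped to mouse orthologs, and sets outside the
informative size window (by default >15 and <=500 effective members) are
dropped before enrichment testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

from .quantify import InputError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE_EXCL = 15
DEFAULT_MAX_SIZE_INCL = 500


@dataclass
class GeneSet:
    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)
    source: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def effective_members(self, universe: set[str] | None) -> frozenset[str]:
        if universe is None:
            return self.members
        return self.members & frozenset(universe)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise InputError(f"duplicate gene-set names: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def parse_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> member...).

    Duplicate member ids within a line collapse to one; duplicate set names
    are an error. Blank lines are skipped.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                    f"(got {len(fields)})"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise InputError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in seen:
                raise InputError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, description=desc, members=members))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_obo(path) -> nx.DiGraph:
    """Load an OBO ontology as a child->parent DiGraph (is_a edges).

    Node attribute ``name`` carries the term name. obonet's convention
    already points edges from child to parent.
    """
    graph = obonet.read_obo(path)
    dag = nx.DiGraph()
    for node, data in graph.nodes(data=True):
        dag.add_node(node, name=data.get("name", ""))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    return dag


def read_two_column_table(path) -> dict[str, set[str]]:
    """Read a tab-delimited two-column mapping (source -> set of targets).

    Lines starting with '#' are skipped; used for both annotation tables
    (gene, term) and orthology/identifier-conversion tables.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def up_propagate(
    annotations: dict[str, set[str]], ontology: nx.DiGraph
) -> dict[str, set[str]]:
    """Extend gene->term annotations to all ancestor terms (true-path rule).

    Output is the transitive closure: a gene annotated to a term is also
    annotated to every parent reachable through the ontology's child->parent
    links. No annotation is removed.
    """
    if not nx.is_directed_acyclic_graph(ontology):
        raise InputError("ontology graph contains a cycle")
    ancestors: dict[str, set[str]] = {}
    order = list(nx.topological_sort(ontology))
    # Children precede parents in child->parent topological order, so walk
    # in reverse and accumulate each node's parents' closures.
    for term in reversed(order):
        anc: set[str] = set()
        for parent in ontology.successors(term):
            anc.add(parent)
            anc |= ancestors[parent]
        ancestors[term] = anc
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        closed = set(terms)
        for t in terms:
            if t not in ancestors:
                raise InputError(f"annotation references unknown term {t!r}")
            closed |= ancestors[t]
        out[gene] = closed
    return out


def sets_from_annotations(
    annotations: dict[str, set[str]],
    ontology: nx.DiGraph | None = None,
    source: str = "ontology",
) -> GeneSetCollection:
    """Invert gene->term annotations into one gene set per term."""
    by_term: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        for t in terms:
            by_term.setdefault(t, set()).add(gene)
    sets = []
    for term in sorted(by_term):
        term_name = ""
        if ontology is not None and term in ontology.nodes:
            term_name = ontology.nodes[term].get("name", "")
        name = f"{term} {term_name}".strip() if term_name else term
        sets.append(
            GeneSet(name=name, description=term_name, members=frozenset(by_term[term]),
                    source=source)
        )
    return GeneSetCollection(sets=sets)


def map_orthologs(
    collection: GeneSetCollection, omap: dict[str, set[str]]
) -> GeneSetCollection:
    """Replace each member by its mapped target ids (e.g. human -> mouse).

    One-to-many mappings expand fully; unmapped members are dropped, and
    sets left empty are dropped. Mapping statistics are logged.
    """
    n_in = n_mapped = n_dropped = 0
    sets = []
    for s in collection:
        mapped: set[str] = set()
        for m in s.members:
            n_in += 1
            targets = omap.get(m)
            if targets:
                n_mapped += 1
                mapped |= targets
            else:
                n_dropped += 1
        if mapped:
            sets.append(
                GeneSet(name=s.name, description=s.description,
                        members=frozenset(mapped), source=s.source)
            )
    logger.info(
        "ortholog mapping: %d members in, %d mapped, %d dropped; "
        "%d/%d sets retained",
        n_in, n_mapped, n_dropped, len(sets), len(collection),
    )
    return GeneSetCollection(sets=sets, universe=collection.universe)


def filter_by_size(
    collection: GeneSetCollection,
    min_excl: int = DEFAULT_MIN_SIZE_EXCL,
    max_incl: int = DEFAULT_MAX_SIZE_INCL,
    universe: set[str] | None = None,
) -> GeneSetCollection:
    """Keep sets whose effective size s satisfies min_excl < s <= max_incl.

    Small sets are likelier to look significant by chance; very large ones
    are too general to interpret. Effective size is measured against the
    universe of quantified proteins when one is supplied.
    """
    if min_excl >= max_incl:
        raise InputError(f"min_excl {min_excl} must be < max_incl {max_incl}")
    universe = universe if universe is not None else collection.universe
    kept = [
        s
        for s in collection
        if min_excl < len(s.effective_members(universe)) <= max_incl
    ]
    logger.info(
        "size filter (%d, %d]: %d of %d sets retained",
        min_excl, max_incl, len(kept), len(collection),
    )
    return GeneSetCollection(sets=kept, universe=universe)
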