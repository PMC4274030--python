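"""Functional diversity of a protein result set via GO semantic similarity.

Wang et al.'s measure scores a GO term A by propagating a semantic
contribution down from A through its ancestors: S_A(A) = 1 and, for an
ancestor t, S_A(t) is the maximum over t's children t' (within A's
ancestor DAG) of w_e · S_A(t'), with one weight per relation type
(is-a 0.8, part-of 0.6 by convention; molecular function has no part-of
edges).  SV(A) = Σ_t S_A(t).  Two terms are compared by how much semantic
mass they share:

    sim(A, B) = Σ_{t ∈ common ancestors} (S_A(t) + S_B(t)) / (SV(A) + SV(B))

Protein-level similarity aggregates the cross-term similarity matrix of
the two annotation sets (best-match average by default), and the
functional dissimilarity of a result set is the mean of 1 − similarity
over all unordered protein pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import obonet

from .star import SeqDivError
from .diversify import ContractViolation

#: Wang et al.'s published semantic-contribution weights per relation
DEFAULT_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

MOLECULAR_FUNCTION = "molecular_function"


class OntologyError(SeqDivError):
    """The ontology file is unusable (cyclic, missing terms, ...)."""


@dataclass
class GoGraph:
    """A namespace-restricted GO DAG.

    ``graph`` is a directed graph with child→parent edges annotated with
    ``relation`` ('is_a' or 'part_of'); obsolete terms and terms from
    other namespaces are absent.
    """

    graph: nx.DiGraph
    namespace: str = MOLECULAR_FUNCTION

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return len(self.graph)

    def parents(self, term: str):
        """(parent, relation) pairs of a term."""
        return [
            (p, self.graph.edges[term, p]["relation"])
            for p in self.graph.successors(term)
        ]

    def ancestor_dag(self, term: str) -> set[str]:
        """The term plus all its ancestors (Wang's DAG_A node set)."""
        if term not in self.graph:
            raise OntologyError(f"unknown GO term {term!r}")
        return {term} | nx.descendants(self.graph, term)


def load_obo(stream_or_path, namespace: str = MOLECULAR_FUNCTION) -> GoGraph:
    """Read an OBO ontology restricted to one namespace.

    Obsolete terms are dropped (obonet skips them); is-a and part-of
    relations become typed child→parent edges.  A cyclic ontology is
    rejected.
    """
    raw = obonet.read_obo(stream_or_path, ignore_obsolete=True)
    g = nx.DiGraph()
    for node, data in raw.nodes(data=True):
        if data.get("namespace", namespace) != namespace:
            continue
        g.add_node(node, name=data.get("name", ""))
    for child, parent, key in raw.edges(keys=True):
        if child not in g or parent not in g:
            continue
        if key == "is_a":
            g.add_edge(child, parent, relation="is_a")
        elif key == "part_of":
            g.add_edge(child, parent, relation="part_of")
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyError(f"ontology contains a cycle: {cycle}")
    return GoGraph(graph=g, namespace=namespace)


@dataclass(frozen=True)
class SValueTable:
    """Per-ancestor semantic contributions of one anchor term."""

    anchor: str
    s: dict[str, float]
    sv: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sv", float(sum(self.s.values())))


def s_values(term: str, g: GoGraph, weights=None) -> SValueTable:
    """Semantic contributions S_term(t) over the term's ancestor DAG.

    Evaluated child-before-parent in topological order, so each ancestor
    takes the best (max) weighted contribution over its children inside
    the DAG; this handles diamonds without double counting.
    """
    weights = dict(DEFAULT_WEIGHTS, **(weights or {}))
    if any(not (0 < w < 1) for w in weights.values()):
        raise ContractViolation("edge weights must lie in (0, 1)")
    dag = g.ancestor_dag(term)
    sub = g.graph.subgraph(dag)
    s: dict[str, float] = {term: 1.0}
    for node in nx.topological_sort(sub):  # children before parents
        if node == term:
            continue
        best = 0.0
        for child in sub.predecessors(node):
            w = weights[sub.edges[child, node]["relation"]]
            best = max(best, w * s[child])
        s[node] = best
    return SValueTable(anchor=term, s=s)


def term_similarity(a: str, b: str, g: GoGraph, weights=None) -> float:
    """Wang semantic similarity of two GO terms, in (0, 1]."""
    ta = s_values(a, g, weights)
    tb = s_values(b, g, weights)
    common = set(ta.s) & set(tb.s)
    shared = sum(ta.s[t] + tb.s[t] for t in common)
    return shared / (ta.sv + tb.sv)


AGGREGATORS = ("bma", "max", "average")


def protein_similarity(
    terms_a, terms_b, g: GoGraph, weights=None, aggregator: str = "bma"
) -> float:
    """Similarity of two proteins from their GO annotation sets.

    Builds the cross-term similarity matrix and combines it with the
    best-match average (each term matched to its best counterpart,
    averaged over both sets); ``max`` and plain ``average`` are available
    as alternatives.  Symmetric in its arguments.
    """
    terms_a, terms_b = sorted(set(terms_a)), sorted(set(terms_b))
    if not terms_a or not terms_b:
        raise ContractViolation("protein similarity needs non-empty term sets")
    if aggregator not in AGGREGATORS:
        raise ContractViolation(f"unknown aggregator {aggregator!r}")
    sim = {
        (x, y): term_similarity(x, y, g, weights) for x in terms_a for y in terms_b
    }
    if aggregator == "max":
        return max(sim.values())
    if aggregator == "average":
        return sum(sim.values()) / len(sim)
    best_a = [max(sim[(x, y)] for y in terms_b) for x in terms_a]
    best_b = [max(sim[(x, y)] for x in terms_a) for y in terms_b]
    return (sum(best_a) + sum(best_b)) / (len(terms_a) + len(terms_b))


def functional_dissimilarity(
    annotations: dict[str, set], g: GoGraph, weights=None, aggregator: str = "bma"
) -> float:
    """Mean pairwise (1 − Wang similarity) over an annotated protein set.

    ``annotations`` maps protein id → set of molecular-function GO terms;
    proteins with empty term sets must be excluded upstream.
    """
    proteins = [p for p, t in annotations.items() if t]
    if len(proteins) < 2:
        raise ContractViolation(
            "functional dissimilarity needs at least 2 annotated proteins"
        )
    dis = [
        1.0
        - protein_similarity(
            annotations[p], annotations[q], g, weights, aggregator
        )
        for p, q in combinations(proteins, 2)
    ]
    return sum(dis) / len(dis)


# ---------------------------------------------------------------------------
# annotation input


def load_annotations_tsv(stream, g: GoGraph | None = None) -> dict[str, set]:
    """Two-column TSV (protein id, GO term id) → annotation sets.

    Terms absent from ``g`` (wrong namespace, obsolete) are dropped when a
    graph is given.
    """
    ann: dict[str, set] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        protein, term = line.split("\t")[:2]
        if g is not None and term not in g:
            continue
        ann.setdefault(protein, set()).add(term)
    return ann


def load_annotations_gaf(
    stream, g: GoGraph | None = None, exclude_iea: bool = False
) -> dict[str, set]:
    """GAF 2.x annotation file → molecular-function annotation sets.

    Keeps aspect 'F' rows, skips comment lines and NOT-qualified rows;
    ``exclude_iea`` additionally drops electronically inferred (IEA)
    annotations.  Terms absent from ``g`` are dropped when a graph is
    given.
    """
    ann: dict[str, set] = {}
    for line in stream:
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise OntologyError(
                f"GAF row has {len(fields)} columns; 2.x requires >= 9"
            )
        protein, qualifier, term, evidence, aspect = (
            fields[1],
            fields[3],
            fields[4],
            fields[6],
            fields[8],
        )
        if aspect != "F" or "NOT" in qualifier.split("|"):
            continue
        if exclude_iea and evidence == "IEA":
            continue
        if g is not None and term not in g:
            continue
        ann.setdefault(protein, set()).add(term)
    return ann
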