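"""GO term overrepresentation with the elim decorrelation procedure.

The enrichment machinery here is the classic one-sided hypergeometric
(Fisher) test per term, plus the elim variant: terms are visited from the
deepest level of the ontology upward, and whenever a term is called
significant its currently annotated genes are removed from all of its
ancestors before those ancestors are tested.  This decorrelates the DAG —
a generic parent no longer inherits the signal of a specific child.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import networkx as nx
from scipy.stats import hypergeom

__all__ = [
    "GoDag",
    "AnnotationSet",
    "EnrichmentResult",
    "propagate_annotations",
    "fisher_term_test",
    "elim_enrichment",
]


class GoDagError(ValueError):
    """Raised for structurally invalid ontologies (cycles, unknown terms)."""


@dataclass
class GoDag:
    """A rooted is_a hierarchy of ontology terms.

    Edges point child -> parent.  Terms with no outgoing is_a edge are
    roots.  The graph must be acyclic and every term must reach a root.
    """

    graph: nx.DiGraph
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise GoDagError(f"ontology contains a cycle through {cycle[0][0]!r}")
        self._ancestors_cache: dict[str, frozenset[str]] = {}
        self._depth_cache: dict[str, dict[str, int]] = {}

    @classmethod
    def from_edges(
        cls,
        terms: list[str] | set[str],
        is_a: list[tuple[str, str]],
        names: dict[str, str] | None = None,
        namespaces: dict[str, str] | None = None,
    ) -> "GoDag":
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for child, parent in is_a:
            for t in (child, parent):
                if t not in g:
                    raise GoDagError(f"is_a references undeclared term {t!r}")
            g.add_edge(child, parent)
        return cls(g, names or {}, namespaces or {})

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    @property
    def leaves(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.in_degree(t) == 0}

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """Strict ancestors of *term* (excludes the term itself)."""
        cached = self._ancestors_cache.get(term)
        if cached is None:
            if term not in self.graph:
                raise GoDagError(f"unknown term {term!r}")
            cached = frozenset(nx.descendants(self.graph, term))
            self._ancestors_cache[term] = cached
        return cached

    def levels(self, scheme: str = "longest") -> dict[str, int]:
        """Term depth: path length to a root (0 for roots).

        ``longest`` uses the longest path to any root, ``shortest`` the
        shortest; elim processes deepest terms first.
        """
        if scheme not in ("longest", "shortest"):
            raise ValueError(f"unknown level scheme {scheme!r}")
        cached = self._depth_cache.get(scheme)
        if cached is not None:
            return cached
        depth: dict[str, int] = {}
        agg = max if scheme == "longest" else min
        for t in nx.topological_sort(self.graph.reverse(copy=False)):
            ps = list(self.graph.successors(t))
            depth[t] = 0 if not ps else agg(depth[p] for p in ps) + 1
        self._depth_cache[scheme] = depth
        return depth


@dataclass
class AnnotationSet:
    """Direct gene->term annotations and their true-path closure."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]

    def genes_for(self, term: str, universe: set[str] | frozenset[str]) -> set[str]:
        return {g for g in universe if term in self.propagated.get(g, ())}


def propagate_annotations(dag: GoDag, direct: dict[str, set[str] | frozenset[str]]) -> AnnotationSet:
    """Close direct annotations under is_a ancestry (true-path rule)."""
    known = dag.terms
    d: dict[str, frozenset[str]] = {}
    p: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        unknown = set(terms) - known
        if unknown:
            raise GoDagError(
                f"gene {gene!r} annotated to unknown term(s): {sorted(unknown)}"
            )
        closure: set[str] = set(terms)
        for t in terms:
            closure |= dag.ancestors(t)
        d[gene] = frozenset(terms)
        p[gene] = frozenset(closure)
    return AnnotationSet(direct=d, propagated=p)


def fisher_term_test(
    study_count: int, study_total: int, pop_count: int, pop_total: int
) -> float:
    """One-sided overrepresentation p-value.

    P(X >= study_count) for X ~ Hypergeom(pop_total, pop_count, study_total):
    drawing study_total genes from a universe of pop_total of which pop_count
    carry the term.
    """
    if not (0 <= study_count <= study_total <= pop_total):
        raise ValueError(
            f"inconsistent counts: study {study_count}/{study_total}, "
            f"population {pop_count}/{pop_total}"
        )
    if not (study_count <= pop_count <= pop_total):
        raise ValueError(
            f"inconsistent counts: study_count {study_count} > pop_count "
            f"{pop_count} or pop_count > pop_total {pop_total}"
        )
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(study_count - 1, pop_total, pop_count, study_total))


@dataclass
class EnrichmentResult:
    term: str
    name: str
    p_elim: float
    p_classic: float
    study_count: int
    study_total: int
    pop_count: int
    pop_total: int
    significant: bool


def elim_enrichment(
    dag: GoDag,
    annotations: AnnotationSet,
    study: set[str],
    population: set[str],
    alpha: float = 0.01,
    level_scheme: str = "longest",
) -> list[EnrichmentResult]:
    """Per-term Fisher tests with bottom-up elimination of significant genes.

    Terms are processed level by level from the deepest.  Each term is
    tested on its *current* annotated gene sets — the propagated
    annotations minus any genes already eliminated for it by significant
    descendants.  When a term's elim p-value is strictly below *alpha*,
    its current genes are marked eliminated for every strict ancestor.
    The uncorrected (classic) p-value is reported alongside.

    The population is a gene universe; it may contain genes with no
    annotation at all.  Results are sorted by p_elim, ties by term ID.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1): {alpha}")
    missing = study - population
    if missing:
        raise ValueError(f"study genes absent from population: {sorted(missing)[:5]}")

    study = set(study)
    population = set(population)
    study_total, pop_total = len(study), len(population)

    # term -> genes (within the universe) annotated to it after propagation
    term_pop: dict[str, set[str]] = {t: set() for t in dag.terms}
    for g in population:
        for t in annotations.propagated.get(g, ()):
            if t in term_pop:
                term_pop[t].add(g)

    depth = dag.levels(level_scheme)
    order = sorted(dag.terms, key=lambda t: (-depth[t], t))

    eliminated: dict[str, set[str]] = {t: set() for t in dag.terms}
    results: list[EnrichmentResult] = []
    for t in order:
        pop_genes = term_pop[t]
        cur = pop_genes - eliminated[t]
        sc, pc = len(cur & study), len(cur)
        p_elim = fisher_term_test(sc, study_total, pc, pop_total)
        p_classic = fisher_term_test(
            len(pop_genes & study), study_total, len(pop_genes), pop_total
        )
        sig = p_elim < alpha
        if sig:
            for anc in dag.ancestors(t):
                eliminated[anc] |= cur
        results.append(
            EnrichmentResult(
                term=t,
                name=dag.names.get(t, ""),
                p_elim=p_elim,
                p_classic=p_classic,
                study_count=sc,
                study_total=study_total,
                pop_count=pc,
                pop_total=pop_total,
                significant=sig,
            )
        )
    results.sort(key=lambda r: (r.p_elim, r.term))
    return results
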