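"""Rooted is_a DAGs with level and lowest-common-ancestor computations.

Term *level* is the length of the longest is_a path from any root down to
the term (roots sit at level 0).  The longest-path convention is the "higher
level" tie rule: when a term is reachable from a root along paths of
different lengths, the deeper one defines its level, so shared annotations
are scored at their most specific placement.  Obsolete terms stay in the
DAG (they still shape levels and ancestor sets) but are excluded as
annotation targets by the transfer filters.
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx


class StructuralError(Exception):
    """The graph violates a DAG structural invariant (e.g. a cycle)."""


class OntologyDAG:
    """Directed acyclic graph of terms linked child -> parent by is_a."""

    def __init__(self, name: str = "") -> None:
        self.name = name
        self._parents: dict[str, set[str]] = {}
        self._children: dict[str, set[str]] = {}
        self.obsolete: set[str] = set()
        self.term_names: dict[str, str] = {}
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._levels: Optional[dict[str, int]] = None

    # ------------------------------------------------------------- building

    def add_term(self, term: str, obsolete: bool = False, name: str = "") -> None:
        self._parents.setdefault(term, set())
        self._children.setdefault(term, set())
        if obsolete:
            self.obsolete.add(term)
        if name:
            self.term_names[term] = name
        self._invalidate()

    def add_is_a(self, child: str, parent: str) -> None:
        self.add_term(child)
        self.add_term(parent)
        self._parents[child].add(parent)
        self._children[parent].add(child)
        self._invalidate()

    def _invalidate(self) -> None:
        self._anc_cache.clear()
        self._levels = None

    # ------------------------------------------------------------ structure

    def __contains__(self, term: str) -> bool:
        return term in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    @property
    def terms(self) -> set[str]:
        return set(self._parents)

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self._parents[term])

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self._children[term])

    @property
    def roots(self) -> set[str]:
        return {t for t, ps in self._parents.items() if not ps}

    def to_networkx(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self._parents)
        for child, ps in self._parents.items():
            for p in ps:
                g.add_edge(child, p)
        return g

    def _require(self, term: str) -> None:
        if term not in self._parents:
            raise KeyError(f"unknown ontology term {term!r}")

    def validate(self) -> None:
        """Acyclicity and rootedness; raises ``StructuralError`` naming one
        offending edge when a cycle exists."""
        g = self.to_networkx()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            u, v = cycle[0][0], cycle[0][1]
            raise StructuralError(f"ontology {self.name!r} has a cycle through "
                                  f"is_a edge {u!r} -> {v!r}")
        if len(self) and not self.roots:
            raise StructuralError(f"ontology {self.name!r} has no root term")

    # ----------------------------------------------------------- algorithms

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable via is_a, including ``term`` itself."""
        self._require(term)
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        seen = {term}
        stack = [term]
        while stack:
            for p in self._parents[stack.pop()]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        result = frozenset(seen)
        self._anc_cache[term] = result
        return result

    def levels(self) -> dict[str, int]:
        if self._levels is None:
            self._levels = compute_term_levels(self)
        return self._levels

    def level(self, term: str) -> int:
        self._require(term)
        return self.levels()[term]


def compute_term_levels(dag: OntologyDAG) -> dict[str, int]:
    """Longest is_a path length from any root to each term; roots are 0.

    Raises ``StructuralError`` (naming a cycle edge) when the graph is not
    acyclic.
    """
    dag.validate()
    g = dag.to_networkx()
    levels: dict[str, int] = {}
    # edges run child -> parent, so process parents (graph sinks) first
    for term in reversed(list(nx.topological_sort(g))):
        ps = dag._parents[term]
        levels[term] = 0 if not ps else max(levels[p] for p in ps) + 1
    return levels


def ancestors(dag: OntologyDAG, term: str) -> frozenset[str]:
    """Reflexive transitive closure over is_a edges."""
    return dag.ancestors(term)


def lca_set(dag: OntologyDAG, t1: str, t2: str) -> frozenset[str]:
    """All lowest common ancestors of ``t1`` and ``t2``.

    A common ancestor is *lowest* when no strict descendant of it is also a
    common ancestor.  Reflexive: ``lca_set(t, t) == {t}``.
    """
    common = dag.ancestors(t1) & dag.ancestors(t2)
    if not common:
        return frozenset()
    # c is dominated if some other member of `common` has c as a strict ancestor
    dominated: set[str] = set()
    for c in common:
        dominated.update(dag.ancestors(c) - {c})
    return frozenset(c for c in common if c not in dominated)


def pair_max_lca_level(dag: OntologyDAG, terms_a: Iterable[str],
                       terms_b: Iterable[str]) -> Optional[int]:
    """Maximum level over all LCAs of all (ta, tb) pairs; None if either
    annotation set is empty or the sets share no common ancestor."""
    terms_a = list(terms_a)
    terms_b = list(terms_b)
    if not terms_a or not terms_b:
        return None
    levels = dag.levels()
    best: Optional[int] = None
    for ta in terms_a:
        for tb in terms_b:
            for lca in lca_set(dag, ta, tb):
                lv = levels[lca]
                if best is None or lv > best:
                    best = lv
    return best
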