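"""Conceptual-graph data model for biological processes.

A :class:`ConceptGraph` is a directed acyclic graph of prior-knowledge
concepts (pathways, pathway variants, components, functional units) linked
by two relation kinds:

* ``part`` — composition (a pathway is composed of reactions),
* ``subtype`` — generalization/specialization (a pathway has variants).

Edges are stored parent → child.  The graph is kept acyclic at insertion
time so the reasoner can rely on a topological order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import networkx as nx

RELATION_KINDS = ("part", "subtype")
CATEGORIES = ("pathway", "variant", "component", "functional-unit", "other")


class GraphError(ValueError):
    """Base class for concept-graph construction errors."""


class DuplicateConceptError(GraphError):
    pass


class UnknownConceptError(GraphError, KeyError):
    def __str__(self):  # KeyError would quote the repr otherwise
        return self.args[0] if self.args else ""


class DuplicateRelationError(GraphError):
    pass


class CycleError(GraphError):
    def __init__(self, path: List[str]):
        self.path = list(path)
        super().__init__("relation would close the cycle: " + " -> ".join(self.path))


@dataclass
class PriorKnowledge:
    """A node of the concept graph.

    ``category`` is advisory metadata used to group report statistics
    (e.g. pathway-level vs functional-unit-level accuracy) and never enters
    rule application.  ``is_dispensable`` marks non-essential components;
    it only takes effect when the reasoner's dispensable mode is on.
    """

    identifier: str
    label: str = ""
    category: str = "other"
    is_dispensable: bool = False

    def __post_init__(self):
        if not self.identifier:
            raise GraphError("concept identifier must be non-empty")
        if self.category not in CATEGORIES:
            raise GraphError(
                "unknown category %r for %r (expected one of %s)"
                % (self.category, self.identifier, ", ".join(CATEGORIES)))


@dataclass(frozen=True)
class Relation:
    parent: str
    child: str
    kind: str

    def __post_init__(self):
        if self.kind not in RELATION_KINDS:
            raise GraphError("unknown relation kind %r" % (self.kind,))
        if self.parent == self.child:
            raise GraphError("self-relation on %r" % (self.parent,))


class ConceptGraph:
    """Mutable DAG of :class:`PriorKnowledge` nodes with typed edges."""

    def __init__(self):
        self._concepts: Dict[str, PriorKnowledge] = {}
        self._dg = nx.DiGraph()

    # -- construction -------------------------------------------------

    def add_concept(self, concept: PriorKnowledge) -> "ConceptGraph":
        if concept.identifier in self._concepts:
            raise DuplicateConceptError(
                "duplicate concept identifier %r" % (concept.identifier,))
        self._concepts[concept.identifier] = concept
        self._dg.add_node(concept.identifier)
        return self

    def add_relation(self, parent: str, child: str, kind: str) -> "ConceptGraph":
        if kind not in RELATION_KINDS:
            raise GraphError("unknown relation kind %r" % (kind,))
        for endpoint in (parent, child):
            if endpoint not in self._concepts:
                raise UnknownConceptError("unknown concept %r" % (endpoint,))
        if parent == child:
            raise CycleError([parent, child])
        if self._dg.has_edge(parent, child):
            raise DuplicateRelationError(
                "relation %r -> %r already present" % (parent, child))
        if nx.has_path(self._dg, child, parent):
            path = nx.shortest_path(self._dg, child, parent)
            raise CycleError(path + [child])
        self._dg.add_edge(parent, child, kind=kind)
        return self

    # -- queries -------------------------------------------------------

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def identifiers(self) -> List[str]:
        return sorted(self._concepts)

    def concept(self, identifier: str) -> PriorKnowledge:
        try:
            return self._concepts[identifier]
        except KeyError:
            raise UnknownConceptError("unknown concept %r" % (identifier,)) from None

    def relations(self) -> List[Relation]:
        return sorted(
            (Relation(p, c, d["kind"]) for p, c, d in self._dg.edges(data=True)),
            key=lambda r: (r.parent, r.child))

    def children(self, identifier: str, kind: Optional[str] = None) -> List[str]:
        self.concept(identifier)
        out = [c for _, c, d in self._dg.out_edges(identifier, data=True)
               if kind is None or d["kind"] == kind]
        return sorted(out)

    def parents(self, identifier: str, kind: Optional[str] = None) -> List[str]:
        self.concept(identifier)
        out = [p for p, _, d in self._dg.in_edges(identifier, data=True)
               if kind is None or d["kind"] == kind]
        return sorted(out)

    def roots(self) -> List[str]:
        return sorted(n for n in self._concepts if self._dg.in_degree(n) == 0)

    def leaves(self) -> List[str]:
        return sorted(n for n in self._concepts if self._dg.out_degree(n) == 0)

    def is_leaf(self, identifier: str) -> bool:
        self.concept(identifier)
        return self._dg.out_degree(identifier) == 0

    def is_specific(self, identifier: str) -> bool:
        """True iff the concept hangs from exactly one parent by a part relation.

        Recomputed from the edges, so it stays correct under any mutation
        sequence.
        """
        return len(self.parents(identifier, "part")) == 1

    # -- validation & ordering -----------------------------------------

    def validate(self) -> List[str]:
        """Return a list of invariant violations (empty = structurally valid)."""
        violations: List[str] = []
        for p, c, d in self._dg.edges(data=True):
            if p not in self._concepts:
                violations.append("edge endpoint %r has no concept record" % (p,))
            if c not in self._concepts:
                violations.append("edge endpoint %r has no concept record" % (c,))
            if d.get("kind") not in RELATION_KINDS:
                violations.append("edge %r -> %r has invalid kind %r"
                                  % (p, c, d.get("kind")))
            if p == c:
                violations.append("self-relation on %r" % (p,))
        try:
            cycle = nx.find_cycle(self._dg)
        except nx.NetworkXNoCycle:
            pass
        else:
            violations.append(
                "cycle: " + " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1])
        return violations

    def topological_order(self, direction: str = "leaf-to-root") -> List[str]:
        """Identifiers ordered so propagation can run in a single pass.

        ``leaf-to-root``: every child precedes each of its parents (the
        prediction pass); ``root-to-leaf``: the reverse (the expectation
        pass).  Deterministic: ties broken lexicographically.
        """
        if direction not in ("leaf-to-root", "root-to-leaf"):
            raise ValueError("direction must be 'leaf-to-root' or 'root-to-leaf'")
        try:
            order = list(nx.lexicographical_topological_sort(self._dg))
        except nx.NetworkXUnfeasible:
            raise CycleError(["<cycle detected during topological sort>"])
        # lexicographical_topological_sort emits parents before children
        # (edges point parent -> child)
        if direction == "leaf-to-root":
            order.reverse()
        return order

    def descendants(self, identifier: str) -> List[str]:
        self.concept(identifier)
        return sorted(nx.descendants(self._dg, identifier))

    def copy(self) -> "ConceptGraph":
        g = ConceptGraph()
        for c in self._concepts.values():
            g.add_concept(PriorKnowledge(c.identifier, c.label,
                                         c.category, c.is_dispensable))
        for r in self.relations():
            g.add_relation(r.parent, r.child, r.kind)
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return "ConceptGraph(%d concepts, %d relations)" % (
            len(self._concepts), self._dg.number_of_edges())
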