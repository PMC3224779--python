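"""Bidirectional diff between the reasoned hierarchy and the target ontology.

Three kinds of disagreement are reported:

1. an inferred subclass axiom missing from the target (``inferred_new`` —
   split off from inferred axioms found directly as asserted edges or
   indirectly via an asserted path);
2. an asserted subclass axiom between defined terms that the definitions
   do not entail (``asserted_not_found``);
3. two distinct target terms whose definitions make them logically
   equivalent (``equivalence_classes``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .core_model import LogicalDefinition, OntologyGraph, Relation, TermId
from .el_reasoner import AxiomSource, Axiom, InferredHierarchy, NormalizedAxiomSet, SubsumptionClosure, classify

log = logging.getLogger(__name__)

__all__ = ["Trace", "ComparisonReport", "compare", "trace_explanation"]

Edge = tuple[TermId, TermId]


@dataclass(frozen=True)
class Trace:
    """Why an edge was inferred: the endpoint definitions plus every
    building-block subsumption, relationship and bridge the completion
    rules touched while deriving it."""

    definitions: tuple[LogicalDefinition, ...]
    isa_edges: frozenset[Edge]
    rel_edges: frozenset[tuple[TermId, Relation, TermId]]
    bridges: frozenset[frozenset[TermId]]
    axioms: frozenset = frozenset()  # the normalized axioms used (for replay)
    note: str = ""


@dataclass
class ComparisonReport:
    inferred_found_direct: set[Edge] = field(default_factory=set)
    inferred_found_indirect: set[Edge] = field(default_factory=set)
    inferred_new: set[Edge] = field(default_factory=set)
    asserted_found: set[Edge] = field(default_factory=set)
    asserted_not_found: set[Edge] = field(default_factory=set)
    equivalence_classes: set[frozenset[TermId]] = field(default_factory=set)
    explanations: dict[Edge, Trace] = field(default_factory=dict)
    labels: dict[TermId, str] = field(default_factory=dict)
    definitions: dict[TermId, LogicalDefinition] = field(default_factory=dict)

    def category_counts(self) -> dict[str, int]:
        return {
            "inferred_axioms": len(self.inferred_found_direct)
            + len(self.inferred_found_indirect)
            + len(self.inferred_new),
            "inferred_found_direct": len(self.inferred_found_direct),
            "inferred_found_indirect": len(self.inferred_found_indirect),
            "inferred_new": len(self.inferred_new),
            "asserted_found": len(self.asserted_found),
            "asserted_not_found": len(self.asserted_not_found),
            "equivalence_classes": len(self.equivalence_classes),
        }


def compare(
    inferred: InferredHierarchy,
    closure: SubsumptionClosure,
    target: OntologyGraph,
    defined_terms: Iterable[TermId],
    *,
    definitions: Mapping[TermId, LogicalDefinition] | None = None,
    labels: Mapping[TermId, str] | None = None,
) -> ComparisonReport:
    """Classify every inferred direct edge and every asserted defined-term edge.

    Reasoned → target: an inferred edge (A, B) is *directly found* if the
    target asserts it, *indirectly found* if the target asserts a path from
    A to B (necessarily of length ≥ 2), and *new* otherwise.  Target →
    reasoned: an asserted edge between two defined, non-obsolete terms is
    *found* iff the closure entails it.  Edges with an undefined or
    obsolete endpoint are outside the comparison and logged.  Pure function
    of its inputs.
    """
    defined = set(defined_terms)
    definitions = dict(definitions or {})
    report = ComparisonReport(
        equivalence_classes=set(inferred.equivalences),
        labels=dict(labels or target.labels()),
        definitions=definitions,
    )

    def obsolete(t: TermId) -> bool:
        info = target.terms.get(t)
        return info is not None and info.obsolete

    asserted_graph = nx.DiGraph()
    asserted_graph.add_nodes_from(t for t in target.terms if not obsolete(t))
    for c, p in target.isa_edges:
        if not obsolete(c) and not obsolete(p):
            asserted_graph.add_edge(c, p)

    for edge in sorted(inferred.direct_edges):
        a, b = edge
        if asserted_graph.has_edge(a, b):
            report.inferred_found_direct.add(edge)
        elif a in asserted_graph and b in asserted_graph and nx.has_path(asserted_graph, a, b):
            report.inferred_found_indirect.add(edge)
        else:
            report.inferred_new.add(edge)
        try:
            report.explanations[edge] = trace_explanation(edge, closure, definitions)
        except LookupError:  # pragma: no cover - direct edges are always derivable
            pass

    skipped = 0
    for edge in sorted(target.isa_edges):
        a, b = edge
        if a not in defined or b not in defined or obsolete(a) or obsolete(b):
            skipped += 1
            continue
        if closure.entails(a, b):
            report.asserted_found.add(edge)
        else:
            report.asserted_not_found.add(edge)
    if skipped:
        log.info("%d asserted target edge(s) outside the comparison (undefined or obsolete endpoint)", skipped)
    return report


def trace_explanation(
    edge: Edge,
    closure: SubsumptionClosure,
    definitions: Mapping[TermId, LogicalDefinition] | None = None,
) -> Trace:
    """Walk the derivation of an inferred edge back to its source axioms.

    Raises ``LookupError`` if the edge was not derived in this run.
    Replaying classification on just the returned axioms re-derives the
    edge (the trace is sufficient, though not necessarily minimal as an
    axiom set).
    """
    definitions = dict(definitions or {})
    child, parent = edge
    root = ("S", child, parent)
    if root not in closure.derivations:
        raise LookupError(f"edge ({child}, {parent}) was not inferred in this run")

    axioms: set[Axiom] = set()
    seen: set[tuple] = set()
    stack = [root]
    while stack:
        fact = stack.pop()
        if fact in seen:
            continue
        seen.add(fact)
        axiom, premises = closure.derivations[fact]
        if axiom is not None:
            axioms.add(axiom)
        stack.extend(premises)

    isa, rels, bridges, used_defs = set(), set(), set(), set()
    for ax in axioms:
        src: AxiomSource = ax.source
        if src is None:
            continue
        if src.kind == "is_a":
            isa.add(src.payload)
        elif src.kind == "relationship":
            rels.add(src.payload)
        elif src.kind == "bridge":
            bridges.add(frozenset(src.payload))
        elif src.kind == "definition":
            used_defs.add(src.payload[0])

    used_defs |= {t for t in edge if t in definitions}
    defs = tuple(definitions[t] for t in sorted(used_defs) if t in definitions)

    note = ""
    dc, dp = definitions.get(child), definitions.get(parent)
    if dc is not None and dp is not None and dc.signature() == dp.signature():
        note = "definitions syntactically identical"
    return Trace(
        definitions=defs,
        isa_edges=frozenset(isa),
        rel_edges=frozenset(rels),
        bridges=frozenset(bridges),
        axioms=frozenset(axioms),
        note=note,
    )
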