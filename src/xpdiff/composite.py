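"""Assemble the single ontology handed to the reasoner.

The composite is the set-union of the building-block subsets, every defined
target term as a named class, the logical definitions as equivalence axioms,
and optional cross-reference-derived bridge equivalences (e.g. a
species-specific anatomy class declared equivalent to its species-neutral
counterpart).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_model import Finding, LogicalDefinition, OntologyGraph, TermId

log = logging.getLogger(__name__)

__all__ = ["CompositeOntology", "build_composite", "build_xref_bridge"]

BridgePair = frozenset  # frozenset of two TermIds


@dataclass
class CompositeOntology:
    graph: OntologyGraph
    definitions: dict[TermId, LogicalDefinition]
    equivalence_bridges: set[BridgePair]
    findings: list[Finding] = field(default_factory=list)


def build_composite(
    subsets: Sequence[OntologyGraph],
    definitions: Iterable[LogicalDefinition],
    bridges: Iterable[BridgePair] = (),
) -> CompositeOntology:
    """Union the subset graphs and attach definitions and bridges.

    Set-union semantics make the operation order-independent.  Conflicting
    labels for one term across subsets produce a warning finding (first
    non-empty label, lowest-sorting spelling, wins).  Genera, fillers and
    bridge endpoints missing from the union are added as isolated atomic
    classes with an ``unresolved_reference`` finding — a stale reference
    then subsumes only itself instead of aborting the run.
    """
    findings: list[Finding] = []
    graph = OntologyGraph()

    label_candidates: dict[TermId, set[str]] = {}
    for subset in subsets:
        for t, info in subset.terms.items():
            graph.add_term(t, obsolete=info.obsolete, xrefs=info.xrefs)
            if info.label:
                label_candidates.setdefault(t, set()).add(info.label)
        graph.isa_edges |= subset.isa_edges
        graph.rel_edges |= subset.rel_edges
    for t, cands in label_candidates.items():
        graph.terms[t].label = min(cands)
        if len(cands) > 1:
            findings.append(
                Finding("label_conflict", f"conflicting labels for {t}: {sorted(cands)}", (t,))
            )

    defmap: dict[TermId, LogicalDefinition] = {}
    for d in definitions:
        prior = defmap.get(d.defined)
        if prior is not None and prior != d:
            raise ValueError(f"conflicting logical definitions for {d.defined}")
        defmap[d.defined] = d

    bridge_set = {frozenset(b) for b in bridges}
    for b in bridge_set:
        if len(b) != 2:
            raise ValueError(f"bridge pair must have two members, got {sorted(map(str, b))}")

    referenced = [t for d in defmap.values() for t in d.referenced()]
    referenced += [t for b in bridge_set for t in b]
    for t in referenced:
        if t not in graph.terms:
            graph.add_term(t)
            findings.append(
                Finding("unresolved_reference", f"referenced term {t} not found in any subset; added as atomic class", (t,))
            )
    for d in defmap.values():
        graph.add_term(d.defined)

    n_unresolved = sum(1 for f in findings if f.kind == "unresolved_reference")
    if n_unresolved:
        log.warning("%d referenced term(s) unresolved; added as atomic classes", n_unresolved)
    return CompositeOntology(graph, defmap, bridge_set, findings)


def build_xref_bridge(
    bridging_ontology: OntologyGraph,
    bridged_prefixes: Iterable[str],
    *,
    own_prefix: str | None = None,
    use_subclass_edges: bool = True,
    use_xrefs: bool = True,
) -> set[BridgePair]:
    """Equivalence pairs linking bridged-prefix classes to the bridging ontology.

    Two sources, both on by default: a subclass edge ``X is_a U`` where X
    carries a bridged prefix and U the bridging ontology's own prefix, and a
    cross-reference on U pointing into a bridged prefix.  One U with xrefs
    to two classes of the same bridged prefix yields two pairs; the
    resulting intra-prefix equivalence surfaces downstream in
    ``equivalence_ax.txt`` for a curator to judge.
    """
    bridged = set(bridged_prefixes)
    if own_prefix is None:
        counts = {p: c for p, c in bridging_ontology.prefixes().items() if p not in bridged}
        if not counts:
            return set()
        top = max(counts.values())
        own_prefix = min(p for p, c in counts.items() if c == top)

    pairs: set[BridgePair] = set()
    if use_subclass_edges:
        for child, parent in bridging_ontology.isa_edges:
            if child.prefix in bridged and parent.prefix == own_prefix:
                pairs.add(frozenset((child, parent)))
    if use_xrefs:
        for t, info in bridging_ontology.terms.items():
            if t.prefix != own_prefix:
                continue
            for x in info.xrefs:
                if x.prefix in bridged:
                    pairs.add(frozenset((x, t)))
    return {p for p in pairs if len({t.prefix for t in p}) == 2}
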