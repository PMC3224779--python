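"""Induced ancestral graphs: the minimal building-block subsets needed for reasoning.

Only terms directly referenced by the logical definitions, plus all their
ancestors on all paths back to the root(s), can influence the inferred
target hierarchy; classification over these subsets is identical to
classification over the full ontologies (tested end-to-end).  Upward
closure follows ``is_a`` by default; additional relations (e.g. ``part_of``)
can be added per subset.  All edges between retained terms are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_model import Finding, LogicalDefinition, OntologyGraph, Relation, TermId

log = logging.getLogger(__name__)

__all__ = ["SubsetSpec", "referenced_terms", "induced_ancestral_graph"]


@dataclass(frozen=True)
class SubsetSpec:
    """What to extract from one building-block ontology."""

    ontology_prefix: str
    seeds: frozenset[TermId]
    closure_relations: frozenset[Relation] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "seeds", frozenset(self.seeds))
        object.__setattr__(self, "closure_relations", frozenset(self.closure_relations))
        bad = {s for s in self.seeds if s.prefix != self.ontology_prefix}
        if bad:
            raise ValueError(
                f"seeds {sorted(map(str, bad))} do not carry prefix {self.ontology_prefix!r}"
            )


def referenced_terms(definitions: Iterable[LogicalDefinition], prefix: str) -> set[TermId]:
    """Genera and fillers with the given prefix; defined terms themselves excluded."""
    definitions = list(definitions)
    defined = {d.defined for d in definitions}
    return {
        t for d in definitions for t in d.referenced() if t.prefix == prefix and t not in defined
    }


def induced_ancestral_graph(
    ontology: OntologyGraph,
    spec: SubsetSpec,
    findings: list[Finding] | None = None,
) -> OntologyGraph:
    """Seeds plus every ancestor reachable via the closure relations.

    Seeds absent from the ontology are skipped with a warning finding —
    a stale reference in a definition file that curators must see; the
    missing term later re-enters reasoning as a fresh atomic class.
    All ``is_a`` and relationship edges with both endpoints retained are
    carried over, along with labels, xrefs and obsolescence flags.
    """
    present = {s for s in spec.seeds if s in ontology.terms}
    for missing in sorted(spec.seeds - present):
        msg = f"seed {missing} not found in ontology {spec.ontology_prefix}"
        log.warning(msg)
        if findings is not None:
            findings.append(Finding("missing_seed", msg, (missing,)))

    parents: dict[TermId, set[TermId]] = {}
    for c, p in ontology.isa_edges:
        if c in ontology.terms and p in ontology.terms:
            parents.setdefault(c, set()).add(p)
    for s, r, o in ontology.rel_edges:
        if r in spec.closure_relations and s in ontology.terms and o in ontology.terms:
            parents.setdefault(s, set()).add(o)

    keep: set[TermId] = set()
    stack = list(present)
    while stack:
        node = stack.pop()
        if node in keep:
            continue
        keep.add(node)
        stack.extend(parents.get(node, ()))

    out = OntologyGraph()
    for t in keep:
        info = ontology.terms[t]
        out.add_term(t, info.label, obsolete=info.obsolete, xrefs=info.xrefs)
    out.isa_edges = {(c, p) for c, p in ontology.isa_edges if c in keep and p in keep}
    out.rel_edges = {(s, r, o) for s, r, o in ontology.rel_edges if s in keep and o in keep}
    return out
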