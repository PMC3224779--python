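"""Domain types shared by every pipeline stage.

The model is deliberately small: named classes (terms) with labels,
obsolescence flags and cross-references; untyped subsumption edges
(``is_a``); and typed relationship edges.  Logical definitions follow the
genus/differentia cross-product pattern used for phenotype ontologies: a
defined term is equivalent to the intersection of one or more named genus
classes and zero or more existential restrictions ``relation some filler``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "TermId",
    "Relation",
    "TermInfo",
    "OntologyGraph",
    "LogicalDefinition",
    "Finding",
    "ParseError",
    "parse_term_id",
    "validate",
]


class ParseError(ValueError):
    """Raised for malformed identifiers, stanzas or documents."""


@dataclass(frozen=True, order=True)
class TermId:
    """A normalized CURIE: ontology prefix plus local identifier.

    Both the colon dialect (``HP:0001943``) and the underscore dialect
    (``MP_0003951``) parse to the same value; the colon form is canonical
    on output so that reports are bit-stable regardless of input spelling.
    """

    prefix: str
    local: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local}"

    @classmethod
    def parse(cls, token: str) -> "TermId":
        return parse_term_id(token)


def parse_term_id(token: str) -> TermId:
    """Parse a CURIE in either the ``PREFIX:LOCAL`` or ``PREFIX_LOCAL`` dialect.

    The separator is the first colon if present, otherwise the *last*
    underscore (prefixes such as ``MOUSE_PATH`` may themselves contain
    underscores, locals never do).
    """
    if not token:
        raise ParseError("empty term identifier")
    token = token.strip()
    if ":" in token:
        prefix, _, local = token.partition(":")
    elif "_" in token:
        prefix, _, local = token.rpartition("_")
    else:
        raise ParseError(f"malformed term identifier {token!r}: no ':' or '_' separator")
    if not prefix or not local:
        raise ParseError(f"malformed term identifier {token!r}: empty prefix or local part")
    return TermId(prefix, local)


@dataclass(frozen=True, order=True)
class Relation:
    """An object property token such as ``inheres_in`` or ``towards``.

    ``is_a`` is *not* a Relation — subsumption is structural and carried by
    :attr:`OntologyGraph.isa_edges`.  Tokens are case-sensitive; an optional
    ``OBO_REL:`` prefix is trimmed on construction.
    """

    name: str

    def __post_init__(self) -> None:
        name = self.name.strip()
        if name.startswith("OBO_REL:"):
            name = name[len("OBO_REL:"):]
        if not name or name == "is_a":
            raise ParseError(f"invalid relation token {self.name!r}")
        object.__setattr__(self, "name", name)

    def __str__(self) -> str:
        return self.name


@dataclass
class TermInfo:
    label: str = ""
    obsolete: bool = False
    xrefs: set[TermId] = field(default_factory=set)


Edge = tuple[TermId, TermId]
RelEdge = tuple[TermId, Relation, TermId]


@dataclass
class OntologyGraph:
    """Named classes plus asserted ``is_a`` edges and typed relationship edges.

    Invariants (checked by :func:`validate`, not enforced on mutation):
    every edge endpoint is a declared term; the ``is_a`` digraph is acyclic;
    obsolete terms carry no ``is_a`` edges.
    """

    terms: dict[TermId, TermInfo] = field(default_factory=dict)
    isa_edges: set[Edge] = field(default_factory=set)
    rel_edges: set[RelEdge] = field(default_factory=set)

    def add_term(
        self,
        tid: TermId,
        label: str = "",
        *,
        obsolete: bool = False,
        xrefs: Iterable[TermId] = (),
    ) -> None:
        info = self.terms.get(tid)
        if info is None:
            self.terms[tid] = TermInfo(label, obsolete, set(xrefs))
        else:
            if label:
                info.label = label
            info.obsolete = info.obsolete or obsolete
            info.xrefs.update(xrefs)

    def add_isa(self, child: TermId, parent: TermId) -> None:
        self.isa_edges.add((child, parent))

    def add_rel(self, subject: TermId, relation: Relation, obj: TermId) -> None:
        self.rel_edges.add((subject, relation, obj))

    def label(self, tid: TermId) -> str:
        info = self.terms.get(tid)
        return info.label if info else ""

    def labels(self) -> dict[TermId, str]:
        return {t: i.label for t, i in self.terms.items()}

    def prefixes(self) -> Counter:
        return Counter(t.prefix for t in self.terms)

    def dominant_prefix(self) -> str:
        """Most frequent term prefix (ties broken lexicographically)."""
        counts = self.prefixes()
        if not counts:
            raise ValueError("empty ontology graph has no prefix")
        top = max(counts.values())
        return min(p for p, c in counts.items() if c == top)

    def isa_digraph(self, *, known_only: bool = True) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for c, p in self.isa_edges:
            if known_only and (c not in self.terms or p not in self.terms):
                continue
            g.add_edge(c, p)
        return g

    def copy(self) -> "OntologyGraph":
        out = OntologyGraph()
        for t, i in self.terms.items():
            out.terms[t] = TermInfo(i.label, i.obsolete, set(i.xrefs))
        out.isa_edges = set(self.isa_edges)
        out.rel_edges = set(self.rel_edges)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return (
            self.isa_edges == other.isa_edges
            and self.rel_edges == other.rel_edges
            and self.terms.keys() == other.terms.keys()
            and all(
                (a.label, a.obsolete, a.xrefs) == (b.label, b.obsolete, b.xrefs)
                for a, b in ((self.terms[t], other.terms[t]) for t in self.terms)
            )
        )


@dataclass(frozen=True)
class LogicalDefinition:
    """``defined ≡ genera₁ ⊓ … ⊓ ∃r₁.f₁ ⊓ …`` — a cross-product definition.

    ``genera`` are the named-class conjuncts, ``differentia`` the
    (relation, filler) existential conjuncts.  A run admits at most one
    definition per defined term.
    """

    defined: TermId
    genera: tuple[TermId, ...]
    differentia: tuple[tuple[Relation, TermId], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genera", tuple(self.genera))
        object.__setattr__(self, "differentia", tuple(self.differentia))
        if len(self.genera) < 1:
            raise ParseError(f"definition of {self.defined} has no genus")
        if self.defined in self.genera or self.defined in (f for _, f in self.differentia):
            raise ParseError(f"definition of {self.defined} refers to itself")

    def referenced(self) -> Iterator[TermId]:
        yield from self.genera
        for _, filler in self.differentia:
            yield filler

    def signature(self) -> tuple[frozenset, frozenset]:
        """Order-insensitive conjunct sets; equal signatures ⇒ equivalent classes."""
        return frozenset(self.genera), frozenset(self.differentia)


@dataclass(frozen=True)
class Finding:
    """A structural problem reported (never raised) by :func:`validate`."""

    kind: str  # dangling | isa_cycle | obsolete_isa | missing_seed | label_conflict | unresolved_reference
    message: str
    terms: tuple[TermId, ...] = ()


def validate(graph: OntologyGraph) -> list[Finding]:
    """Structural QC of an ontology graph; pure and idempotent.

    Reports dangling edge endpoints, ``is_a`` cycles (one finding per
    strongly connected component, members sorted) and ``is_a`` edges
    incident to obsolete terms.
    """
    findings: list[Finding] = []
    for child, parent in sorted(graph.isa_edges):
        for end in (child, parent):
            if end not in graph.terms:
                findings.append(
                    Finding("dangling", f"is_a edge ({child}, {parent}) references undeclared term {end}", (end,))
                )
    for s, r, o in sorted(graph.rel_edges):
        for end in (s, o):
            if end not in graph.terms:
                findings.append(
                    Finding("dangling", f"relationship ({s}, {r}, {o}) references undeclared term {end}", (end,))
                )

    g = graph.isa_digraph(known_only=True)
    for scc in nx.strongly_connected_components(g):
        members = tuple(sorted(scc))
        if len(members) > 1 or g.has_edge(members[0], members[0]):
            findings.append(
                Finding("isa_cycle", "is_a cycle through " + ", ".join(map(str, members)), members)
            )

    for child, parent in sorted(graph.isa_edges):
        child_info = graph.terms.get(child)
        parent_info = graph.terms.get(parent)
        if child_info is not None and child_info.obsolete:
            findings.append(
                Finding("obsolete_isa", f"obsolete term {child} has outgoing is_a edge to {parent}", (child, parent))
            )
        if parent_info is not None and parent_info.obsolete:
            findings.append(
                Finding("obsolete_isa", f"obsolete term {parent} has is_a child {child}", (child, parent))
            )
    return findings
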