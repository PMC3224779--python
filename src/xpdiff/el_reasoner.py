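"""Subsumption classification for the EL fragment the cross-product pattern uses.

The composite ontology only ever contains named classes, conjunction,
existential restriction, subclass axioms and equivalences, i.e. the EL
description logic without negation or disjointness — so classification is
polynomial and the ontology can never be inconsistent.  The engine is the
standard two-phase procedure: structural normalization into four normal
forms, then saturation under the EL completion rules to a least fixpoint.

Normal forms (all classes named, original or fresh):

* NF1  ``A ⊑ B``
* NF2  ``A ⊓ B ⊑ C``
* NF3  ``A ⊑ ∃r.B``
* NF4  ``∃r.A ⊑ B``

Completion rules, applied until nothing new derives:

* CR1  ``A⊑B, B⊑C ⇒ A⊑C``
* CR2  ``A⊑B₁, A⊑B₂, B₁⊓B₂⊑C ⇒ A⊑C``
* CR3  ``A⊑B, B⊑∃r.C ⇒ A⊑∃r.C``
* CR4  ``A⊑∃r.B, B⊑B′, ∃r.B′⊑C ⇒ A⊑C``

Every derived fact records the axiom and premise facts that produced it, so
disagreement reports can explain an inference by the definitions and
building-block edges that drove it.
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .composite import CompositeOntology
from .core_model import LogicalDefinition, Relation, TermId

__all__ = [
    "AxiomSource",
    "Sub",
    "SubConj",
    "SubEx",
    "ExSub",
    "NormalizedAxiomSet",
    "SubsumptionClosure",
    "InferredHierarchy",
    "normalize",
    "classify",
    "inferred_target_axioms",
    "subset_axiom_set",
]

_FRESH_PREFIX = "_N"


@dataclass(frozen=True)
class AxiomSource:
    """Where a normalized axiom came from: an edge, a definition or a bridge."""

    kind: str  # 'is_a' | 'relationship' | 'definition' | 'bridge'
    payload: tuple

    def __repr__(self) -> str:  # compact, for traces
        return f"{self.kind}{self.payload}"


def _src(kind: str, *payload) -> AxiomSource:
    return AxiomSource(kind, tuple(payload))


@dataclass(frozen=True)
class Sub:  # NF1
    sub: TermId
    sup: TermId
    source: AxiomSource = field(compare=False, default=None)


@dataclass(frozen=True)
class SubConj:  # NF2
    left1: TermId
    left2: TermId
    sup: TermId
    source: AxiomSource = field(compare=False, default=None)


@dataclass(frozen=True)
class SubEx:  # NF3
    sub: TermId
    rel: Relation
    filler: TermId
    source: AxiomSource = field(compare=False, default=None)


@dataclass(frozen=True)
class ExSub:  # NF4
    rel: Relation
    filler: TermId
    sup: TermId
    source: AxiomSource = field(compare=False, default=None)


Axiom = Sub | SubConj | SubEx | ExSub


@dataclass
class NormalizedAxiomSet:
    type1: set[Sub] = field(default_factory=set)
    type2: set[SubConj] = field(default_factory=set)
    type3: set[SubEx] = field(default_factory=set)
    type4: set[ExSub] = field(default_factory=set)
    fresh_names: set[TermId] = field(default_factory=set)
    extra_names: set[TermId] = field(default_factory=set)  # names with no axioms

    def all_axioms(self) -> list[Axiom]:
        return [*self.type1, *self.type2, *self.type3, *self.type4]

    def names(self) -> set[TermId]:
        out = set(self.extra_names)
        for ax in self.type1:
            out.update((ax.sub, ax.sup))
        for ax in self.type2:
            out.update((ax.left1, ax.left2, ax.sup))
        for ax in self.type3:
            out.update((ax.sub, ax.filler))
        for ax in self.type4:
            out.update((ax.filler, ax.sup))
        return out


def _fresh(defined: TermId, tag: str) -> TermId:
    digest = hashlib.sha1(f"{defined}|{tag}".encode()).hexdigest()[:10]
    return TermId(_FRESH_PREFIX, digest)


def normalize(composite: CompositeOntology, *, include_rel_edges: bool = True) -> NormalizedAxiomSet:
    """Translate the composite ontology into the four EL normal forms.

    ``is_a`` edges become NF1; relationship edges the existential reading
    ``S ⊑ ∃r.O`` (NF3, switchable off); each definition contributes both
    directions of its equivalence — ``defined`` under every conjunct, and a
    fresh-name encoding of "everything under all conjuncts is under
    ``defined``" (NF4 axioms naming each existential conjunct, then a
    left-associated NF2 chain).  Bridges become mutual NF1 axioms.  Axioms
    incident to obsolete terms are dropped: obsolete classes take no part
    in reasoning.  Fresh names are content-hashed, so normalization is
    deterministic.
    """
    graph = composite.graph
    axioms = NormalizedAxiomSet()

    def obsolete(t: TermId) -> bool:
        info = graph.terms.get(t)
        return info is not None and info.obsolete

    axioms.extra_names = {t for t in graph.terms if not obsolete(t)}

    for child, parent in graph.isa_edges:
        if obsolete(child) or obsolete(parent):
            continue
        axioms.type1.add(Sub(child, parent, _src("is_a", child, parent)))

    if include_rel_edges:
        for s, r, o in graph.rel_edges:
            if obsolete(s) or obsolete(o):
                continue
            axioms.type3.add(SubEx(s, r, o, _src("relationship", s, r, o)))

    for d in sorted(composite.definitions.values(), key=lambda d: d.defined):
        if obsolete(d.defined):
            continue
        src = _src("definition", d.defined)
        # direction 1: defined is under every conjunct
        for g in d.genera:
            axioms.type1.add(Sub(d.defined, g, src))
        for r, f in d.differentia:
            axioms.type3.add(SubEx(d.defined, r, f, src))
        # direction 2: the conjunction is under defined, via fresh names
        conjuncts: list[TermId] = list(d.genera)
        for i, (r, f) in enumerate(d.differentia):
            n = _fresh(d.defined, f"ex{i}|{r}|{f}")
            axioms.fresh_names.add(n)
            axioms.type4.add(ExSub(r, f, n, src))
            conjuncts.append(n)
        if len(conjuncts) == 1:
            axioms.type1.add(Sub(conjuncts[0], d.defined, src))
        else:
            prev = conjuncts[0]
            for i, c in enumerate(conjuncts[1:], start=1):
                if i == len(conjuncts) - 1:
                    target = d.defined
                else:
                    target = _fresh(d.defined, f"chain{i}")
                    axioms.fresh_names.add(target)
                axioms.type2.add(SubConj(prev, c, target, src))
                prev = target

    for pair in composite.equivalence_bridges:
        x, y = sorted(pair)
        if obsolete(x) or obsolete(y):
            continue
        src = _src("bridge", x, y)
        axioms.type1.add(Sub(x, y, src))
        axioms.type1.add(Sub(y, x, src))
    return axioms


def subset_axiom_set(axioms: Iterable[Axiom]) -> NormalizedAxiomSet:
    """Re-bundle a bag of normalized axioms (e.g. from an explanation trace)."""
    out = NormalizedAxiomSet()
    for ax in axioms:
        if isinstance(ax, Sub):
            out.type1.add(ax)
        elif isinstance(ax, SubConj):
            out.type2.add(ax)
        elif isinstance(ax, SubEx):
            out.type3.add(ax)
        elif isinstance(ax, ExSub):
            out.type4.add(ax)
        else:
            raise TypeError(f"not a normalized axiom: {ax!r}")
    out.fresh_names = {n for n in out.names() if n.prefix == _FRESH_PREFIX}
    return out


SFact = tuple  # ('S', A, B)
RFact = tuple  # ('R', r, A, B)


@dataclass
class SubsumptionClosure:
    """All entailed named-class subsumptions, restricted to original names.

    ``subsumes[T]`` is the set of entailed superclasses of ``T`` (reflexive
    and transitive); ``equiv_classes`` partitions the names into classes of
    mutually subsuming terms.  Derivation provenance for every fact is kept
    on the side for explanation traces.
    """

    subsumes: dict[TermId, set[TermId]]
    equiv_classes: list[frozenset[TermId]]
    derivations: dict[tuple, tuple] = field(default_factory=dict, repr=False)

    def entails(self, sub: TermId, sup: TermId) -> bool:
        return sup in self.subsumes.get(sub, {sub})


def classify(axioms: NormalizedAxiomSet) -> SubsumptionClosure:
    """Saturate under CR1–CR4; sound and complete for the fragment.

    The least fixpoint is unique, so the result is independent of axiom
    iteration order.  Fresh normalization names are stripped from the
    returned closure.
    """
    names = axioms.names()

    t1_by_sub: dict[TermId, list[Sub]] = {}
    for ax in axioms.type1:
        t1_by_sub.setdefault(ax.sub, []).append(ax)
    t2_by_conj: dict[TermId, list[tuple[TermId, SubConj]]] = {}
    for ax in axioms.type2:
        t2_by_conj.setdefault(ax.left1, []).append((ax.left2, ax))
        if ax.left2 != ax.left1:
            t2_by_conj.setdefault(ax.left2, []).append((ax.left1, ax))
    t3_by_sub: dict[TermId, list[SubEx]] = {}
    for ax in axioms.type3:
        t3_by_sub.setdefault(ax.sub, []).append(ax)
    t4_by_rel_filler: dict[tuple[Relation, TermId], list[ExSub]] = {}
    for ax in axioms.type4:
        t4_by_rel_filler.setdefault((ax.rel, ax.filler), []).append(ax)
    t4_rels = {ax.rel for ax in axioms.type4}

    S: dict[TermId, set[TermId]] = {a: set() for a in names}
    R: dict[Relation, set[tuple[TermId, TermId]]] = {}
    R_by_second: dict[tuple[Relation, TermId], set[TermId]] = {}

    prov: dict[tuple, tuple] = {}
    queue: deque[tuple] = deque()

    def add_S(a: TermId, b: TermId, axiom: Axiom | None, premises: tuple) -> None:
        if b in S.setdefault(a, set()):
            return
        S[a].add(b)
        fact = ("S", a, b)
        prov[fact] = (axiom, premises)
        queue.append(fact)

    def add_R(r: Relation, a: TermId, b: TermId, axiom: Axiom | None, premises: tuple) -> None:
        pairs = R.setdefault(r, set())
        if (a, b) in pairs:
            return
        pairs.add((a, b))
        R_by_second.setdefault((r, b), set()).add(a)
        fact = ("R", r, a, b)
        prov[fact] = (axiom, premises)
        queue.append(fact)

    for a in names:
        add_S(a, a, None, ())

    while queue:
        fact = queue.popleft()
        if fact[0] == "S":
            _, a, b = fact
            for ax in t1_by_sub.get(b, ()):  # CR1
                add_S(a, ax.sup, ax, (fact,))
            for other, ax in t2_by_conj.get(b, ()):  # CR2
                if other in S[a]:
                    add_S(a, ax.sup, ax, (fact, ("S", a, other)))
            for ax in t3_by_sub.get(b, ()):  # CR3
                add_R(ax.rel, a, ax.filler, ax, (fact,))
            # CR4, triggered by the S(B,B') premise: existing R(r, X, B=a) pairs
            for r in t4_rels:
                for ax in t4_by_rel_filler.get((r, b), ()):
                    for x in R_by_second.get((r, a), ()):
                        add_S(x, ax.sup, ax, (("R", r, x, a), fact))
        else:
            _, r, a, b = fact
            for bprime in tuple(S.get(b, ())):  # CR4, triggered by the R premise
                for ax in t4_by_rel_filler.get((r, bprime), ()):
                    add_S(a, ax.sup, ax, (fact, ("S", b, bprime)))

    fresh = axioms.fresh_names
    restricted = {
        a: {b for b in supers if b not in fresh}
        for a, supers in S.items()
        if a not in fresh
    }

    equiv_classes: list[frozenset[TermId]] = []
    seen: set[TermId] = set()
    for a in sorted(restricted):
        if a in seen:
            continue
        cls = frozenset(b for b in restricted[a] if a in restricted.get(b, ()))
        equiv_classes.append(cls)
        seen.update(cls)
    return SubsumptionClosure(restricted, equiv_classes, prov)


@dataclass(frozen=True)
class InferredHierarchy:
    """Direct inferred edges between equivalence-class representatives."""

    direct_edges: frozenset[tuple[TermId, TermId]]
    equivalences: frozenset[frozenset[TermId]]
    representative: Mapping[TermId, TermId] = field(default_factory=dict, compare=False)


def inferred_target_axioms(
    closure: SubsumptionClosure,
    target_prefix: str,
    defined_terms: Iterable[TermId],
) -> InferredHierarchy:
    """Restrict the closure to defined target-prefix terms.

    Equivalence classes are collapsed onto their lowest-sorting member and
    the strict subsumption order between representatives is transitively
    reduced, so ``direct_edges`` is the minimal edge set with the entailed
    reachability — the hierarchy a curator would actually assert.
    """
    relevant = sorted(
        t for t in set(defined_terms)
        if t.prefix == target_prefix and t in closure.subsumes
    )
    relevant_set = set(relevant)

    rep: dict[TermId, TermId] = {}
    classes: list[frozenset[TermId]] = []
    for t in relevant:
        if t in rep:
            continue
        cls = frozenset(
            u for u in closure.subsumes[t]
            if u in relevant_set and t in closure.subsumes.get(u, ())
        )
        r = min(cls)
        for u in cls:
            rep[u] = r
        classes.append(cls)

    dag = nx.DiGraph()
    dag.add_nodes_from(sorted(set(rep.values())))
    for a in dag.nodes:
        for b in closure.subsumes[a]:
            rb = rep.get(b)
            if rb is not None and rb != a:
                dag.add_edge(a, rb)
    reduced = nx.transitive_reduction(dag)
    return InferredHierarchy(
        direct_edges=frozenset(reduced.edges),
        equivalences=frozenset(c for c in classes if len(c) >= 2),
        representative=rep,
    )
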