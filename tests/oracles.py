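"""Independent oracles and random-instance generators for the test suite.

Everything here deliberately avoids the code paths it checks: subsumption
is decided by constructing the least (canonical) model of the axioms and
reading class membership off it — one shared element per named class, the
standard EL canonical-model argument — rather than by completion rules;
cycle detection is a plain three-color DFS; reachability a plain BFS.
"""

from __future__ import annotations

import random
from itertools import count

from xpdiff.composite import CompositeOntology, build_composite
from xpdiff.core_model import LogicalDefinition, OntologyGraph, Relation, TermId
from xpdiff.el_reasoner import ExSub, NormalizedAxiomSet, Sub, SubConj, SubEx


def model_subsumptions(axioms: NormalizedAxiomSet) -> dict[TermId, set[TermId]]:
    """All entailed A ⊑ B over the axiom set's names, by canonical model.

    Domain: one element per named class (tagged by the class).  Interpret
    every axiom as a closure rule on the extension sets until fixpoint;
    A ⊑ B is entailed iff A's canonical element lies in B's extension.
    """
    names = sorted(axioms.names())
    ext: dict[TermId, set[TermId]] = {n: {n} for n in names}
    rel: dict[Relation, set[tuple[TermId, TermId]]] = {}
    changed = True
    while changed:
        changed = False
        for ax in axioms.type1:
            add = ext[ax.sub] - ext[ax.sup]
            if add:
                ext[ax.sup] |= add
                changed = True
        for ax in axioms.type2:
            add = (ext[ax.left1] & ext[ax.left2]) - ext[ax.sup]
            if add:
                ext[ax.sup] |= add
                changed = True
        for ax in axioms.type3:
            pairs = rel.setdefault(ax.rel, set())
            add = {(d, ax.filler) for d in ext[ax.sub]} - pairs
            if add:
                pairs |= add
                changed = True
        for ax in axioms.type4:
            pairs = rel.get(ax.rel, set())
            add = {d for d, e in pairs if e in ext[ax.filler]} - ext[ax.sup]
            if add:
                ext[ax.sup] |= add
                changed = True
    return {a: {b for b in names if a in ext[b]} for a in names}


def composite_subsumptions(comp: CompositeOntology) -> dict[TermId, set[TermId]]:
    """Canonical-model subsumption directly over a composite ontology,
    treating definitions as native equivalences (no normalization step)."""
    graph = comp.graph

    def obsolete(t: TermId) -> bool:
        info = graph.terms.get(t)
        return info is not None and info.obsolete

    names = sorted(t for t in graph.terms if not obsolete(t))
    ext: dict[TermId, set[TermId]] = {n: {n} for n in names}
    rel: dict[Relation, set[tuple[TermId, TermId]]] = {}
    live = set(names)
    changed = True
    while changed:
        changed = False
        for c, p in graph.isa_edges:
            if c in live and p in live and ext[c] - ext[p]:
                ext[p] |= ext[c]
                changed = True
        for s, r, o in graph.rel_edges:
            if s in live and o in live:
                pairs = rel.setdefault(r, set())
                add = {(d, o) for d in ext[s]} - pairs
                if add:
                    pairs |= add
                    changed = True
        for pair in comp.equivalence_bridges:
            x, y = sorted(pair)
            if x in live and y in live and ext[x] != ext[y]:
                ext[x] |= ext[y]
                ext[y] |= ext[x]
                changed = True
        for d in comp.definitions.values():
            if d.defined not in live:
                continue
            # defined ⊑ every conjunct
            for g in d.genera:
                if ext[d.defined] - ext[g]:
                    ext[g] |= ext[d.defined]
                    changed = True
            for r, f in d.differentia:
                pairs = rel.setdefault(r, set())
                add = {(el, f) for el in ext[d.defined]} - pairs
                if add:
                    pairs |= add
                    changed = True
            # conjunction of all conjuncts ⊑ defined
            candidates: set[TermId] | None = None
            for g in d.genera:
                candidates = set(ext[g]) if candidates is None else candidates & ext[g]
            for r, f in d.differentia:
                pairs = rel.get(r, set())
                sat = {el for el, e in pairs if e in ext[f]}
                candidates = sat if candidates is None else candidates & sat
            add = (candidates or set()) - ext[d.defined]
            if add:
                ext[d.defined] |= add
                changed = True
    return {a: {b for b in names if a in ext[b]} for a in names}


def has_cycle(nodes, edges) -> bool:
    """Three-color iterative DFS cycle check on a digraph given as edge pairs."""
    succ: dict = {n: [] for n in nodes}
    for a, b in edges:
        succ.setdefault(a, []).append(b)
        succ.setdefault(b, [])
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in succ}
    for start in succ:
        if color[start] != WHITE:
            continue
        stack = [(start, iter(succ[start]))]
        color[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GREY:
                    return True
                if color[nxt] == WHITE:
                    color[nxt] = GREY
                    stack.append((nxt, iter(succ[nxt])))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return False


def reachable(edges, start) -> set:
    succ: dict = {}
    for a, b in edges:
        succ.setdefault(a, set()).add(b)
    seen, frontier = {start}, [start]
    while frontier:
        node = frontier.pop()
        for nxt in succ.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen


# --------------------------------------------------------------------------
# random instances

def random_axiom_set(rng: random.Random, max_names: int = 40, max_axioms: int = 60) -> NormalizedAxiomSet:
    names = [TermId("C", f"{i:03d}") for i in range(rng.randint(4, max_names))]
    rels = [Relation(f"r{i}") for i in range(rng.randint(1, 5))]
    ax = NormalizedAxiomSet(extra_names=set(names))
    for _ in range(rng.randint(0, max_axioms)):
        a, b, c = (rng.choice(names) for _ in range(3))
        r = rng.choice(rels)
        kind = rng.randrange(4)
        if kind == 0:
            ax.type1.add(Sub(a, b))
        elif kind == 1:
            ax.type2.add(SubConj(a, b, c))
        elif kind == 2:
            ax.type3.add(SubEx(a, r, b))
        else:
            ax.type4.add(ExSub(r, a, b))
    return ax


def random_rank_dag(rng: random.Random, prefix: str, n: int, rels=()) -> OntologyGraph:
    g = OntologyGraph()
    for i in range(1, n + 1):
        g.add_term(TermId(prefix, f"{i:04d}"), f"{prefix} {i}")
    ids = sorted(g.terms)
    for i in range(1, n):
        for _ in range(rng.randint(1, 2)):
            g.add_isa(ids[i], ids[rng.randrange(i)])
    for r in rels:
        for _ in range(rng.randint(0, n // 3)):
            i = rng.randrange(1, n)
            g.add_rel(ids[i], r, ids[rng.randrange(i)])
    return g


def random_composite(rng: random.Random) -> CompositeOntology:
    """A small composite with graphs, definitions, bridges and the odd
    unresolved reference — exercise everything normalize() translates."""
    inheres = Relation("inheres_in")
    towards = Relation("towards")
    ga = random_rank_dag(rng, "AA", rng.randint(4, 9), rels=(inheres,))
    gb = random_rank_dag(rng, "BB", rng.randint(4, 9), rels=(towards,))
    pool = sorted(ga.terms) + sorted(gb.terms)
    defs = []
    for i in range(rng.randint(2, 5)):
        genera = tuple(rng.choice(pool) for _ in range(rng.randint(1, 2)))
        differentia = tuple(
            (rng.choice([inheres, towards]), rng.choice(pool))
            for _ in range(rng.randint(0, 2))
        )
        defs.append(LogicalDefinition(TermId("TT", f"{i:04d}"), genera, differentia))
    if rng.random() < 0.3:  # a dangling reference, resolved as an atomic class
        defs.append(
            LogicalDefinition(
                TermId("TT", "9999"), (TermId("AA", "9998"),), ((inheres, rng.choice(pool)),)
            )
        )
    bridges = set()
    for _ in range(rng.randint(0, 2)):
        bridges.add(frozenset((rng.choice(sorted(ga.terms)), rng.choice(sorted(gb.terms)))))
    return build_composite([ga, gb], defs, bridges)
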