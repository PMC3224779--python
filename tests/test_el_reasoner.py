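import random

import pytest

from conftest import make_graph
from oracles import (
    composite_subsumptions,
    model_subsumptions,
    random_axiom_set,
    random_composite,
    reachable,
)

from xpdiff.composite import build_composite
from xpdiff.core_model import LogicalDefinition, Relation, TermId
from xpdiff.el_reasoner import (
    ExSub,
    NormalizedAxiomSet,
    Sub,
    SubConj,
    SubEx,
    classify,
    inferred_target_axioms,
    normalize,
)
from xpdiff.synthetic import worked_example


def T(s):
    return TermId.parse(s)


def _def_axioms(axset, kind):
    pool = {1: axset.type1, 2: axset.type2, 3: axset.type3, 4: axset.type4}[kind]
    return {ax for ax in pool if ax.source is not None and ax.source.kind == "definition"}


def test_normalization_of_four_conjunct_definition_counts():
    """A genus plus three existential differentia must yield: 1 NF1 + 3 NF3
    axioms for the 'defined under each conjunct' direction, 3 NF4 axioms
    naming the existentials, and a 3-step NF2 conjunction chain back to the
    defined class."""
    corpus = worked_example("hypoglycemia_parse")
    comp = build_composite([], corpus.definitions)
    axset = normalize(comp)
    assert len(_def_axioms(axset, 1)) == 1
    assert len(_def_axioms(axset, 3)) == 3
    assert len(_def_axioms(axset, 4)) == 3
    assert len(_def_axioms(axset, 2)) == 3
    assert len(axset.fresh_names) == 5  # 3 existential names + 2 chain intermediates


def test_single_genus_definition_is_a_plain_equivalence():
    d = LogicalDefinition(T("MP:1"), (T("PATO:1"),))
    axset = normalize(build_composite([], [d]))
    assert {(ax.sub, ax.sup) for ax in axset.type1} == {
        (T("MP:1"), T("PATO:1")),
        (T("PATO:1"), T("MP:1")),
    }
    assert not axset.type2 and not axset.type3 and not axset.type4


def test_normalization_is_deterministic():
    corpus = worked_example("sperm_motility")
    comp = build_composite(corpus.blocks, corpus.definitions)
    a, b = normalize(comp), normalize(comp)
    assert a.type1 == b.type1 and a.type2 == b.type2
    assert a.type3 == b.type3 and a.type4 == b.type4 and a.fresh_names == b.fresh_names


def test_classify_empty_axiom_set_is_reflexive_only():
    axset = NormalizedAxiomSet(extra_names={T("A:1"), T("A:2")})
    closure = classify(axset)
    assert closure.subsumes == {T("A:1"): {T("A:1")}, T("A:2"): {T("A:2")}}


def test_copper_fixture_entails_the_missing_subsumption():
    """Both phenotypes share the quality conjunct; the process-ontology edge
    copper-ion-homeostasis ⊑ ion-homeostasis must propagate to the defined
    terms."""
    corpus = worked_example("copper_homeostasis")
    comp = build_composite(corpus.blocks, corpus.definitions)
    closure = classify(normalize(comp))
    assert closure.entails(T("MP:0003951"), T("MP:0001765"))
    assert not closure.entails(T("MP:0001765"), T("MP:0003951"))


def test_symbol_identical_definitions_share_an_equivalence_class():
    corpus = worked_example("uric_acid_equivalence")
    comp = build_composite(corpus.blocks, corpus.definitions)
    closure = classify(normalize(comp))
    pair = frozenset({T("MP:0009356"), T("MP:0001541")})
    assert pair in {c for c in closure.equiv_classes if len(c) >= 2}


def test_closure_strips_fresh_names_and_is_reflexive_transitive(rng):
    for _ in range(20):
        comp = random_composite(rng)
        axset = normalize(comp)
        closure = classify(axset)
        assert not (set(closure.subsumes) & axset.fresh_names)
        for a, supers in closure.subsumes.items():
            assert a in supers
            assert not (supers & axset.fresh_names)
            for b in supers:
                assert supers >= closure.subsumes[b]  # transitivity


def test_classifier_agrees_with_canonical_model_oracle(rng):
    """Keystone soundness/completeness check on random normalized axiom
    sets (the 200-instance sweep lives in the acceptance suite)."""
    for _ in range(60):
        axset = random_axiom_set(rng)
        got = classify(axset).subsumes
        assert got == model_subsumptions(axset)


def test_normalization_preserves_entailment_on_random_composites(rng):
    """classify∘normalize, restricted to original names, equals a
    canonical-model oracle that consumes the composite directly."""
    for _ in range(30):
        comp = random_composite(rng)
        got = classify(normalize(comp)).subsumes
        assert got == composite_subsumptions(comp)


def test_classification_is_monotone_under_added_axioms(rng):
    for _ in range(15):
        axset = random_axiom_set(rng, max_names=15, max_axioms=25)
        before = classify(axset).subsumes
        names = sorted(axset.names())
        axset.type1.add(Sub(rng.choice(names), rng.choice(names)))
        after = classify(axset).subsumes
        for a, supers in before.items():
            assert supers <= after[a]


def test_classification_is_independent_of_axiom_iteration_order(rng):
    axset = random_axiom_set(rng)
    reference = classify(axset).subsumes
    for _ in range(5):
        shuffled = NormalizedAxiomSet(extra_names=set(axset.extra_names))
        for name, pool in (("type1", axset.type1), ("type2", axset.type2),
                           ("type3", axset.type3), ("type4", axset.type4)):
            items = sorted(pool, key=repr)
            rng.shuffle(items)
            getattr(shuffled, name).update(items)
        assert classify(shuffled).subsumes == reference


# ------------------------------------------------- inferred target axioms

def _closure_of(*subs):
    axset = NormalizedAxiomSet()
    for a, b in subs:
        axset.type1.add(Sub(T(a), T(b)))
    return classify(axset)


def test_chain_reduces_to_direct_edges_only():
    closure = _closure_of(("MP:1", "MP:2"), ("MP:2", "MP:3"))
    inferred = inferred_target_axioms(closure, "MP", {T("MP:1"), T("MP:2"), T("MP:3")})
    assert inferred.direct_edges == {(T("MP:1"), T("MP:2")), (T("MP:2"), T("MP:3"))}
    assert inferred.equivalences == frozenset()


def test_copper_fixture_yields_exactly_one_direct_edge():
    corpus = worked_example("copper_homeostasis")
    comp = build_composite(corpus.blocks, corpus.definitions)
    closure = classify(normalize(comp))
    inferred = inferred_target_axioms(closure, "MP", {d.defined for d in corpus.definitions})
    assert inferred.direct_edges == {(T("MP:0003951"), T("MP:0001765"))}


def test_transitive_reduction_preserves_reachability_on_random_closures(rng):
    """The reduced edge set must reach exactly what the unreduced strict
    subsumption order reaches (independent BFS oracle), and never mention
    a term outside the defined target set or a self-loop."""
    for _ in range(20):
        n = rng.randint(3, 12)
        names = [T(f"MP:{i}") for i in range(n)]
        subs = [(str(rng.choice(names)), str(rng.choice(names))) for _ in range(2 * n)]
        closure = _closure_of(*subs)
        defined = set(names)
        inferred = inferred_target_axioms(closure, "MP", defined)
        reps = set(inferred.representative.values())
        full = {
            (a, b)
            for a in reps
            for b in closure.subsumes[a]
            if b in reps and b != a and inferred.representative[b] == b
        }
        for a, b in inferred.direct_edges:
            assert a != b and a.prefix == "MP" and b.prefix == "MP"
        for a in reps:
            assert (reachable(inferred.direct_edges, a) - {a}) == {b for x, b in full if x == a}
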