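import pytest

from conftest import make_graph
from oracles import reachable

from xpdiff.comparison import compare, trace_explanation
from xpdiff.composite import build_composite
from xpdiff.core_model import TermId
from xpdiff.el_reasoner import classify, inferred_target_axioms, normalize, subset_axiom_set
from xpdiff.pipeline import analyze
from xpdiff.synthetic import CorpusSpec, generate_corpus, worked_example


def T(s):
    return TermId.parse(s)


def run_corpus(corpus, **kw):
    return analyze(corpus.blocks, corpus.definitions, corpus.target, **kw)


def test_inferred_edge_absent_from_target_is_new():
    """Enlarged inguinal lymph nodes ⊑ enlarged lymph nodes is entailed by
    the anatomy but asserted nowhere in the target: category 'new'."""
    corpus = worked_example("inguinal_lymph_node")
    report = run_corpus(corpus).report
    assert report.inferred_new == {(T("MP:0009623"), T("MP:0000702"))}
    assert not report.inferred_found_direct and not report.inferred_found_indirect


def test_asserted_path_of_length_two_is_indirectly_found():
    corpus = worked_example("copper_homeostasis")
    # interpose a middle term so the inferred edge is only reachable via a path
    mid = T("MP:0000005")
    corpus.target.add_term(mid, "intermediate phenotype")
    corpus.target.add_isa(T("MP:0003951"), mid)
    corpus.target.add_isa(mid, T("MP:0001765"))
    report = run_corpus(corpus).report
    edge = (T("MP:0003951"), T("MP:0001765"))
    assert report.inferred_found_indirect == {edge}
    # cross-check with a plain BFS over the asserted edges
    assert T("MP:0001765") in reachable(corpus.target.isa_edges, T("MP:0003951"))


def test_asserted_edge_is_directly_found_when_target_agrees():
    corpus = worked_example("copper_homeostasis")
    corpus.target.add_isa(T("MP:0003951"), T("MP:0001765"))
    report = run_corpus(corpus).report
    edge = (T("MP:0003951"), T("MP:0001765"))
    assert report.inferred_found_direct == {edge}
    assert report.asserted_found == {edge}
    assert not report.inferred_new and not report.asserted_not_found


def test_unsupported_asserted_edge_and_new_edge_in_the_motility_fixture():
    """The target files sperm motility under behavior (not entailed → type-2
    disagreement) while the entailed motility ⊑ locomotion link is absent
    (type-1 disagreement)."""
    corpus = worked_example("sperm_motility")
    report = run_corpus(corpus).report
    assert report.asserted_not_found == {(T("MP:0002674"), T("MP:0004924"))}
    assert report.inferred_new == {(T("MP:0002674"), T("MP:0001392"))}


def test_asserted_edges_with_undefined_endpoints_are_outside_the_comparison():
    corpus = worked_example("copper_homeostasis")
    report = run_corpus(corpus).report
    # both asserted edges point at the undefined root MP:0000001
    assert not report.asserted_found and not report.asserted_not_found


def test_report_partitions_hold_on_random_corpora(rng):
    for seed in range(8):
        corpus = generate_corpus(
            CorpusSpec(n_missing_links=2, n_spurious_links=2, n_duplicate_defs=1, seed=seed)
        )
        result = run_corpus(corpus)
        r = result.report
        inferred = set(result.inferred.direct_edges)
        parts = [r.inferred_found_direct, r.inferred_found_indirect, r.inferred_new]
        assert parts[0] | parts[1] | parts[2] == inferred
        assert sum(map(len, parts)) == len(inferred)  # pairwise disjoint
        assert not (r.asserted_found & r.asserted_not_found)
        defined = {d.defined for d in corpus.definitions}
        comparable = {
            e for e in corpus.target.isa_edges if e[0] in defined and e[1] in defined
        }
        assert r.asserted_found | r.asserted_not_found == comparable
        # the overlap is the same set seen from either direction
        entailed_asserted = {e for e in comparable if result.closure.entails(*e)}
        assert r.asserted_found == entailed_asserted


def test_clean_corpus_reports_no_disagreements():
    corpus = generate_corpus(CorpusSpec(seed=5))
    r = run_corpus(corpus).report
    assert not r.inferred_new and not r.asserted_not_found and not r.equivalence_classes


def test_compare_is_pure_and_input_order_insensitive():
    corpus = worked_example("sperm_motility")
    result = run_corpus(corpus)
    defined = [d.defined for d in corpus.definitions]
    a = compare(result.inferred, result.closure, corpus.target, defined,
                definitions={d.defined: d for d in corpus.definitions})
    b = compare(result.inferred, result.closure, corpus.target, list(reversed(defined)),
                definitions={d.defined: d for d in reversed(corpus.definitions)})
    for field in ("inferred_found_direct", "inferred_found_indirect", "inferred_new",
                  "asserted_found", "asserted_not_found", "equivalence_classes"):
        assert getattr(a, field) == getattr(b, field)


# ---------------------------------------------------------------- traces

def test_trace_cites_the_building_block_edge_behind_the_inference():
    corpus = worked_example("copper_homeostasis")
    result = run_corpus(corpus)
    trace = trace_explanation(
        (T("MP:0003951"), T("MP:0001765")), result.closure,
        {d.defined: d for d in corpus.definitions},
    )
    assert (T("GO:0006878"), T("GO:0050801")) in trace.isa_edges
    assert {d.defined for d in trace.definitions} == {T("MP:0003951"), T("MP:0001765")}


def test_trace_notes_syntactically_identical_definitions():
    corpus = worked_example("uric_acid_equivalence")
    result = run_corpus(corpus)
    trace = trace_explanation(
        (T("MP:0001541"), T("MP:0009356")), result.closure,
        {d.defined: d for d in corpus.definitions},
    )
    assert trace.note == "definitions syntactically identical"


def test_trace_lookup_error_for_underived_edge():
    corpus = worked_example("copper_homeostasis")
    result = run_corpus(corpus)
    with pytest.raises(LookupError):
        trace_explanation((T("MP:0001765"), T("MP:0003951")), result.closure)


def test_replaying_only_traced_axioms_rederives_the_edge(rng):
    """Sufficiency of explanations: classifying just the axioms named in a
    trace must re-derive the explained edge."""
    for seed in range(5):
        corpus = generate_corpus(
            CorpusSpec(n_missing_links=2, n_duplicate_defs=1, seed=100 + seed)
        )
        result = run_corpus(corpus)
        for edge, trace in sorted(result.report.explanations.items())[:10]:
            replay = classify(subset_axiom_set(trace.axioms))
            assert replay.entails(*edge)
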