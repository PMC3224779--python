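import random

import pytest

from xpdiff.core_model import OntologyGraph, Relation, TermId


@pytest.fixture
def rng():
    return random.Random(20110418)


def make_graph(terms: dict[str, str], isa=(), rels=(), obsolete=(), xrefs=()):
    """Terse graph builder: string CURIEs in, OntologyGraph out."""
    g = OntologyGraph()
    for tid, label in terms.items():
        g.add_term(TermId.parse(tid), label, obsolete=tid in set(obsolete))
    for c, p in isa:
        g.add_isa(TermId.parse(c), TermId.parse(p))
    for s, r, o in rels:
        g.add_rel(TermId.parse(s), Relation(r), TermId.parse(o))
    for t, x in xrefs:
        g.terms[TermId.parse(t)].xrefs.add(TermId.parse(x))
    return g


def random_ontology(rng: random.Random, prefix: str = "RR", n: int | None = None) -> OntologyGraph:
    """Random valid ontology: rank DAG + xrefs + one isolated obsolete term."""
    from oracles import random_rank_dag

    n = n or rng.randint(3, 12)
    g = random_rank_dag(rng, prefix, n, rels=(Relation("part_of"),))
    ids = sorted(g.terms)
    for _ in range(rng.randint(0, 3)):
        g.terms[rng.choice(ids)].xrefs.add(TermId("XX", f"{rng.randint(1, 99):04d}"))
    if rng.random() < 0.5:
        g.add_term(TermId(prefix, "9000"), "retired term", obsolete=True)
    return g
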