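"""Deterministic synthetic corpora with planted, known disagreements.

A corpus emulates the entity–quality validation setting: several randomly
generated building-block ontologies (one quality ontology in the role PATO
plays, plus entity ontologies in the role of GO/MA/ChEBI), cross-product
definitions of target phenotype terms (one quality genus, one
``inheres_in`` filler), and a target ontology whose asserted hierarchy is
the true entailed hierarchy *after* three kinds of planted damage:

* deleted asserted edges  → must resurface as *new* inferred axioms,
* inserted non-entailed edges → must be reported as *asserted not found*,
* duplicated definitions under fresh ids → must form equivalence classes.

Ground truth is recomputed after planting from plain graph reachability
over the building blocks (an independent code path from the EL reasoner),
so recovery checks can demand exact equality.  Everything is a pure
function of the spec, including its seed.

Also here: hand-built miniature corpora reproducing classic curation
findings on mammalian-phenotype definitions (copper homeostasis, inguinal
lymph nodes, a blood/urine filler mix-up, sperm motility vs locomotion),
used as golden end-to-end fixtures.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .core_model import LogicalDefinition, OntologyGraph, Relation, TermId
from .obo_io import parse_obo, write_obo

__all__ = [
    "CorpusSpec",
    "GroundTruth",
    "Corpus",
    "GenerationError",
    "generate_corpus",
    "worked_example",
    "write_corpus",
    "WORKED_EXAMPLES",
]

QUALITY_PREFIX = "QL"
TARGET_PREFIX = "TG"
INHERES_IN = Relation("inheres_in")
PART_OF = Relation("part_of")

Edge = tuple[TermId, TermId]


class GenerationError(RuntimeError):
    """The requested corpus cannot be planted (e.g. no deletable edge left)."""


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    ``n_blocks`` counts entity building blocks; a quality ontology is always
    generated in addition.  ``dag_density`` is the expected number of
    parents per non-root term (1 ⇒ tree, up to 2).  The planted counts map
    one-to-one onto the three disagreement categories of the report.
    """

    n_blocks: int = 3
    terms_per_block: int = 20
    dag_density: float = 1.3
    n_defined: int = 30
    n_missing_links: int = 0
    n_spurious_links: int = 0
    n_duplicate_defs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_blocks, self.terms_per_block, self.n_defined,
            self.n_missing_links, self.n_spurious_links, self.n_duplicate_defs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("corpus spec counts must be non-negative")
        if self.n_defined < 2 * self.n_duplicate_defs:
            raise ValueError("need n_defined >= 2 * n_duplicate_defs")
        if not 1.0 <= self.dag_density <= 2.0:
            raise ValueError("dag_density must be in [1, 2]")


@dataclass
class GroundTruth:
    """Exactly what the comparison report must say about a planted corpus."""

    expected_new: set[Edge] = field(default_factory=set)
    expected_not_found: set[Edge] = field(default_factory=set)
    expected_equivalences: set[frozenset[TermId]] = field(default_factory=set)


@dataclass
class Corpus:
    blocks: list[OntologyGraph]
    definitions: list[LogicalDefinition]
    target: OntologyGraph
    truth: GroundTruth


def _tid(prefix: str, i: int) -> TermId:
    return TermId(prefix, f"{i:07d}")


def _random_dag(prefix: str, n_terms: int, density: float, rng: random.Random) -> OntologyGraph:
    """Rooted random DAG via rank-ordered parent sampling: term i may only
    point at earlier terms, so acyclicity holds by construction."""
    g = OntologyGraph()
    for i in range(1, n_terms + 1):
        g.add_term(_tid(prefix, i), f"{prefix} term {i}")
    for i in range(2, n_terms + 1):
        child = _tid(prefix, i)
        g.add_isa(child, _tid(prefix, rng.randrange(1, i)))
        if i >= 3 and rng.random() < density - 1.0:
            second = rng.randrange(1, i)
            if _tid(prefix, second) != next(iter(p for c, p in g.isa_edges if c == child)):
                g.add_isa(child, _tid(prefix, second))
        if i >= 3 and rng.random() < 0.15:  # decorative partonomy
            g.add_rel(child, PART_OF, _tid(prefix, rng.randrange(1, i)))
    return g


def _ancestor_map(graph: OntologyGraph) -> dict[TermId, set[TermId]]:
    """Reflexive-transitive is_a ancestors, by plain reachability."""
    g = graph.isa_digraph()
    return {t: {t} | nx.descendants(g, t) for t in g.nodes}


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Build blocks, definitions, damaged target and exact ground truth."""
    rng = random.Random(spec.seed)

    # a compact quality ontology: EQ definitions reuse a handful of core
    # qualities over many entities, which is what makes hierarchies entailed
    quality = _random_dag(QUALITY_PREFIX, 6, spec.dag_density, rng)
    entities = [
        _random_dag(f"E{b}", spec.terms_per_block, spec.dag_density, rng)
        for b in range(spec.n_blocks)
    ]
    blocks = [quality] + entities
    anc: dict[TermId, set[TermId]] = {}
    for block in blocks:
        anc.update(_ancestor_map(block))

    if spec.n_defined and not entities:
        raise GenerationError("cannot define terms without entity blocks")

    quality_terms = sorted(quality.terms)
    combos: set[tuple[TermId, TermId]] = set()
    definitions: list[LogicalDefinition] = []
    for i in range(spec.n_defined):
        for _ in range(200):
            q = rng.choice(quality_terms)
            e = rng.choice(sorted(rng.choice(entities).terms))
            if (q, e) not in combos:
                combos.add((q, e))
                break
        else:
            raise GenerationError("cannot sample distinct definition conjuncts")
        definitions.append(LogicalDefinition(_tid(TARGET_PREFIX, i + 1), (q,), ((INHERES_IN, e),)))

    dup_sources = rng.sample(definitions, spec.n_duplicate_defs)
    duplicates = [
        LogicalDefinition(_tid(TARGET_PREFIX, spec.n_defined + k + 1), d.genera, d.differentia)
        for k, d in enumerate(dup_sources)
    ]
    all_defs = definitions + duplicates
    body = {d.defined: (d.genera[0], d.differentia[0][1]) for d in all_defs}

    def entailed(a: TermId, b: TermId) -> bool:
        qa, fa = body[a]
        qb, fb = body[b]
        return qb in anc[qa] and fb in anc[fa]

    by_sig: dict[tuple, list[TermId]] = {}
    for d in all_defs:
        by_sig.setdefault(d.signature(), []).append(d.defined)
    classes = [sorted(members) for members in by_sig.values()]
    rep = {m: cls[0] for cls in classes for m in cls}

    rep_dag = nx.DiGraph()
    rep_dag.add_nodes_from(sorted(set(rep.values())))
    for a in rep_dag.nodes:
        for b in rep_dag.nodes:
            if a != b and entailed(a, b):
                rep_dag.add_edge(a, b)
    true_direct = set(nx.transitive_reduction(rep_dag).edges)

    asserted = nx.DiGraph()
    asserted.add_nodes_from(body)
    asserted.add_edges_from(true_direct)

    deleted: list[Edge] = []
    candidates = sorted(true_direct)
    rng.shuffle(candidates)
    for a, b in candidates:
        if len(deleted) == spec.n_missing_links:
            break
        asserted.remove_edge(a, b)
        if nx.has_path(asserted, a, b):
            asserted.add_edge(a, b)  # alternative route exists; not cleanly missing
        else:
            deleted.append((a, b))
    if len(deleted) < spec.n_missing_links:
        raise GenerationError(
            f"only {len(deleted)} of {spec.n_missing_links} edges can be deleted without leaving a bypass"
        )

    nodes = sorted(body)
    if spec.n_spurious_links and len(nodes) < 2:
        raise GenerationError("need at least two defined terms to plant a spurious edge")
    spurious: list[Edge] = []
    for _ in range(500 * max(1, spec.n_spurious_links)):
        if len(spurious) == spec.n_spurious_links:
            break
        a, b = rng.sample(nodes, 2)
        if entailed(a, b) or asserted.has_edge(a, b) or nx.has_path(asserted, b, a):
            continue
        asserted.add_edge(a, b)
        spurious.append((a, b))
    if len(spurious) < spec.n_spurious_links:
        raise GenerationError("cannot plant the requested number of acyclic spurious edges")

    target = OntologyGraph()
    for t in nodes:
        target.add_term(t, f"synthetic phenotype {int(t.local)}")
    for a, b in asserted.edges:
        target.add_isa(a, b)

    truth = GroundTruth(
        expected_not_found={(a, b) for a, b in asserted.edges if not entailed(a, b)},
        expected_equivalences={frozenset(c) for c in classes if len(c) >= 2},
    )
    for a, b in true_direct:
        if not asserted.has_edge(a, b) and not nx.has_path(asserted, a, b):
            truth.expected_new.add((a, b))

    return Corpus(blocks, all_defs, target, truth)


def write_corpus(corpus: Corpus, outdir: str | Path) -> dict[str, object]:
    """Serialize a corpus as standard OBO files (one per building block,
    one definition file, one target ontology); returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block_paths = []
    for block in corpus.blocks:
        path = outdir / f"{block.dominant_prefix()}.obo"
        path.write_text(write_obo(block))
        block_paths.append(path)

    def_graph = OntologyGraph()
    for d in corpus.definitions:
        def_graph.add_term(d.defined, corpus.target.label(d.defined))
    def_path = outdir / "definitions.obo"
    def_path.write_text(write_obo(def_graph, corpus.definitions))

    target_path = outdir / "target.obo"
    target_path.write_text(write_obo(corpus.target))
    return {"blocks": block_paths, "definitions": def_path, "target": target_path}


# --------------------------------------------------------------------------
# hand-built golden corpora

HYPOGLYCEMIA_OBO = """\
format-version: 1.2

[Term]
id: HP:0001943
name: Hypoglycemia
intersection_of: PATO:0001163 ! decreased concentration
intersection_of: qualifier PATO:0000460 ! abnormal
intersection_of: towards CHEBI:17234 ! glucose
intersection_of: inheres_in FMA:9670 ! Portion of blood
"""


def _graph(terms: dict[str, str], isa: list[tuple[str, str]]) -> OntologyGraph:
    g = OntologyGraph()
    for tid, label in terms.items():
        g.add_term(TermId.parse(tid), label)
    for c, p in isa:
        g.add_isa(TermId.parse(c), TermId.parse(p))
    return g


def _eq(defined: str, genera: list[str], differentia: list[tuple[str, str]]) -> LogicalDefinition:
    return LogicalDefinition(
        TermId.parse(defined),
        tuple(TermId.parse(g) for g in genera),
        tuple((Relation(r), TermId.parse(f)) for r, f in differentia),
    )


def _copper_homeostasis() -> Corpus:
    go = _graph(
        {
            "GO:0065008": "regulation of biological quality",
            "GO:0050801": "ion homeostasis",
            "GO:0006878": "copper ion homeostasis",
        },
        [("GO:0050801", "GO:0065008"), ("GO:0006878", "GO:0050801")],
    )
    pato = _graph(
        {"PATO:0000001": "quality", "PATO:0000460": "abnormal"},
        [("PATO:0000460", "PATO:0000001")],
    )
    defs = [
        _eq("MP:0003951", ["PATO:0000460"], [("inheres_in", "GO:0006878")]),
        _eq("MP:0001765", ["PATO:0000460"], [("inheres_in", "GO:0050801")]),
    ]
    target = _graph(
        {
            "MP:0000001": "mammalian phenotype",
            "MP:0003951": "abnormal copper homeostasis",
            "MP:0001765": "abnormal ion homeostasis",
        },
        [("MP:0003951", "MP:0000001"), ("MP:0001765", "MP:0000001")],
    )
    truth = GroundTruth(expected_new={(TermId("MP", "0003951"), TermId("MP", "0001765"))})
    return Corpus([go, pato], defs, target, truth)


def _inguinal_lymph_node() -> Corpus:
    ma = _graph(
        {
            "MA:0000003": "organ",
            "MA:0000139": "lymph node",
            "MA:0002560": "inguinal lymph node",
        },
        [("MA:0000139", "MA:0000003"), ("MA:0002560", "MA:0000139")],
    )
    pato = _graph(
        {"PATO:0000001": "quality", "PATO:0000586": "increased size"},
        [("PATO:0000586", "PATO:0000001")],
    )
    defs = [
        _eq("MP:0009623", ["PATO:0000586"], [("inheres_in", "MA:0002560")]),
        _eq("MP:0000702", ["PATO:0000586"], [("inheres_in", "MA:0000139")]),
    ]
    target = _graph(
        {
            "MP:0009623": "enlarged inguinal lymph nodes",
            "MP:0000702": "enlarged lymph nodes",
        },
        [],
    )
    truth = GroundTruth(expected_new={(TermId("MP", "0009623"), TermId("MP", "0000702"))})
    return Corpus([ma, pato], defs, target, truth)


def _uric_acid_equivalence() -> Corpus:
    ma = _graph(
        {"MA:0002450": "body fluid", "MA:0000059": "blood", "MA:0002405": "urine"},
        [("MA:0000059", "MA:0002450"), ("MA:0002405", "MA:0002450")],
    )
    pato = _graph(
        {"PATO:0000001": "quality", "PATO:0000460": "abnormal"},
        [("PATO:0000460", "PATO:0000001")],
    )
    # the urine term was (erroneously) defined with the blood filler too
    defs = [
        _eq("MP:0009356", ["PATO:0000460"], [("inheres_in", "MA:0000059")]),
        _eq("MP:0001541", ["PATO:0000460"], [("inheres_in", "MA:0000059")]),
    ]
    target = _graph(
        {
            "MP:0009356": "abnormal urine uric acid level",
            "MP:0001541": "abnormal blood uric acid level",
        },
        [],
    )
    truth = GroundTruth(
        expected_equivalences={frozenset({TermId("MP", "0009356"), TermId("MP", "0001541")})}
    )
    return Corpus([ma, pato], defs, target, truth)


def _sperm_motility() -> Corpus:
    go = _graph(
        {
            "GO:0040011": "locomotion",
            "GO:0030317": "sperm motility",
            "GO:0007610": "behavior",
        },
        [("GO:0030317", "GO:0040011")],
    )
    pato = _graph(
        {"PATO:0000001": "quality", "PATO:0000460": "abnormal"},
        [("PATO:0000460", "PATO:0000001")],
    )
    defs = [
        _eq("MP:0002674", ["PATO:0000001"],
            [("qualifier", "PATO:0000460"), ("inheres_in", "GO:0030317")]),
        _eq("MP:0001392", ["PATO:0000001"],
            [("qualifier", "PATO:0000460"), ("inheres_in", "GO:0040011")]),
        _eq("MP:0004924", ["PATO:0000001"],
            [("qualifier", "PATO:0000460"), ("inheres_in", "GO:0007610")]),
    ]
    # the target files sperm motility under behavior, which the definitions
    # do not entail, and omits the entailed motility/locomotion link
    target = _graph(
        {
            "MP:0002674": "abnormal sperm motility",
            "MP:0001392": "abnormal locomotor activity",
            "MP:0004924": "abnormal behavior",
        },
        [("MP:0002674", "MP:0004924")],
    )
    truth = GroundTruth(
        expected_new={(TermId("MP", "0002674"), TermId("MP", "0001392"))},
        expected_not_found={(TermId("MP", "0002674"), TermId("MP", "0004924"))},
    )
    return Corpus([go, pato], defs, target, truth)


def _hypoglycemia_parse() -> Corpus:
    pato = _graph(
        {
            "PATO:0000001": "quality",
            "PATO:0001163": "decreased concentration",
            "PATO:0000460": "abnormal",
        },
        [("PATO:0001163", "PATO:0000001"), ("PATO:0000460", "PATO:0000001")],
    )
    chebi = _graph({"CHEBI:17234": "glucose"}, [])
    fma = _graph({"FMA:9670": "Portion of blood"}, [])
    _, doc = parse_obo(io.StringIO(HYPOGLYCEMIA_OBO))
    target = _graph({"HP:0001943": "Hypoglycemia"}, [])
    return Corpus([pato, chebi, fma], doc.definitions, target, GroundTruth())


WORKED_EXAMPLES = {
    "copper_homeostasis": _copper_homeostasis,
    "inguinal_lymph_node": _inguinal_lymph_node,
    "uric_acid_equivalence": _uric_acid_equivalence,
    "sperm_motility": _sperm_motility,
    "hypoglycemia_parse": _hypoglycemia_parse,
}


def worked_example(name: str) -> Corpus:
    """A hand-built miniature corpus with its expected report, by name."""
    try:
        builder = WORKED_EXAMPLES[name]
    except KeyError:
        raise LookupError(
            f"unknown worked example {name!r}; choose from {sorted(WORKED_EXAMPLES)}"
        ) from None
    return builder()
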