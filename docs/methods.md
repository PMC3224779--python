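# Methods

## The model

A *cross-product logical definition* declares a target term equivalent to
an EL concept: `D ≡ G₁ ⊓ … ⊓ Gₘ ⊓ ∃r₁.F₁ ⊓ … ⊓ ∃rₖ.Fₖ` with named genus
classes `Gᵢ` (typically qualities) and existential differentia over object
properties such as `inheres_in`, `towards`, `qualifier`. Together with the
asserted `is_a` hierarchies of the building-block ontologies (and optional
equivalence bridges), this stays inside the EL description logic: named
classes, conjunction, existential restriction, subclass and equivalence
axioms. EL has two properties this tool leans on: classification is
polynomial, and without negation or disjointness the ontology can never be
inconsistent — every run produces a hierarchy, never a contradiction.

`is_a` is structural subsumption, not an object property. Relationship
edges `S r O` in building blocks are read existentially (`S ⊑ ∃r.O`), the
standard OBO-to-OWL interpretation; this reading is switchable off because
its effect on target inferences depends on whether any definition
quantifies over the relation.

## Classification

Normalization maps the composite to four normal forms (NF1 `A⊑B`, NF2
`A⊓B⊑C`, NF3 `A⊑∃r.B`, NF4 `∃r.A⊑B`). Each definition contributes both
directions of its equivalence: `D` under every conjunct (NF1/NF3), and the
converse encoded with fresh names — one NF4 axiom `∃rᵢ.Fᵢ ⊑ Nᵢ` per
differentia, then a left-associated NF2 chain over `G₁…Gₘ,N₁…Nₖ` ending in
`⊑ D`. A single-genus definition with no differentia degenerates to a
plain mutual-subclass pair. Fresh names are sha1-derived from the defined
term and conjunct, so normalization is a pure function of its input.

Saturation applies the EL completion rules (CR1 transitivity, CR2
conjunction introduction, CR3 existential propagation, CR4 existential
elimination) with a worklist until fixpoint. The fixpoint is unique, so
results do not depend on iteration order; the engine is sound and complete
for this fragment. The test suite checks exactly that against an
*independent* oracle: the least (canonical) model with one shared element
per named class is materialized by semantic rule application, and `A ⊑ B`
is read off as membership of A's canonical element in B's extension. Both
code paths are exercised on hundreds of random axiom sets and random
composites, over all ordered class pairs. Every derived fact records its
rule premises, so an inferred edge can be explained by the definitions,
building-block edges and bridges that drove it; replaying classification on
just the traced axioms re-derives the edge (traces are sufficient, not
guaranteed minimal).

Role hierarchies, role chains, inverse roles and nominals are deliberately
out of the fragment: the genus/differentia pattern does not use them.
External OWL reasoners can be plugged in behind the `-r` backend switch,
but the internal engine is the reference implementation and the only
bundled backend.

## Subset extraction

Only terms referenced by the definitions, their ancestors, and edges among
them can affect target-term inferences, so each building block is reduced
to its *induced ancestral graph*: seeds = referenced terms (plus bridge
endpoints), upward closure along `is_a` to all roots, all `is_a` and
relationship edges between retained terms carried over. Upward closure can
additionally follow configured relations (e.g. `part_of`) for ontologies
where such paths matter; this is configuration, not default, because
closure along `is_a` already preserves every subsumption the definitions
can exploit when definitions only quantify over retained-term relations.
The invariance is enforced empirically at the byte level: with and without
extraction, the five report files must be identical on every tested corpus.

Seeds missing from a supplied ontology are skipped with a warning finding
and later behave as fresh atomic classes (they subsume only themselves), so
a stale reference suppresses inferences instead of fabricating them or
aborting the run.

## Comparison semantics

Inferred axioms are computed between equivalence-class representatives
(lowest-sorting member) as the transitive reduction of the strict entailed
order — the edges a curator would actually assert. Each inferred direct
edge is *directly found* (asserted), *indirectly found* (asserted path,
necessarily length ≥ 2 — the only reading under which "directly found"
means edge membership), or *new*. In the opposite direction an asserted
edge between two defined terms is *found* iff the closure entails it —
entailment, not direct-edge membership, which makes the found/overlap count
symmetric between the two directions. Asserted edges with an undefined or
obsolete endpoint are outside the comparison and counted in the log.
Equivalence classes of size ≥ 2 are reported once, members sorted.

## Structural policies

* **Obsolete terms** are retained in the model (so findings can name them)
  but excluded from reasoning and comparison. How the original tooling in
  this area treated obsolete references is generally unspecified; exclusion
  is the conservative choice — an obsolete class should neither give nor
  receive inferences.
* **`is_a` cycles** abort the pipeline with a structural error: arbitrary
  cycle-breaking would silently corrupt ancestral closure.
* **Duplicate `[Term]` stanzas** resolve last-writer-wins with a warning;
  conflicting definitions for one term across files are an error.
* **Bridges** are kept as explicit equivalence pairs consumed by the
  reasoner rather than rewritten into the graph, so reports can attribute
  an inference to bridging. Both bridge sources (cross-references, and
  cross-prefix subclass edges into the bridging ontology) are supported and
  individually switchable; one neutral class cross-referenced to two
  classes of the same prefix yields both pairs, and the resulting
  intra-prefix equivalence is surfaced for a curator rather than filtered.
* **Determinism**: all outputs are sorted (stanzas by id, report lines by
  child then parent, equivalence classes by members); serialization has no
  timestamps; re-running an unchanged configuration is byte-identical.

## The synthetic corpus generator

A generated corpus emulates the entity–quality validation setting: one
compact quality ontology (6 terms — mirroring how phenotype definitions
reuse a handful of core qualities over many entities) and 3 entity
ontologies of 20 terms, built as rooted random DAGs by rank-ordered parent
sampling (≈1.3 parents per term; acyclic by construction), decorated with
occasional `part_of` edges. 30 target terms get unique
quality-plus-`inheres_in`-filler definitions; the target hierarchy is the
transitive reduction of the true entailed order. Damage is then planted:
3 deleted direct edges (chosen so no asserted bypass remains), 2 inserted
non-entailed acyclic edges, 1 definition duplicated under a fresh id with
no asserted placement. Ground truth is recomputed *after* planting from
plain `networkx` reachability over the blocks — a code path independent of
the reasoner — so recovery tests demand exact set equality, even when one
planted change shifts another edge between the direct/indirect/new
categories. Infeasible plants (no cleanly deletable edge left, no acyclic
non-entailed pair found within bounded retries) raise a generation error
rather than degrading silently.

What the generator does **not** emulate: the scale (10⁴–10⁵ classes),
multi-relation definitions per term, inter-ontology references inside
building blocks, xref bridges, label noise, and the skewed topologies of
real ontologies. Passing the recovery and invariance suites therefore
demonstrates correctness of the machinery on the pattern's logic, not
performance or report quality on any particular real release; counts on
real ontologies depend entirely on the release snapshots used.

## Problem sizes

The oracle-agreement sweep uses 200 random axiom sets of ≤ 40 names and
≤ 60 axioms over ≤ 5 relations — large enough that every completion rule
fires in combination, small enough that the quadratic canonical-model
oracle stays instant. Recovery uses 20 corpora at the default conditions
above; subset invariance 50 corpora. These sizes were chosen as the point
where adding instances stopped changing coverage, and the whole suite runs
in seconds.

## Known limitations

* No OWL/RDF serialization; the composite is written back as OBO, with
  equivalence semantics living in the reasoner.
* OBO support covers the tag subset the pattern needs (`id`, `name`,
  `is_a`, `relationship`, `intersection_of`, `xref`, `is_obsolete`);
  clause qualifiers and other metadata are ignored with a log message.
* Explanation traces are sufficient sets of source axioms, not minimized
  justifications.
* The tool reports disagreements; it never repairs either ontology —
  whether the target, the building block or the definition is wrong is a
  curator's judgment.
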