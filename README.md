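# xpdiff

**Validate logically-defined ontologies by automated reasoning.**

Biomedical ontologies such as the Mammalian Phenotype Ontology increasingly
carry *cross-product logical definitions*: a term like *Hypoglycemia* is
declared equivalent to an intersection of building-block classes,

```
HP:0001943  ≡  PATO:0001163 ('decreased concentration')
              ⊓ ∃ qualifier.PATO:0000460 ('abnormal')
              ⊓ ∃ towards.CHEBI:17234 ('glucose')
              ⊓ ∃ inheres_in.FMA:9670 ('portion of blood')
```

If the definitions are right, the manually asserted `is_a` hierarchy of the
target ontology should follow logically from the hierarchies of the
referenced building blocks (GO, PATO, anatomy and chemical ontologies, …).
`xpdiff` checks this: it classifies the combined ontology with an EL
subsumption reasoner and reports every disagreement, giving curators a
prioritized worklist. Three kinds of disagreement are detected:

1. a subclass link **implied** by the definitions but **not asserted** in
   the target ontology (`inf_ax_not_found.txt`),
2. a subclass link **asserted** but **not implied**
   (`assert_ax_not_found.txt`),
3. two target terms whose definitions make them **equivalent**
   (`equivalence_ax.txt`) — usually a duplicated or erroneous definition.

Because only the referenced terms and their ancestors can influence the
result, `xpdiff` reasons over the *induced ancestral graph* of each
building block — the referenced terms plus all ancestors on all paths to
the root, with all relationships among the retained terms — which provably
leaves the reports byte-identical while keeping the composite small.
Equivalence bridges between species-specific and species-neutral anatomy
classes can be generated from cross-references (`--bridge`).

The reasoner is an internal implementation of the standard EL completion
calculus (normal forms `A⊑B`, `A⊓B⊑C`, `A⊑∃r.B`, `∃r.A⊑B`; saturation
rules CR1–CR4), which is sound and complete for everything the
genus/differentia pattern can express and cannot run into inconsistency.
Its output is cross-checked in the test suite against an independent
canonical-model oracle.

## Worked example

The package ships miniature corpora reproducing classic curation findings.
Writing the copper-homeostasis corpus to disk and running the tool:

```python
from xpdiff.synthetic import worked_example, write_corpus
paths = write_corpus(worked_example("copper_homeostasis"), "corpus/")
```

```
$ xpdiff corpus/definitions.obo -e corpus/GO.obo -e corpus/PATO.obo \
         -t corpus/target.obo -o out/
```

`out/inf_ax_not_found.txt` then contains:

```
child_id	child_label	parent_id	parent_label
MP:0003951	abnormal copper homeostasis	MP:0001765	abnormal ion homeostasis
    def MP:0003951 = PATO:0000460 and inheres_in some GO:0006878
    def MP:0001765 = PATO:0000460 and inheres_in some GO:0050801
```

Read: because *copper ion homeostasis* (GO:0006878) is a descendant of
*ion homeostasis* (GO:0050801) in the process ontology, and both phenotype
definitions share the quality conjunct, *abnormal copper homeostasis* must
be a subclass of *abnormal ion homeostasis* — but the target ontology does
not say so. The definitions of both terms are printed under the axiom as
the debugging hint. `out/run_summary.yaml` records the category counts and
the per-ontology subset sizes; `composite.obo` and `reasoned.obo` hold the
ontology given to the reasoner and the inferred target hierarchy.

The library surface mirrors the pipeline: `parse_obo` →
`induced_ancestral_graph` → `build_composite` → `normalize` / `classify` →
`inferred_target_axioms` → `compare` → `write_reports`, all importable from
`xpdiff`. The `xpdiff.synthetic` module generates full random corpora with
*planted* disagreements and exact ground truth, which is how the pipeline
is validated end to end.

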