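"""In-memory end-to-end pipeline: subsets → composite → classification → diff.

The command-line front end parses files and delegates here; tests and the
synthetic-corpus recovery checks call :func:`analyze` directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .comparison import ComparisonReport, compare
from .composite import BridgePair, CompositeOntology, build_composite
from .core_model import Finding, LogicalDefinition, OntologyGraph, Relation, TermId, validate
from .el_reasoner import InferredHierarchy, SubsumptionClosure, classify, inferred_target_axioms, normalize
from .extraction import SubsetSpec, induced_ancestral_graph, referenced_terms

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "StructuralError", "analyze"]


class StructuralError(RuntimeError):
    """An is_a cycle or similar defect that makes reasoning meaningless."""

    def __init__(self, findings: Sequence[Finding]):
        self.findings = list(findings)
        super().__init__("; ".join(f.message for f in findings))


@dataclass
class PipelineResult:
    report: ComparisonReport
    composite: CompositeOntology
    closure: SubsumptionClosure
    inferred: InferredHierarchy
    reasoned: OntologyGraph
    subset_sizes: dict[str, tuple[int, int]]  # prefix -> (subset terms, full terms)
    findings: list[Finding]


def _check_structure(graph: OntologyGraph, what: str) -> list[Finding]:
    findings = validate(graph)
    cycles = [f for f in findings if f.kind == "isa_cycle"]
    if cycles:
        raise StructuralError(
            [Finding(f.kind, f"{what}: {f.message}", f.terms) for f in cycles]
        )
    return findings


def analyze(
    blocks: Sequence[OntologyGraph],
    definitions: Sequence[LogicalDefinition],
    target: OntologyGraph,
    *,
    bridges: Iterable[BridgePair] = (),
    full_import: bool = False,
    closure_relations: Iterable[Relation] = (),
    target_prefix: str | None = None,
    include_rel_edges: bool = True,
) -> PipelineResult:
    """Run the whole evaluation and return the comparison report.

    ``full_import`` skips subset extraction and reasons over the complete
    building blocks; by the ancestral-closure argument the report is
    identical either way, only resource use differs.  ``target_prefix``
    defaults to the most common prefix among the defined terms.
    """
    findings: list[Finding] = []
    for i, block in enumerate(blocks):
        findings.extend(_check_structure(block, f"building block {i}"))
    findings.extend(_check_structure(target, "target ontology"))

    defined_terms = {d.defined for d in definitions}
    if target_prefix is None:
        if not defined_terms:
            target_prefix = target.dominant_prefix() if target.terms else ""
        else:
            counts: dict[str, int] = {}
            for t in defined_terms:
                counts[t.prefix] = counts.get(t.prefix, 0) + 1
            top = max(counts.values())
            target_prefix = min(p for p, c in counts.items() if c == top)

    bridges = {frozenset(b) for b in bridges}
    bridge_terms = {t for b in bridges for t in b}
    closure_relations = frozenset(closure_relations)

    subset_sizes: dict[str, tuple[int, int]] = {}
    if full_import:
        subsets = [b.copy() for b in blocks]
    else:
        subsets = []
        for block in blocks:
            kept = OntologyGraph()
            for prefix in sorted({t.prefix for t in block.terms}):
                seeds = referenced_terms(definitions, prefix)
                seeds |= {t for t in bridge_terms if t.prefix == prefix}
                seeds = {s for s in seeds if s in block.terms}
                if not seeds:
                    continue
                sub = induced_ancestral_graph(
                    block,
                    SubsetSpec(prefix, frozenset(seeds), closure_relations),
                    findings,
                )
                kept.terms.update(sub.terms)
                kept.isa_edges |= sub.isa_edges
                kept.rel_edges |= sub.rel_edges
            subsets.append(kept)
        for block, sub in zip(blocks, subsets):
            if block.terms:
                prefix = block.dominant_prefix()
                subset_sizes[prefix] = (len(sub.terms), len(block.terms))
                log.info(
                    "subset %s: %d of %d terms (%.2f%%)",
                    prefix, len(sub.terms), len(block.terms),
                    100.0 * len(sub.terms) / len(block.terms),
                )

    composite = build_composite(subsets, definitions, bridges)
    findings.extend(composite.findings)

    axioms = normalize(composite, include_rel_edges=include_rel_edges)
    closure = classify(axioms)
    inferred = inferred_target_axioms(closure, target_prefix, defined_terms)

    labels = {}
    for block in blocks:
        labels.update(block.labels())
    labels.update(target.labels())
    report = compare(
        inferred,
        closure,
        target,
        defined_terms,
        definitions={d.defined: d for d in definitions},
        labels=labels,
    )
    log.info("category counts: %s", report.category_counts())

    reasoned = OntologyGraph()
    for t in sorted(inferred.representative):
        reasoned.add_term(t, labels.get(t, ""))
    for a, b in inferred.direct_edges:
        reasoned.add_isa(a, b)

    return PipelineResult(
        report=report,
        composite=composite,
        closure=closure,
        inferred=inferred,
        reasoned=reasoned,
        subset_sizes=subset_sizes,
        findings=findings,
    )
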