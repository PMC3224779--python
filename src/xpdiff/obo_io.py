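"""OBO flat-file reading/writing and the plain-text disagreement reports.

Reading is backed by :mod:`obonet` (tag-value OBO parser; trailing ``!``
comments are stripped, duplicate ``[Term]`` stanzas resolve last-writer-wins).
Writing is a purpose-built serializer because the pipeline requires
byte-identical output across runs: stanzas sorted by term id, fixed tag
order, no timestamps.

Recognized tags: ``id``, ``name``, ``is_a``, ``relationship``,
``intersection_of``, ``xref``, ``is_obsolete``.  Anything else is ignored
with a debug log; OBO 1.4 clause qualifiers are not supported.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, TYPE_CHECKING

import obonet

from .core_model import (
    LogicalDefinition,
    OntologyGraph,
    ParseError,
    Relation,
    TermId,
    parse_term_id,
)

if TYPE_CHECKING:  # pragma: no cover
    from .comparison import ComparisonReport

log = logging.getLogger(__name__)

REPORT_FILES = (
    "inf_ax_found.txt",
    "inf_ax_not_found.txt",
    "assert_ax_found.txt",
    "assert_ax_not_found.txt",
    "equivalence_ax.txt",
)

_RECOGNIZED_TAGS = {
    "id", "name", "is_a", "relationship", "intersection_of", "xref", "is_obsolete",
}


@dataclass
class DefinitionDocument:
    """The logical definitions carried by one parsed OBO document."""

    source: str
    definitions: list[LogicalDefinition] = field(default_factory=list)

    @property
    def referenced_prefixes(self) -> set[str]:
        return {t.prefix for d in self.definitions for t in d.referenced()}


def _read_text(source: str | os.PathLike | TextIO) -> tuple[str, str]:
    """Return (text, source name) from a path, path-like or open text handle."""
    if hasattr(source, "read"):
        return source.read(), getattr(source, "name", "<stream>")
    path = Path(source)
    try:
        return path.read_text(), str(path)
    except OSError as exc:
        raise IOError(f"cannot read OBO document {path}: {exc}") from exc


_ID_LINE = re.compile(r"^id:\s*(\S+)", re.MULTILINE)


def parse_obo(source: str | os.PathLike | TextIO) -> tuple[OntologyGraph, DefinitionDocument]:
    """Parse an OBO document into a graph plus its logical definitions.

    ``intersection_of`` lines with a single token become genera, with two
    tokens (relation + filler) differentia.  A stanza with fewer than two
    ``intersection_of`` lines is not a valid intersection and yields no
    definition (logged at debug level).
    """
    text, name = _read_text(source)
    seen: set[str] = set()
    for tok in _ID_LINE.findall(text):
        if tok in seen:
            log.warning("%s: duplicate [Term] stanza for %s — last writer wins", name, tok)
        seen.add(tok)

    try:
        net = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueErrors on bad stanzas
        raise ParseError(f"cannot parse OBO document {name}: {exc}") from exc

    graph = OntologyGraph()
    doc = DefinitionDocument(source=name)
    for node, data in net.nodes(data=True):
        try:
            tid = parse_term_id(node)
        except ParseError as exc:
            raise ParseError(f"{name}: bad term id {node!r}: {exc}") from exc
        xrefs = set()
        for raw in data.get("xref", ()):
            tok = raw.split()[0] if raw.split() else ""
            try:
                xrefs.add(parse_term_id(tok))
            except ParseError:
                log.debug("%s: ignoring non-CURIE xref %r on %s", name, raw, node)
        graph.add_term(
            tid,
            data.get("name", ""),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            xrefs=xrefs,
        )
        for unknown in set(data) - _RECOGNIZED_TAGS:
            log.debug("%s: ignoring unrecognized tag %r on %s", name, unknown, node)

    # edges from raw tag values, so targets undeclared in the file still show up
    for node, data in net.nodes(data=True):
        tid = parse_term_id(node)
        for raw in data.get("is_a", ()):
            graph.add_isa(tid, parse_term_id(raw))
        for raw in data.get("relationship", ()):
            parts = raw.split()
            if len(parts) != 2:
                raise ParseError(f"{name}: malformed relationship line {raw!r} on {node}")
            graph.add_rel(tid, Relation(parts[0]), parse_term_id(parts[1]))

        inter = data.get("intersection_of", ())
        if not inter:
            continue
        if len(inter) < 2:
            log.debug("%s: %s has a single intersection_of line — not a valid intersection, skipped", name, node)
            continue
        genera: list[TermId] = []
        differentia: list[tuple[Relation, TermId]] = []
        for raw in inter:
            parts = raw.split()
            if len(parts) == 1:
                genera.append(parse_term_id(parts[0]))
            elif len(parts) == 2:
                differentia.append((Relation(parts[0]), parse_term_id(parts[1])))
            else:
                raise ParseError(f"{name}: malformed intersection_of line {raw!r} on {node}")
        if not genera:
            log.warning("%s: definition of %s has no genus conjunct — skipped", name, node)
            continue
        doc.definitions.append(LogicalDefinition(tid, tuple(genera), tuple(differentia)))
    doc.definitions.sort(key=lambda d: d.defined)
    return graph, doc


def merge_definition_documents(docs: Sequence[DefinitionDocument]) -> list[LogicalDefinition]:
    """Concatenate definition files; cross-file duplicates for one term are an error."""
    by_term: dict[TermId, tuple[str, LogicalDefinition]] = {}
    for doc in docs:
        for d in doc.definitions:
            prior = by_term.get(d.defined)
            if prior is not None and prior[1] != d:
                raise ParseError(
                    f"conflicting logical definitions for {d.defined} in {prior[0]} and {doc.source}"
                )
            by_term[d.defined] = (doc.source, d)
    return [d for _, d in sorted(by_term.values(), key=lambda sd: sd[1].defined)]


def _definition_line(d: LogicalDefinition) -> str:
    parts = [str(g) for g in d.genera] + [f"{r} some {f}" for r, f in d.differentia]
    return f"{d.defined} = " + " and ".join(parts)


def write_obo(graph: OntologyGraph, definitions: Sequence[LogicalDefinition] = ()) -> str:
    """Serialize deterministically: sorted stanzas, fixed tag order.

    Tag order inside a stanza is id, name, is_obsolete, is_a, relationship,
    intersection_of, xref.  Output is byte-identical across runs for equal
    inputs and differs for unequal validated graphs.
    """
    defs = {d.defined: d for d in definitions}
    out = ["format-version: 1.2", ""]
    for tid in sorted(set(graph.terms) | set(defs)):
        info = graph.terms.get(tid)
        out.append("[Term]")
        out.append(f"id: {tid}")
        if info is not None and info.label:
            out.append(f"name: {info.label}")
        if info is not None and info.obsolete:
            out.append("is_obsolete: true")
        for child, parent in sorted(e for e in graph.isa_edges if e[0] == tid):
            out.append(f"is_a: {parent}")
        for s, r, o in sorted(e for e in graph.rel_edges if e[0] == tid):
            out.append(f"relationship: {r} {o}")
        d = defs.get(tid)
        if d is not None:
            for g in d.genera:
                out.append(f"intersection_of: {g}")
            for r, f in d.differentia:
                out.append(f"intersection_of: {r} {f}")
        if info is not None:
            for x in sorted(info.xrefs):
                out.append(f"xref: {x}")
        out.append("")
    return "\n".join(out) + "\n"


_HEADER = "child_id\tchild_label\tparent_id\tparent_label"


def _axiom_line(edge, labels: Mapping[TermId, str], category: str = "") -> str:
    child, parent = edge
    cols = [str(child), labels.get(child, ""), str(parent), labels.get(parent, "")]
    if category:
        cols.append(category)
    return "\t".join(cols)


def _definition_block(edge, definitions: Mapping[TermId, LogicalDefinition]) -> list[str]:
    lines = []
    for term in edge:
        d = definitions.get(term)
        lines.append("    def " + (_definition_line(d) if d else f"{term} = (none)"))
    return lines


def write_reports(report: "ComparisonReport", outdir: str | os.PathLike) -> list[str]:
    """Write the five disagreement report files; returns their names.

    The two ``*_not_found`` files append the logical definitions of both
    endpoints under each axiom line — the curator's debugging hint.  All
    files are sorted (child id, then parent id) and byte-stable.
    """
    outdir = Path(outdir)
    labels = report.labels
    defs = report.definitions

    contents: dict[str, str] = {}

    found = [(e, "direct") for e in report.inferred_found_direct]
    found += [(e, "indirect") for e in report.inferred_found_indirect]
    lines = [_HEADER + "\tcategory"]
    for edge, cat in sorted(found):
        lines.append(_axiom_line(edge, labels, cat))
    contents["inf_ax_found.txt"] = "\n".join(lines) + "\n"

    lines = [_HEADER]
    for edge in sorted(report.inferred_new):
        lines.append(_axiom_line(edge, labels))
        lines.extend(_definition_block(edge, defs))
    contents["inf_ax_not_found.txt"] = "\n".join(lines) + "\n"

    lines = [_HEADER]
    for edge in sorted(report.asserted_found):
        lines.append(_axiom_line(edge, labels))
    contents["assert_ax_found.txt"] = "\n".join(lines) + "\n"

    lines = [_HEADER]
    for edge in sorted(report.asserted_not_found):
        lines.append(_axiom_line(edge, labels))
        lines.extend(_definition_block(edge, defs))
    contents["assert_ax_not_found.txt"] = "\n".join(lines) + "\n"

    lines = ["equivalent_terms"]
    for cls in sorted(tuple(sorted(c)) for c in report.equivalence_classes):
        lines.append("\t".join(f"{t} ({labels.get(t, '')})" for t in cls))
    contents["equivalence_ax.txt"] = "\n".join(lines) + "\n"

    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {outdir} is not writable: {exc}") from exc
    for fname in REPORT_FILES:
        (outdir / fname).write_text(contents[fname])
    return list(REPORT_FILES)
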