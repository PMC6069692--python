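"""Readers and writers for the annotation dialect and the analysis sidecar.

Two inputs describe a document:

* an annotation XML file in the 2012-style clinical temporal-annotation
  dialect — ``<TEXT>`` holding the raw text, and ``<TAGS>`` holding
  ``TIMEX3``/``EVENT``/``TLINK`` elements with 0-based half-open character
  offsets (see ``docs/formats.md``; the dialect is frozen there and the
  fixtures are the normative examples);
* a sentence-analysis sidecar — JSON lines, one record per sentence with
  tokens+POS, a bracketed constituency parse, dependency triples,
  predicate frames and the section label.  Analyses are *inputs*: this
  package bundles no parser or semantic role labeler.
"""

from __future__ import annotations

import json
import logging
import re
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from lxml import etree

from .model import (
    AnnotatedSentence,
    Document,
    EventAttrs,
    EventType,
    FrameArgument,
    Mention,
    MentionCategory,
    PredicateFrame,
    RelationGraph,
    RelType,
    Span,
    StructuralError,
    TemporalRelation,
    TimeAttrs,
    TimeType,
    Token,
)
from .trees import format_bracketed_tree, parse_bracketed_tree

logger = logging.getLogger(__name__)

Source = Union[str, Path, IO]

SIDECAR_SCHEMA_VERSION = 1

#: Default collapse of the 2012-dialect TLINK label inventory onto the
#: three canonical types.  Config-editable; unmapped labels are an error.
DEFAULT_TLINK_LABEL_MAP: dict[str, RelType] = {
    "BEFORE": RelType.BEFORE,
    "AFTER": RelType.AFTER,
    "OVERLAP": RelType.OVERLAP,
    "SIMULTANEOUS": RelType.OVERLAP,
    "DURING": RelType.OVERLAP,
    "BEGUN_BY": RelType.OVERLAP,
    "ENDED_BY": RelType.OVERLAP,
    "BEFORE_OVERLAP": RelType.BEFORE,
}

_CANONICAL_EVENT_TYPES = {t.value for t in EventType}


def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        data = source.read()
        return data.decode("utf-8") if isinstance(data, bytes) else data
    return Path(source).read_text(encoding="utf-8")


def _open_sink(sink, mode="w"):
    if hasattr(sink, "write"):
        return sink, False
    return open(sink, mode, encoding="utf-8"), True


# ---------------------------------------------------------------------------
# Annotation XML


def _parse_mention_element(element, doc_id: str) -> Mention:
    mid = element.get("id")
    start = int(element.get("start"))
    end = int(element.get("end"))
    text = element.get("text", "")
    if element.tag == "TIMEX3":
        ttype = TimeType(element.get("type", "DATE").upper())
        return Mention(
            id=mid,
            doc_id=doc_id,
            span=Span(start, end),
            text=text,
            category=MentionCategory.TIME,
            time_attrs=TimeAttrs(ttype, element.get("val", ""), element.get("mod", "")),
        )
    raw_type = element.get("type", "OTHER").upper()
    etype = EventType(raw_type) if raw_type in _CANONICAL_EVENT_TYPES else EventType.OTHER
    return Mention(
        id=mid,
        doc_id=doc_id,
        span=Span(start, end),
        text=text,
        category=MentionCategory.EVENT,
        event_attrs=EventAttrs(
            etype, element.get("polarity", "POS"), element.get("modality", "FACTUAL")
        ),
    )


def map_tlink_label(label: str, label_map: Optional[dict[str, RelType]] = None) -> RelType:
    table = DEFAULT_TLINK_LABEL_MAP if label_map is None else label_map
    key = label.strip().upper()
    if key not in table:
        raise StructuralError(
            f"unmappable TLINK label {label!r}; known labels: {sorted(table)}"
        )
    return table[key]


def read_annotation_xml(
    source: Source,
    doc_id: str = "",
    label_map: Optional[dict[str, RelType]] = None,
) -> tuple[str, dict[str, Mention], RelationGraph, dict[str, int]]:
    """Parse one annotation file into (text, mentions, relations, counts)."""
    root = etree.fromstring(_read_text(source).encode("utf-8"))
    doc_id = doc_id or root.get("id", "") or "doc"
    text_el = root.find("TEXT")
    text = text_el.text or "" if text_el is not None else ""
    mentions: dict[str, Mention] = {}
    counts = {"TIMEX3": 0, "EVENT": 0, "TLINK": 0}
    tags = root.find("TAGS")
    elements = list(tags) if tags is not None else []
    for element in elements:
        if element.tag in ("TIMEX3", "EVENT"):
            mention = _parse_mention_element(element, doc_id)
            if mention.id in mentions:
                raise StructuralError(f"{doc_id}: duplicate mention id {mention.id!r}")
            if text and text[mention.span.start : mention.span.end] != mention.text:
                raise StructuralError(
                    f"{doc_id}: mention {mention.id} text {mention.text!r} does not "
                    f"match document substring at {mention.span}"
                )
            mentions[mention.id] = mention
            counts[element.tag] += 1
    relations = RelationGraph(mentions=mentions)
    for element in elements:
        if element.tag != "TLINK":
            continue
        counts["TLINK"] += 1
        from_id, to_id = element.get("fromID"), element.get("toID")
        for mid in (from_id, to_id):
            if mid not in mentions:
                raise StructuralError(
                    f"{doc_id}: TLINK {element.get('id')!r} references unknown "
                    f"mention id {mid!r}"
                )
        relations.add(
            TemporalRelation(from_id, to_id, map_tlink_label(element.get("type", ""), label_map))
        )
    logger.info(
        "%s: parsed %d TIMEX3, %d EVENT, %d TLINK records",
        doc_id,
        counts["TIMEX3"],
        counts["EVENT"],
        counts["TLINK"],
    )
    return text, mentions, relations, counts


def write_annotation_xml(doc: Document, sink) -> None:
    """Write a document (text, mentions, gold relations) to annotation XML."""
    root = etree.Element("ClinicalNarrativeTemporalAnnotation", id=doc.doc_id)
    text_el = etree.SubElement(root, "TEXT")
    text_el.text = doc.text
    tags = etree.SubElement(root, "TAGS")
    for mention in sorted(doc.mentions.values(), key=lambda m: (m.span.start, m.id)):
        if mention.is_time:
            attrs = mention.time_attrs or TimeAttrs(TimeType.DATE)
            etree.SubElement(
                tags,
                "TIMEX3",
                id=mention.id,
                start=str(mention.span.start),
                end=str(mention.span.end),
                text=mention.text,
                type=attrs.time_type.value,
                val=attrs.value,
                mod=attrs.mod,
            )
        else:
            attrs = mention.event_attrs or EventAttrs(EventType.OTHER)
            etree.SubElement(
                tags,
                "EVENT",
                id=mention.id,
                start=str(mention.span.start),
                end=str(mention.span.end),
                text=mention.text,
                type=attrs.event_type.value,
                polarity=attrs.polarity,
                modality=attrs.modality,
            )
    if doc.gold_relations is not None:
        _append_tlinks(tags, doc.gold_relations)
    _write_xml(root, sink)


def _append_tlinks(tags, relations: RelationGraph) -> None:
    for i, rel in enumerate(relations.sorted()):
        from_text = to_text = ""
        if rel.source in relations.mentions:
            from_text = relations.mentions[rel.source].text
        if rel.target in relations.mentions:
            to_text = relations.mentions[rel.target].text
        etree.SubElement(
            tags,
            "TLINK",
            id=f"TL{i}",
            fromID=rel.source,
            fromText=from_text,
            toID=rel.target,
            toText=to_text,
            type=rel.rel_type.value,
        )


def _write_xml(root, sink) -> None:
    payload = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")
    handle, close = _open_sink(sink)
    try:
        handle.write(payload)
    finally:
        if close:
            handle.close()


def write_predictions(relations: RelationGraph, sink) -> None:
    """Emit a TLINK-only file in the annotation dialect.

    Every mention id must resolve through the graph's mention index;
    reading the file back with :func:`read_predictions` yields an equal
    relation set.
    """
    relations.validate()
    root = etree.Element("ClinicalNarrativeTemporalAnnotation")
    tags = etree.SubElement(root, "TAGS")
    _append_tlinks(tags, relations)
    _write_xml(root, sink)


def read_predictions(
    source: Source,
    mentions: Optional[dict[str, Mention]] = None,
    label_map: Optional[dict[str, RelType]] = None,
) -> RelationGraph:
    """Read a TLINK-only file back into a relation graph."""
    root = etree.fromstring(_read_text(source).encode("utf-8"))
    graph = RelationGraph(mentions=mentions or {})
    for element in root.iter("TLINK"):
        graph.add(
            TemporalRelation(
                element.get("fromID"),
                element.get("toID"),
                map_tlink_label(element.get("type", ""), label_map),
            )
        )
    if mentions is not None:
        graph.validate()
    return graph


# ---------------------------------------------------------------------------
# Sentence-analysis sidecar (JSON lines, one sentence per record)


def sentence_to_record(sentence: AnnotatedSentence) -> dict:
    return {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "start": sentence.span.start,
        "end": sentence.span.end,
        "tokens": [
            {"text": t.text, "start": t.span.start, "end": t.span.end, "pos": t.pos}
            for t in sentence.tokens
        ],
        "tree": format_bracketed_tree(sentence.tree),
        "deps": [list(d) for d in sentence.dependencies],
        "frames": [
            {
                "predicate": f.predicate_index,
                "args": [
                    {"role": a.role, "start": a.span.start, "end": a.span.end, "kind": a.kind}
                    for a in f.arguments
                ],
            }
            for f in sentence.frames
        ],
        "section": sentence.section_label,
        "starts_with_enumeration": sentence.starts_with_enumeration,
        "ends_with_colon": sentence.ends_with_colon,
    }


def record_to_sentence(record: dict) -> AnnotatedSentence:
    tokens = [
        Token(t["text"], Span(t["start"], t["end"]), t["pos"]) for t in record["tokens"]
    ]
    tree = parse_bracketed_tree(record["tree"])
    if len(tree.leaves()) != len(tokens):
        raise StructuralError(
            f"sidecar record at {record.get('start')}: tree has "
            f"{len(tree.leaves())} leaves but {len(tokens)} tokens"
        )
    frames = [
        PredicateFrame(
            f["predicate"],
            tuple(
                FrameArgument(a["role"], Span(a["start"], a["end"]), a["kind"])
                for a in f["args"]
            ),
        )
        for f in record.get("frames", [])
    ]
    return AnnotatedSentence(
        span=Span(record["start"], record["end"]),
        tokens=tokens,
        tree=tree,
        dependencies=[tuple(d) for d in record.get("deps", [])],
        frames=frames,
        section_label=record.get("section", ""),
        starts_with_enumeration=record.get("starts_with_enumeration", False),
        ends_with_colon=record.get("ends_with_colon", False),
    )


def read_sidecar(source: Source) -> list[AnnotatedSentence]:
    text = _read_text(source)
    sentences = [
        record_to_sentence(json.loads(line)) for line in text.splitlines() if line.strip()
    ]
    return sentences


def write_sidecar(sentences: Iterable[AnnotatedSentence], sink) -> None:
    handle, close = _open_sink(sink)
    try:
        for sentence in sentences:
            handle.write(json.dumps(sentence_to_record(sentence)) + "\n")
    finally:
        if close:
            handle.close()


def read_document(
    annotation_source: Source,
    analysis_source: Source,
    doc_id: str = "",
    label_map: Optional[dict[str, RelType]] = None,
) -> Document:
    """Assemble a document from its annotation XML and analysis sidecar.

    Gold TLINK labels are collapsed onto {BEFORE, AFTER, OVERLAP} through
    the label map, mention sentence indices are resolved against the
    sidecar sentence spans, and record counts are kept in ``doc.meta``.
    """
    text, mentions, relations, counts = read_annotation_xml(
        annotation_source, doc_id, label_map
    )
    sentences = read_sidecar(analysis_source)
    doc = Document(
        doc_id=doc_id or (next(iter(mentions.values())).doc_id if mentions else "doc"),
        text=text,
        sentences=sentences,
        mentions=mentions,
        gold_relations=relations,
        meta={"read_counts": counts},
    )
    doc.assign_sentence_indices()
    return doc


# ---------------------------------------------------------------------------
# Plain-text lexicons and section identification


def read_lexicon_lines(source: Source) -> list[str]:
    """One entry per line; '#' starts a comment; blanks ignored."""
    entries = []
    for raw in _read_text(source).splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            entries.append(line)
    return entries


def load_default_lexicon(name: str) -> list[str]:
    text = resources.files("directrel.data").joinpath(name).read_text(encoding="utf-8")
    entries = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            entries.append(line)
    return entries


def default_section_headers() -> list[str]:
    return load_default_lexicon("section_headers.txt")


def default_medication_frequencies() -> list[str]:
    return load_default_lexicon("med_frequency.txt")


_HEADER_LINE_RE = re.compile(r"^\s*([A-Z][A-Z /&-]+[A-Z])\s*:\s*$", re.MULTILINE)


def assign_sections(
    text: str,
    sentences: Iterable[AnnotatedSentence],
    headers: Optional[list[str]] = None,
    overwrite: bool = False,
) -> None:
    """Fill ``section_label`` from line-initial "HEADER:" lines in the text.

    A matched header labels every following sentence until the next
    header.  Existing (sidecar-provided) labels win unless ``overwrite``.
    """
    known = {h.upper() for h in (headers if headers is not None else default_section_headers())}
    boundaries: list[tuple[int, str]] = []
    for match in _HEADER_LINE_RE.finditer(text):
        name = match.group(1).strip().upper()
        if name in known:
            boundaries.append((match.start(), name))
    for sentence in sentences:
        if sentence.section_label and not overwrite:
            continue
        label = ""
        for offset, name in boundaries:
            if offset <= sentence.span.start:
                label = name
            else:
                break
        sentence.section_label = label
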