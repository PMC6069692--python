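"""Seeded synthetic-corpus generator with gold linguistic analyses.

Each generated sentence instantiates one construction template:

* direct — modification (a time PP attached to the event's NP), shared
  predicate (argument + temporal adjunct of one verb), PP-exception
  ("two months of diarrhea"), coordination-exception ("fever and
  epigastric pain this morning"), type-preserving-exception ("an episode
  of <problem> ...");
* non-direct — head violation ("resection of <problem> on <date>": the
  time modifies a phrase the event does not head), cross-clause (time
  and event in different coordinated clauses), and a frequency
  distractor (medication frequency next to a problem mention).

Templates emit the surface tokens together with a consistent gold
constituency tree, predicate-argument frames and head-percolated
dependencies, so the rule engine's recovery of the planted direct /
non-direct labels is exact by construction.  Relation types for direct
pairs are drawn from a configurable overlap/before/after mix
(defaulting to the 66/18/16 imbalance typical of clinical time-event
links) and are signalled on the surface by the temporal preposition, so
classifier labels are a deterministic function of planted features.
All randomness flows from a single seed.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

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
    TemporalRelation,
    TimeAttrs,
    TimeType,
    Token,
)
from .rules import HeadTable, tree_to_dependencies
from .trees import format_bracketed_tree, parse_bracketed_tree

# ---------------------------------------------------------------------------
# Slot lexicons (small, fixed, versioned here)

PROBLEMS = [
    ("pneumonia",),
    ("epigastric", "pain"),
    ("fever",),
    ("diarrhea",),
    ("orthostasis",),
    ("hypotension",),
    ("chest", "pain"),
    ("anemia",),
    ("nausea",),
    ("dyspnea",),
]
TREATMENTS = [
    ("laparoscopic", "cholecystectomy"),
    ("chemotherapy",),
    ("warfarin",),
    ("metformin",),
    ("antibiotics",),
    ("cardioversion",),
    ("dialysis",),
    ("lisinopril",),
]
TESTS = [
    ("creatinine",),
    ("chest", "x-ray"),
    ("cardiac", "catheterization"),
    ("repeat", "CBC"),
    ("flex", "sigmoidoscopy"),
    ("blood", "cultures"),
    ("MRI",),
    ("echocardiogram",),
]
DATES = [
    ("2016-03-13",),
    ("10-22",),
    ("12-01",),
    ("Friday",),
    ("Monday",),
    ("Tuesday",),
    ("9-28-92",),
    ("11-03",),
]
BARE_TIMES = [("this", "afternoon"), ("this", "morning"), ("last", "night")]
DURATIONS = [("two", "months"), ("three", "days"), ("six", "weeks"), ("48", "hours")]
FREQUENCIES = [("bid",), ("prn",), ("q2h",), ("tid",), ("daily",)]
HEAD_NOUNS = [("resection",), ("evaluation",), ("a", "course")]
SECTIONS = ["HISTORY OF PRESENT ILLNESS", "HOSPITAL COURSE", "LABORATORY DATA"]

#: Temporal preposition planted as the surface cue of the relation type.
TRIGGERS = {RelType.OVERLAP: "on", RelType.BEFORE: "before", RelType.AFTER: "after"}

_NUMBER_RE = re.compile(r"^\d|^\d.*\d$")
_DET = {"the", "a", "an", "this", "last", "some"}


def _pos(token: str) -> str:
    if token.lower() in _DET:
        return "DT"
    if _NUMBER_RE.match(token):
        return "CD"
    if token.lower() in ("two", "three", "six"):
        return "CD"
    return "NN"


def _np(tokens: Sequence[str]) -> str:
    inner = " ".join(f"({_pos(t)} {t})" for t in tokens)
    return f"(NP {inner})"


class _Builder:
    """Tracks token positions while a template assembles its sentence."""

    def __init__(self) -> None:
        self.tokens: list[str] = []

    def add(self, *tokens: str) -> Span:
        start = len(self.tokens)
        self.tokens.extend(tokens)
        return Span(start, len(self.tokens))


@dataclass
class SentenceSpec:
    tokens: list[str]
    tree: str
    frames: list[tuple[int, list[tuple[str, int, int, str]]]]
    time_span: Span
    time_type: TimeType
    event_span: Span
    event_type: EventType
    rel_type: Optional[RelType]  # None for non-direct pairs
    construction: str


# ---------------------------------------------------------------------------
# Templates


def _t_modification(rng: random.Random, rel: RelType) -> SentenceSpec:
    b = _Builder()
    b.add("The", "patient")
    verb = b.add("underwent").start
    event_slot = rng.choice(TREATMENTS)
    e = b.add(*event_slot)
    trigger = TRIGGERS[rel]
    b.add(trigger)
    date = rng.choice(DATES)
    t = b.add(*date)
    b.add(".")
    tree = (
        "(S (NP (DT The) (NN patient)) (VP (VBD underwent) "
        f"(NP {_np(event_slot)} (PP (IN {trigger}) {_np(date)}))) (. .))"
    )
    frames = [(verb, [("A0", 0, 2, "ARGUMENT"), ("A1", e.start, t.end, "ARGUMENT")])]
    return SentenceSpec(
        b.tokens, tree, frames, t, TimeType.DATE, e, EventType.TREATMENT, rel, "modification"
    )


def _t_same_predicate(rng: random.Random, rel: RelType) -> SentenceSpec:
    b = _Builder()
    b.add("The", "team")
    verb = b.add("checked").start
    event_slot = rng.choice(TESTS)
    e = b.add(*event_slot)
    bare = rel is RelType.OVERLAP and rng.random() < 0.5
    if bare:
        time_slot = rng.choice(BARE_TIMES)
        t = b.add(*time_slot)
        tail = f"{_np(time_slot)}"
        time_type = TimeType.TIME
        tmp_span = t
    else:
        trigger = TRIGGERS[rel]
        trig_span = b.add(trigger)
        time_slot = rng.choice(DATES)
        t = b.add(*time_slot)
        tail = f"(PP (IN {trigger}) {_np(time_slot)})"
        time_type = TimeType.DATE
        tmp_span = Span(trig_span.start, t.end)
    b.add(".")
    tree = (
        f"(S (NP (DT The) (NN team)) (VP (VBD checked) {_np(event_slot)} {tail}) (. .))"
    )
    frames = [
        (
            verb,
            [
                ("A0", 0, 2, "ARGUMENT"),
                ("A1", e.start, e.end, "ARGUMENT"),
                ("AM-TMP", tmp_span.start, tmp_span.end, "ADJUNCT"),
            ],
        )
    ]
    return SentenceSpec(
        b.tokens, tree, frames, t, time_type, e, EventType.TEST, rel, "same_predicate"
    )


def _t_pp_exception(rng: random.Random, rel: RelType) -> SentenceSpec:
    assert rel is RelType.OVERLAP
    b = _Builder()
    b.add("The", "patient")
    verb = b.add("had").start
    duration = rng.choice(DURATIONS)
    t = b.add(*duration)
    b.add("of")
    problem = rng.choice(PROBLEMS)
    e = b.add(*problem)
    b.add(".")
    tree = (
        "(S (NP (DT The) (NN patient)) (VP (VBD had) "
        f"(NP {_np(duration)} (PP (IN of) {_np(problem)}))) (. .))"
    )
    frames = [(verb, [("A0", 0, 2, "ARGUMENT"), ("A1", t.start, e.end, "ARGUMENT")])]
    return SentenceSpec(
        b.tokens, tree, frames, t, TimeType.DURATION, e, EventType.PROBLEM, rel, "pp_exception"
    )


def _t_coordination(rng: random.Random, rel: RelType) -> SentenceSpec:
    b = _Builder()
    b.add("The", "patient")
    verb = b.add("had").start
    other = rng.choice(PROBLEMS)
    problem = rng.choice([p for p in PROBLEMS if p != other])
    # the annotated event is the first coordinate, so the coordination's
    # lexical head (the last coordinate) lies outside the mention and the
    # exception case is genuinely required
    e = b.add(*problem)
    b.add("and")
    o = b.add(*other)
    trigger = TRIGGERS[rel]
    trig_span = b.add(trigger)
    date = rng.choice(DATES)
    t = b.add(*date)
    b.add(".")
    tree = (
        "(S (NP (DT The) (NN patient)) (VP (VBD had) "
        f"(NP {_np(problem)} (CC and) {_np(other)}) "
        f"(PP (IN {trigger}) {_np(date)})) (. .))"
    )
    frames = [
        (
            verb,
            [
                ("A0", 0, 2, "ARGUMENT"),
                ("A1", e.start, o.end, "ARGUMENT"),
                ("AM-TMP", trig_span.start, t.end, "ADJUNCT"),
            ],
        )
    ]
    return SentenceSpec(
        b.tokens, tree, frames, t, TimeType.DATE, e, EventType.PROBLEM, rel, "coordination"
    )


def _t_type_preserving(rng: random.Random, rel: RelType) -> SentenceSpec:
    b = _Builder()
    b.add("She")
    verb = b.add("had").start
    phrase_start = b.add("an", "episode", "of").start
    problem = rng.choice(PROBLEMS)
    e = b.add(*problem)
    trigger = TRIGGERS[rel]
    trig_span = b.add(trigger)
    date = rng.choice(DATES)
    t = b.add(*date)
    b.add(".")
    tree = (
        "(S (NP (PRP She)) (VP (VBD had) "
        f"(NP (NP (DT an) (NN episode)) (PP (IN of) {_np(problem)})) "
        f"(PP (IN {trigger}) {_np(date)})) (. .))"
    )
    frames = [
        (
            verb,
            [
                ("A0", 0, 1, "ARGUMENT"),
                ("A1", phrase_start, e.end, "ARGUMENT"),
                ("AM-TMP", trig_span.start, t.end, "ADJUNCT"),
            ],
        )
    ]
    return SentenceSpec(
        b.tokens, tree, frames, t, TimeType.DATE, e, EventType.PROBLEM, rel, "type_preserving"
    )


def _t_head_violation(rng: random.Random, rel=None) -> SentenceSpec:
    b = _Builder()
    b.add("The", "patient")
    verb = b.add("underwent").start
    head = rng.choice(HEAD_NOUNS)
    h = b.add(*head)
    b.add("of")
    problem = rng.choice(PROBLEMS)
    e = b.add(*problem)
    trigger = TRIGGERS[rng.choice(list(TRIGGERS))]
    b.add(trigger)
    date = rng.choice(DATES)
    t = b.add(*date)
    b.add(".")
    tree = (
        "(S (NP (DT The) (NN patient)) (VP (VBD underwent) "
        f"(NP (NP {_np(head)} (PP (IN of) {_np(problem)})) "
        f"(PP (IN {trigger}) {_np(date)}))) (. .))"
    )
    frames = [(verb, [("A0", 0, 2, "ARGUMENT"), ("A1", h.start, t.end, "ARGUMENT")])]
    return SentenceSpec(
        b.tokens, tree, frames, t, TimeType.DATE, e, EventType.PROBLEM, None, "head_violation"
    )


def _t_cross_clause(rng: random.Random, rel=None) -> SentenceSpec:
    b = _Builder()
    b.add("The", "patient")
    verb1 = b.add("received").start
    treatment = rng.choice(TREATMENTS)
    e = b.add(*treatment)
    b.add(",", "and")
    trigger = TRIGGERS[rng.choice(list(TRIGGERS))]
    trig_span = b.add(trigger)
    date = rng.choice(DATES)
    t = b.add(*date)
    b.add("she")
    verb2 = b.add("remained").start
    b.add("stable")
    b.add(".")
    tree = (
        "(S (S (NP (DT The) (NN patient)) "
        f"(VP (VBD received) {_np(treatment)})) (, ,) (CC and) "
        f"(S (PP (IN {trigger}) {_np(date)}) (NP (PRP she)) "
        "(VP (VBD remained) (ADJP (JJ stable)))) (. .))"
    )
    frames = [
        (verb1, [("A0", 0, 2, "ARGUMENT"), ("A1", e.start, e.end, "ARGUMENT")]),
        (
            verb2,
            [
                ("AM-TMP", trig_span.start, t.end, "ADJUNCT"),
                ("A0", verb2 - 1, verb2, "ARGUMENT"),
                ("A1", verb2 + 1, verb2 + 2, "ARGUMENT"),
            ],
        ),
    ]
    return SentenceSpec(
        b.tokens, tree, frames, t, TimeType.DATE, e, EventType.TREATMENT, None, "cross_clause"
    )


def _t_frequency_distractor(rng: random.Random, rel=None) -> SentenceSpec:
    b = _Builder()
    b.add("The", "patient", "was")
    verb = b.add("given").start
    treatment = rng.choice(TREATMENTS)
    tr = b.add(*treatment)
    freq = rng.choice(FREQUENCIES)
    t = b.add(*freq)
    b.add("for")
    problem = rng.choice(PROBLEMS)
    e = b.add(*problem)
    b.add(".")
    tree = (
        "(S (NP (DT The) (NN patient)) (VP (VBD was) (VP (VBN given) "
        f"{_np(treatment)} (ADVP (RB {freq[0]})) (PP (IN for) {_np(problem)}))) (. .))"
    )
    frames = [
        (
            verb,
            [
                ("A1", tr.start, tr.end, "ARGUMENT"),
                ("AM-TMP", t.start, t.end, "ADJUNCT"),
                ("AM-PNC", t.end, e.end, "ADJUNCT"),
            ],
        )
    ]
    return SentenceSpec(
        b.tokens,
        tree,
        frames,
        t,
        TimeType.FREQUENCY,
        e,
        EventType.PROBLEM,
        None,
        "frequency_distractor",
    )


_TemplateFn = Callable[[random.Random, Optional[RelType]], SentenceSpec]

#: name -> (builder, supported relation types or None for non-direct)
TEMPLATES: dict[str, tuple[_TemplateFn, Optional[frozenset[RelType]]]] = {
    "modification": (_t_modification, frozenset(RelType)),
    "same_predicate": (_t_same_predicate, frozenset(RelType)),
    "pp_exception": (_t_pp_exception, frozenset({RelType.OVERLAP})),
    "coordination": (_t_coordination, frozenset(RelType)),
    "type_preserving": (_t_type_preserving, frozenset(RelType)),
    "head_violation": (_t_head_violation, None),
    "cross_clause": (_t_cross_clause, None),
    "frequency_distractor": (_t_frequency_distractor, None),
}

DEFAULT_TEMPLATE_WEIGHTS = {
    "modification": 0.20,
    "same_predicate": 0.20,
    "pp_exception": 0.10,
    "coordination": 0.10,
    "type_preserving": 0.10,
    "head_violation": 0.10,
    "cross_clause": 0.10,
    "frequency_distractor": 0.10,
}

#: Relation-type imbalance of direct pairs (overlap-heavy clinical profile).
DEFAULT_REL_TYPE_MIX = {
    RelType.OVERLAP: 0.66,
    RelType.BEFORE: 0.18,
    RelType.AFTER: 0.16,
}


@dataclass
class GeneratorConfig:
    n_documents: int = 500
    sentences_per_document: tuple[int, int] = (2, 6)
    template_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE_WEIGHTS)
    )
    rel_type_mix: dict[RelType, float] = field(
        default_factory=lambda: dict(DEFAULT_REL_TYPE_MIX)
    )
    seed: int = 7
    tree_noise: float = 0.0  # probability of flattening a sentence's tree

    def validate(self) -> None:
        if any(w < 0 for w in self.template_weights.values()) or (
            sum(self.template_weights.values()) <= 0
        ):
            raise ValueError("template weights must be nonnegative with positive sum")
        unknown = set(self.template_weights) - set(TEMPLATES)
        if unknown:
            raise ValueError(f"unknown templates in weights: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Materialization


def _flatten_tree(tree_str: str) -> str:
    leaves = parse_bracketed_tree(tree_str).leaves()
    inner = " ".join(f"({leaf.label} {leaf.token})" for leaf in leaves)
    return f"(S {inner})"


def materialize_sentence(
    spec: SentenceSpec, char_offset: int, section_label: str = ""
) -> AnnotatedSentence:
    """Turn a template output into an AnnotatedSentence at a char offset."""
    tokens: list[Token] = []
    cursor = char_offset
    for i, text in enumerate(spec.tokens):
        if i:
            cursor += 1  # single space separator
        tokens.append(Token(text, Span(cursor, cursor + len(text)), ""))
        cursor += len(text)
    tree = parse_bracketed_tree(spec.tree)
    leaves = tree.leaves()
    if len(leaves) != len(tokens):
        raise ValueError(
            f"template {spec.construction}: tree/token mismatch "
            f"({len(leaves)} leaves vs {len(tokens)} tokens)"
        )
    tokens = [
        Token(tok.text, tok.span, leaf.label) for tok, leaf in zip(tokens, leaves)
    ]
    frames = [
        PredicateFrame(
            pred,
            tuple(FrameArgument(role, Span(s, e), kind) for role, s, e, kind in args),
        )
        for pred, args in spec.frames
    ]
    return AnnotatedSentence(
        span=Span(char_offset, cursor),
        tokens=tokens,
        tree=tree,
        dependencies=tree_to_dependencies(tree, HeadTable()),
        frames=frames,
        section_label=section_label,
        starts_with_enumeration=False,
        ends_with_colon=spec.tokens[-1] == ":",
    )


def _sentence_text(spec: SentenceSpec) -> str:
    return " ".join(spec.tokens)


def build_document(
    doc_id: str, specs: Sequence[SentenceSpec], section_label: str = ""
) -> Document:
    """Assemble a document (text, sentences, mentions, gold) from specs."""
    header = f"{section_label}:\n" if section_label else ""
    text_parts: list[str] = []
    sentences: list[AnnotatedSentence] = []
    mentions: dict[str, Mention] = {}
    gold_relations: list[TemporalRelation] = []
    gold_pairs: dict[tuple[str, str], dict] = {}
    offset = len(header)
    for i, spec in enumerate(specs):
        sentence = materialize_sentence(spec, offset, section_label)
        sentences.append(sentence)
        sentence_text = _sentence_text(spec)
        text_parts.append(sentence_text)
        offset += len(sentence_text) + 1

        def _char_span(token_span: Span) -> Span:
            return Span(
                sentence.tokens[token_span.start].span.start,
                sentence.tokens[token_span.end - 1].span.end,
            )

        t_span = _char_span(spec.time_span)
        e_span = _char_span(spec.event_span)
        time_id = f"T{len([m for m in mentions.values() if m.is_time])}"
        event_id = f"E{len([m for m in mentions.values() if m.is_event])}"
        full_text = header + " ".join(text_parts)
        mentions[time_id] = Mention(
            id=time_id,
            doc_id=doc_id,
            span=t_span,
            text=full_text[t_span.start : t_span.end],
            category=MentionCategory.TIME,
            sentence_index=i,
            time_attrs=TimeAttrs(spec.time_type),
        )
        mentions[event_id] = Mention(
            id=event_id,
            doc_id=doc_id,
            span=e_span,
            text=full_text[e_span.start : e_span.end],
            category=MentionCategory.EVENT,
            sentence_index=i,
            event_attrs=EventAttrs(spec.event_type),
        )
        gold_pairs[(time_id, event_id)] = {
            "is_direct": spec.rel_type is not None,
            "construction": spec.construction,
            "rel_type": spec.rel_type,
        }
        if spec.rel_type is not None:
            gold_relations.append(TemporalRelation(time_id, event_id, spec.rel_type))
    gold = RelationGraph(gold_relations, mentions)
    doc = Document(
        doc_id=doc_id,
        text=header + " ".join(text_parts),
        sentences=sentences,
        mentions=mentions,
        gold_relations=gold,
        meta={"gold_pairs": gold_pairs, "section": section_label},
    )
    return doc


def generate_corpus(config: Optional[GeneratorConfig] = None) -> list[Document]:
    """Generate a deterministic synthetic corpus from the config's seed."""
    config = config or GeneratorConfig()
    config.validate()
    rng = random.Random(config.seed)
    direct_names = [n for n, (_, rels) in TEMPLATES.items() if rels is not None]
    nondirect_names = [n for n, (_, rels) in TEMPLATES.items() if rels is None]
    weights = config.template_weights
    direct_total = sum(weights.get(n, 0.0) for n in direct_names)
    nondirect_total = sum(weights.get(n, 0.0) for n in nondirect_names)
    rel_names = list(config.rel_type_mix)
    rel_weights = [config.rel_type_mix[r] for r in rel_names]

    docs: list[Document] = []
    for d in range(config.n_documents):
        n_sentences = rng.randint(*config.sentences_per_document)
        section = rng.choice(SECTIONS)
        specs: list[SentenceSpec] = []
        for _ in range(n_sentences):
            direct = rng.random() * (direct_total + nondirect_total) < direct_total
            if direct and direct_total > 0:
                rel = rng.choices(rel_names, weights=rel_weights)[0]
                candidates = [
                    n
                    for n in direct_names
                    if weights.get(n, 0.0) > 0 and rel in TEMPLATES[n][1]
                ]
                name = rng.choices(
                    candidates, weights=[weights[n] for n in candidates]
                )[0]
                spec = TEMPLATES[name][0](rng, rel)
            else:
                candidates = [n for n in nondirect_names if weights.get(n, 0.0) > 0]
                name = rng.choices(
                    candidates, weights=[weights[n] for n in candidates]
                )[0]
                spec = TEMPLATES[name][0](rng, None)
            if rng.random() < config.tree_noise:
                spec.tree = _flatten_tree(spec.tree)
            specs.append(spec)
        docs.append(build_document(f"synth-{d:04d}", specs, section))
    return docs


def write_corpus(docs: Sequence[Document], out_dir) -> None:
    """Write annotation XML + analysis sidecar per document."""
    from pathlib import Path

    from .io_formats import write_annotation_xml, write_sidecar

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        write_annotation_xml(doc, out / f"{doc.doc_id}.xml")
        write_sidecar(doc.sentences, out / f"{doc.doc_id}.analyses.jsonl")
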