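"""Core domain model: mentions, temporal relations, documents, candidates.

Character offsets are 0-based half-open intervals over the raw document
text; token and frame spans are half-open intervals over token indices.
Temporal relations are ordered links with one of three types (before,
after, overlap), matching the clinical TLINK convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, NamedTuple, Optional

from .trees import ConstituencyNode

logger = logging.getLogger(__name__)


class StructuralError(ValueError):
    """Inconsistent annotation structure (dangling ids, bad spans)."""


class MentionCategory(str, Enum):
    TIME = "TIME"
    EVENT = "EVENT"


class TimeType(str, Enum):
    DATE = "DATE"
    TIME = "TIME"
    DURATION = "DURATION"
    FREQUENCY = "FREQUENCY"


class EventType(str, Enum):
    PROBLEM = "PROBLEM"
    TEST = "TEST"
    TREATMENT = "TREATMENT"
    OTHER = "OTHER"


class RelType(str, Enum):
    BEFORE = "BEFORE"
    AFTER = "AFTER"
    OVERLAP = "OVERLAP"


#: Classifier label alphabet: the three relation types plus the null class.
NO_RELATION = "NO_RELATION"


class Span(NamedTuple):
    start: int
    end: int

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TimeAttrs:
    time_type: TimeType
    value: str = ""
    mod: str = ""


@dataclass(frozen=True)
class EventAttrs:
    event_type: EventType
    polarity: str = "POS"
    modality: str = "FACTUAL"


@dataclass
class Mention:
    """A time expression or clinical event mention."""

    id: str
    doc_id: str
    span: Span
    text: str
    category: MentionCategory
    sentence_index: int = -1
    time_attrs: Optional[TimeAttrs] = None
    event_attrs: Optional[EventAttrs] = None

    def __post_init__(self) -> None:
        if self.span.start >= self.span.end:
            raise StructuralError(
                f"mention {self.id}: empty or inverted span {self.span}"
            )
        if self.category is MentionCategory.TIME and self.event_attrs is not None:
            raise StructuralError(f"mention {self.id}: TIME with event attributes")
        if self.category is MentionCategory.EVENT and self.time_attrs is not None:
            raise StructuralError(f"mention {self.id}: EVENT with time attributes")

    @property
    def is_time(self) -> bool:
        return self.category is MentionCategory.TIME

    @property
    def is_event(self) -> bool:
        return self.category is MentionCategory.EVENT


@dataclass(frozen=True, order=True)
class TemporalRelation:
    """Ordered (source, target, type) link between two mention ids."""

    source: str
    target: str
    rel_type: RelType

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise StructuralError(
                f"self-relation on mention {self.source} is not allowed"
            )


class RelationGraph:
    """A set of temporal relations plus the mention index resolving them."""

    def __init__(
        self,
        relations: Iterable[TemporalRelation] = (),
        mentions: Optional[dict[str, Mention]] = None,
    ):
        self.relations: set[TemporalRelation] = set(relations)
        self.mentions: dict[str, Mention] = dict(mentions or {})

    def add(self, relation: TemporalRelation) -> None:
        self.relations.add(relation)

    def resolve(self, mention_id: str) -> Mention:
        try:
            return self.mentions[mention_id]
        except KeyError:
            raise StructuralError(f"unresolvable mention id {mention_id!r}") from None

    def validate(self) -> None:
        for rel in self.relations:
            self.resolve(rel.source)
            self.resolve(rel.target)

    def sorted(self) -> list[TemporalRelation]:
        return sorted(self.relations)

    def __contains__(self, relation: TemporalRelation) -> bool:
        return relation in self.relations

    def __iter__(self) -> Iterator[TemporalRelation]:
        return iter(self.relations)

    def __len__(self) -> int:
        return len(self.relations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RelationGraph):
            return NotImplemented
        return self.relations == other.relations

    def copy(self) -> "RelationGraph":
        return RelationGraph(self.relations, self.mentions)


class Token(NamedTuple):
    text: str
    span: Span
    pos: str


@dataclass(frozen=True)
class FrameArgument:
    role: str
    span: Span  # token-index interval, half-open
    kind: str  # "ARGUMENT" | "ADJUNCT"


@dataclass(frozen=True)
class PredicateFrame:
    predicate_index: int
    arguments: tuple[FrameArgument, ...]


@dataclass
class AnnotatedSentence:
    """One sentence of gold linguistic analysis from the sidecar file."""

    span: Span
    tokens: list[Token]
    tree: ConstituencyNode
    dependencies: list[tuple[int, int, str]] = field(default_factory=list)
    frames: list[PredicateFrame] = field(default_factory=list)
    section_label: str = ""
    starts_with_enumeration: bool = False
    ends_with_colon: bool = False

    def token_span_for_chars(self, span: Span) -> Span:
        """Half-open token-index interval of tokens overlapping a char span."""
        indices = [
            i for i, tok in enumerate(self.tokens) if tok.span.overlaps(span)
        ]
        if not indices:
            raise StructuralError(
                f"character span {span} covers no token of sentence at {self.span}"
            )
        return Span(indices[0], indices[-1] + 1)


@dataclass(frozen=True)
class CandidatePair:
    time: Mention
    event: Mention

    def __post_init__(self) -> None:
        if not self.time.is_time or not self.event.is_event:
            raise StructuralError("candidate pair must be (TIME, EVENT)")
        if self.time.sentence_index != self.event.sentence_index:
            raise StructuralError(
                f"pair ({self.time.id}, {self.event.id}) crosses sentences"
            )

    @property
    def sentence_index(self) -> int:
        return self.time.sentence_index

    @property
    def key(self) -> tuple[str, str]:
        return (self.time.id, self.event.id)


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[AnnotatedSentence]
    mentions: dict[str, Mention]
    gold_relations: Optional[RelationGraph] = None
    meta: dict = field(default_factory=dict)

    def mention(self, mention_id: str) -> Mention:
        try:
            return self.mentions[mention_id]
        except KeyError:
            raise StructuralError(
                f"{self.doc_id}: unresolvable mention id {mention_id!r}"
            ) from None

    def sentence_for(self, mention: Mention) -> AnnotatedSentence:
        if not 0 <= mention.sentence_index < len(self.sentences):
            raise StructuralError(
                f"{self.doc_id}: mention {mention.id} has no resolved sentence"
            )
        return self.sentences[mention.sentence_index]

    def assign_sentence_indices(self) -> None:
        """Locate each mention in the sentence containing its span start.

        Mentions crossing a sentence boundary (mis-segmentation) go to the
        sentence containing the start, with a warning.
        """
        for mention in self.mentions.values():
            index = None
            for i, sentence in enumerate(self.sentences):
                if sentence.span.start <= mention.span.start < sentence.span.end:
                    index = i
                    if mention.span.end > sentence.span.end:
                        warnings.warn(
                            f"{self.doc_id}: mention {mention.id} crosses a "
                            f"sentence boundary; assigned to sentence {i}",
                            stacklevel=2,
                        )
                    break
            if index is None:
                raise StructuralError(
                    f"{self.doc_id}: mention {mention.id} at {mention.span} lies "
                    "outside every sentence span"
                )
            mention.sentence_index = index


def enumerate_candidates(doc: Document) -> list[CandidatePair]:
    """All intra-sentential (time expression, event mention) pairs.

    Pairs are ordered by (sentence index, time start, event start) so that
    repeated calls enumerate identically.  Event-event and time-time pairs
    are never candidates.
    """
    for mention in doc.mentions.values():
        if mention.sentence_index < 0:
            raise StructuralError(
                f"{doc.doc_id}: mention {mention.id} has no sentence index; "
                "call assign_sentence_indices() first"
            )
    times = sorted(
        (m for m in doc.mentions.values() if m.is_time),
        key=lambda m: (m.sentence_index, m.span.start, m.id),
    )
    events = sorted(
        (m for m in doc.mentions.values() if m.is_event),
        key=lambda m: (m.sentence_index, m.span.start, m.id),
    )
    pairs = [
        CandidatePair(time=t, event=e)
        for t in times
        for e in events
        if t.sentence_index == e.sentence_index
    ]
    pairs.sort(
        key=lambda p: (p.sentence_index, p.time.span.start, p.event.span.start)
    )
    return pairs
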