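"""Deterministic direct / non-direct decision for time-event pairs.

A pair is *direct* when either (1) the phrase headed by one mention
modifies the phrase headed by the other, or (2) both mentions are
arguments or adjuncts of the same predicate — in both cases with each
mention required to be the head of its phrase.  Three exception cases
relax the head requirement by widening a mention's projection:

* PP case — the mention heads the NP complement of a preposition; the
  projection widens to the PP.
* coordination case — the mention heads one coordinate of a coordinated
  constituent; the projection widens to the whole coordination.
* type-preserving case — a containing phrase matches a template from the
  type-preserving lexicon ("episodes of <problem>", "period of
  <duration>", ...) whose semantic type is still that of the mention; the
  projection widens to the matching phrase.

Widening is chained to a fixed point, so e.g. a type-preserving phrase
sitting inside a PP widens twice.  All decisions are pure functions of
the (gold or parsed) sentence analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Optional, Sequence

from .model import (
    AnnotatedSentence,
    CandidatePair,
    Mention,
    MentionCategory,
    Span,
)
from .trees import ConstituencyNode

# ---------------------------------------------------------------------------
# Head finding


class HeadTable:
    """Per-label head-child search rules (direction + label priority groups).

    For a node's label, each group of child labels is scanned in the given
    direction; the first child whose label falls in the group is the head
    child.  If no group matches, the fallback is the first child in the
    scan direction.  Unknown labels use the leftmost child.
    """

    def __init__(self, rules: Optional[dict[str, tuple[str, Sequence[frozenset[str]]]]] = None):
        self.rules = dict(DEFAULT_HEAD_RULES if rules is None else rules)

    def head_child(self, node: ConstituencyNode) -> ConstituencyNode:
        if node.is_terminal:
            raise ValueError("terminal nodes have no head child")
        if len(node.children) == 1:
            return node.children[0]
        direction, groups = self.rules.get(node.label, ("left", ()))
        children = node.children if direction == "left" else list(reversed(node.children))
        for group in groups:
            for child in children:
                if child.label in group:
                    return child
        return children[0]

    def lexical_head(self, node: ConstituencyNode) -> ConstituencyNode:
        """Descend through head children to the head terminal."""
        while not node.is_terminal:
            node = self.head_child(node)
        return node

    def head_spine(self, node: ConstituencyNode) -> list[ConstituencyNode]:
        spine = [node]
        while not node.is_terminal:
            node = self.head_child(node)
            spine.append(node)
        return spine


_NOMINAL = frozenset({"NN", "NNS", "NNP", "NNPS", "NX", "PRP", "CD"})
_VERBAL = frozenset({"VBD", "VBN", "MD", "VBZ", "VB", "VBG", "VBP"})

DEFAULT_HEAD_RULES: dict[str, tuple[str, Sequence[frozenset[str]]]] = {
    # NP: rightmost nominal terminal, else rightmost nested NP, else
    # rightmost adjectival/quantifier material.
    "NP": ("right", (_NOMINAL, frozenset({"NP", "NX"}), frozenset({"JJ", "JJR", "JJS", "QP", "RB"}))),
    "NX": ("right", (_NOMINAL, frozenset({"NP", "NX"}))),
    "QP": ("right", (frozenset({"CD", "NN"}),)),
    # PP: the preposition is the head.
    "PP": ("left", (frozenset({"IN", "TO", "RP"}),)),
    "VP": ("left", (_VERBAL, frozenset({"VP"}))),
    "S": ("left", (frozenset({"VP"}), frozenset({"S", "SBAR"}))),
    "SBAR": ("left", (frozenset({"S"}), frozenset({"IN", "WHNP", "WHADVP"}))),
    "SINV": ("left", (frozenset({"VP", "VBZ", "VBD", "VBP", "VB"}),)),
    "ADVP": ("right", (frozenset({"RB", "RBR", "RBS", "ADVP"}), frozenset({"JJ", "IN", "NP", "CD", "NN"}))),
    "ADJP": ("right", (frozenset({"JJ", "JJR", "JJS", "ADJP"}), frozenset({"VBN", "VBG", "RB"}))),
}


def find_head(node: ConstituencyNode, table: Optional[HeadTable] = None) -> ConstituencyNode:
    """The head child of a constituent under the (default) head table."""
    return (table or HeadTable()).head_child(node)


# ---------------------------------------------------------------------------
# Type-preserving lexicon

_PLACEHOLDER_RE = re.compile(r"\[(Event|Time)-([A-Za-z]+)\]")


@dataclass(frozen=True)
class TypePreservingTemplate:
    prefix: tuple[str, ...]
    suffix: tuple[str, ...]
    category: MentionCategory
    subtype: str  # PROBLEM / TREATMENT / TEST / DATE / DURATION / TIME / FREQUENCY

    @classmethod
    def parse(cls, line: str) -> "TypePreservingTemplate":
        match = _PLACEHOLDER_RE.search(line)
        if match is None:
            raise ValueError(f"template {line!r} has no [..] placeholder")
        if _PLACEHOLDER_RE.search(line, match.end()) is not None:
            raise ValueError(f"template {line!r} has more than one placeholder")
        category = MentionCategory.EVENT if match.group(1) == "Event" else MentionCategory.TIME
        prefix = tuple(line[: match.start()].lower().split())
        suffix = tuple(line[match.end() :].lower().split())
        return cls(prefix, suffix, category, match.group(2).upper())


class TypePreservingLexicon:
    """Templates for phrases whose semantic type is still the mention's.

    The shipped lexicon holds the published example templates; it is
    loaded from a plain-text config file (one template per line, ``#``
    comments) and is freely extensible.
    """

    def __init__(self, templates: Iterable[TypePreservingTemplate] = ()):
        self.templates = list(templates)

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "TypePreservingLexicon":
        templates = []
        for raw in lines:
            line = raw.split("#", 1)[0].strip()
            if line:
                templates.append(TypePreservingTemplate.parse(line))
        return cls(templates)

    @classmethod
    def default(cls) -> "TypePreservingLexicon":
        text = (
            resources.files("directrel.data")
            .joinpath("type_preserving.txt")
            .read_text(encoding="utf-8")
        )
        return cls.from_lines(text.splitlines())

    @classmethod
    def empty(cls) -> "TypePreservingLexicon":
        return cls()

    def _mention_subtype(self, mention: Mention) -> Optional[str]:
        if mention.is_time and mention.time_attrs is not None:
            return mention.time_attrs.time_type.value
        if mention.is_event and mention.event_attrs is not None:
            return mention.event_attrs.event_type.value
        return None

    def matches(
        self,
        phrase: ConstituencyNode,
        sentence: AnnotatedSentence,
        mention: Mention,
        mention_tokens: Span,
    ) -> bool:
        """Does ``phrase`` instantiate some template with the mention in
        the placeholder slot?"""
        subtype = self._mention_subtype(mention)
        if subtype is None:
            return False
        tokens = [sentence.tokens[i].text.lower() for i in range(phrase.start, phrase.end)]
        for template in self.templates:
            if template.category is not mention.category or template.subtype != subtype:
                continue
            k, m = len(template.prefix), len(template.suffix)
            if len(tokens) <= k + m:
                continue
            if tuple(tokens[:k]) != template.prefix:
                continue
            if m and tuple(tokens[-m:]) != template.suffix:
                continue
            slot = Span(phrase.start + k, phrase.end - m)
            if slot.contains(mention_tokens):
                return True
        return False


# ---------------------------------------------------------------------------
# Projections and decisions


class ExceptionCase(str, Enum):
    NONE = "NONE"
    PP_CASE = "PP_CASE"
    COORD_CASE = "COORD_CASE"
    TYPE_PRESERVING_CASE = "TYPE_PRESERVING_CASE"


class Rationale(str, Enum):
    MODIFICATION = "MODIFICATION"
    SAME_PREDICATE = "SAME_PREDICATE"
    NOT_HEAD = "NOT_HEAD"
    NO_SYNTACTIC_LINK = "NO_SYNTACTIC_LINK"


ALL_EXCEPTIONS = frozenset(
    {ExceptionCase.PP_CASE, ExceptionCase.COORD_CASE, ExceptionCase.TYPE_PRESERVING_CASE}
)

_PREP_LABELS = frozenset({"IN", "TO"})
_CLAUSE_LABELS = frozenset({"S", "SBAR", "SQ", "SINV", "FRAG", "ROOT", "TOP", "UCP"})
_CONJ_TOKENS = frozenset({",", ";"})


@dataclass
class Projection:
    """A mention's maximal head projection after exception widening.

    ``base`` is the un-widened projection (the largest node lexically
    headed inside the mention); ``node`` is the final, possibly widened
    projection.  The chain of nodes from ``node`` down to ``base`` is the
    mention's projection spine, against which modifiers attach.
    """

    node: ConstituencyNode
    mention_tokens: Span
    aligned: bool
    base: Optional[ConstituencyNode] = None
    exceptions: list[ExceptionCase] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.base is None:
            self.base = self.node

    @property
    def span(self) -> Span:
        return Span(self.node.start, self.node.end)

    def chain(self) -> list[ConstituencyNode]:
        """Nodes from the widened projection down to the base, inclusive."""
        nodes = [self.base]
        node = self.base
        while node is not self.node and node.parent is not None:
            node = node.parent
            nodes.append(node)
        return nodes


def _is_coordinated(parent: ConstituencyNode, member: ConstituencyNode) -> bool:
    """>= 2 same-label coordinates joined by conjunctions and/or commas.

    Every child must be a coordinate (same label as ``member``) or a
    conjunction/comma terminal; a lone comma after e.g. a fronted
    adjunct is not coordination.
    """
    same = [c for c in parent.children if c.label == member.label]
    if len(same) < 2 or not any(c is member for c in same):
        return False
    has_conj = False
    for child in parent.children:
        if child.label == member.label:
            continue
        if child.is_terminal and (child.label == "CC" or child.token in _CONJ_TOKENS):
            has_conj = True
            continue
        return False
    return has_conj


def maximal_head_projection(
    mention: Mention,
    sentence: AnnotatedSentence,
    lexicon: Optional[TypePreservingLexicon] = None,
    head_table: Optional[HeadTable] = None,
    enabled_exceptions: frozenset[ExceptionCase] = ALL_EXCEPTIONS,
) -> Projection:
    """Largest constituent headed by the mention, widened by exceptions.

    If the mention's tokens do not form a constituent (crossing brackets)
    the smallest covering node is returned with ``aligned=False`` and no
    widening is attempted.
    """
    table = head_table or HeadTable()
    lexicon = lexicon if lexicon is not None else TypePreservingLexicon.default()
    tree = sentence.tree
    span = sentence.token_span_for_chars(mention.span)

    if tree.exact_node(span.start, span.end) is None:
        covering = tree.smallest_covering(span.start, span.end)
        return Projection(covering, span, aligned=False)

    # base: widest node whose lexical head token lies inside the mention
    best: Optional[ConstituencyNode] = None
    for node in tree.iter_nodes():
        head = table.lexical_head(node)
        if span.start <= head.start < span.end:
            if best is None or (node.end - node.start) > (best.end - best.start):
                best = node
            elif (node.end - node.start) == (best.end - best.start) and node.is_ancestor_of(best):
                best = node
    assert best is not None  # every terminal is its own lexical head
    projection = Projection(best, span, aligned=True, base=best)

    changed = True
    while changed:
        changed = False
        node = projection.node
        # resume the head walk: climb while the parent is still headed
        # (lexically) inside the current projection
        parent = node.parent
        while parent is not None and projection.span.contains(
            Span(table.lexical_head(parent).start, table.lexical_head(parent).end)
        ):
            node = parent
            projection.node = node
            parent = node.parent
            changed = True
        # type-preserving phrases (checked first: the template slot is
        # defined over the mention, independent of prior widening)
        if ExceptionCase.TYPE_PRESERVING_CASE in enabled_exceptions:
            for ancestor in node.ancestors():
                if lexicon.matches(ancestor, sentence, mention, span):
                    projection.node = ancestor
                    projection.exceptions.append(ExceptionCase.TYPE_PRESERVING_CASE)
                    changed = True
                    break
            if changed:
                continue
        parent = node.parent
        if parent is None:
            break
        # PP case: mention heads the NP complement of a preposition
        if (
            ExceptionCase.PP_CASE in enabled_exceptions
            and parent.label == "PP"
            and node.label in {"NP", "NX", "QP"}
            and any(c.is_terminal and c.label in _PREP_LABELS for c in parent.children)
        ):
            projection.node = parent
            projection.exceptions.append(ExceptionCase.PP_CASE)
            changed = True
            continue
        # coordination case: mention heads one coordinate
        if ExceptionCase.COORD_CASE in enabled_exceptions and _is_coordinated(parent, node):
            projection.node = parent
            projection.exceptions.append(ExceptionCase.COORD_CASE)
            changed = True
            continue
    return projection


def detect_modification(
    time_proj: Projection,
    event_proj: Projection,
    sentence: AnnotatedSentence,
    head_table: Optional[HeadTable] = None,
) -> bool:
    """Is one projection a modifier attached inside the other?

    True iff one mention's projection is a direct child of a node on the
    other mention's projection chain (widened projection down to its
    base) — i.e. the two phrases combine into a bigger grammatical
    element headed (or type-headed, after exceptions) by one of them.
    """

    def modifies(inner: Projection, outer: Projection) -> bool:
        chain = outer.chain()
        chain_ids = {id(n) for n in chain}
        for node in chain:
            if node.is_terminal:
                continue
            for child in node.children:
                if child is inner.node and id(child) not in chain_ids:
                    return True
        return False

    return modifies(time_proj, event_proj) or modifies(event_proj, time_proj)


@dataclass(frozen=True)
class SharedPredicate:
    predicate_index: int
    time_span: Span  # smallest frame span containing the time mention
    event_span: Span
    via_dependency_fallback: bool = False


def _frame_spans_containing(frame, tokens: Span):
    return [arg for arg in frame.arguments if Span(*arg.span).contains(tokens)]


def detect_shared_predicate(
    time: Mention,
    event: Mention,
    sentence: AnnotatedSentence,
    dependency_fallback: bool = True,
) -> Optional[SharedPredicate]:
    """A predicate of which both mentions are arguments/adjuncts, if any.

    At least one of the two containing spans must be a true ARGUMENT (two
    bare adjuncts of the same verb do not relate to each other).  When the
    sentence carries no predicate frames and ``dependency_fallback`` is
    on, a dependency approximation is used instead: both mentions attach
    to the same verb directly or through a single preposition; such
    results are flagged ``via_dependency_fallback``.
    """
    t_span = sentence.token_span_for_chars(time.span)
    e_span = sentence.token_span_for_chars(event.span)
    for frame in sentence.frames:
        t_args = _frame_spans_containing(frame, t_span)
        e_args = _frame_spans_containing(frame, e_span)
        if not t_args or not e_args:
            continue
        if not any(a.kind == "ARGUMENT" for a in t_args + e_args):
            continue
        t_best = min(t_args, key=lambda a: a.span.end - a.span.start)
        e_best = min(e_args, key=lambda a: a.span.end - a.span.start)
        return SharedPredicate(frame.predicate_index, Span(*t_best.span), Span(*e_best.span))
    if sentence.frames or not dependency_fallback or not sentence.dependencies:
        return None
    head_of = {dep: head for head, dep, _ in sentence.dependencies}

    def attachment_target(span: Span) -> Optional[int]:
        for i in range(span.start, span.end):
            head = head_of.get(i)
            if head is None or span.start <= head < span.end:
                continue
            if head >= 0 and sentence.tokens[head].pos in _PREP_LABELS:
                head = head_of.get(head, -1)
            if head is not None and head >= 0:
                return head
        return None

    t_target = attachment_target(t_span)
    e_target = attachment_target(e_span)
    if (
        t_target is not None
        and t_target == e_target
        and sentence.tokens[t_target].pos.startswith(("VB", "MD"))
    ):
        return SharedPredicate(t_target, t_span, e_span, via_dependency_fallback=True)
    return None


@dataclass
class DirectDecision:
    pair: CandidatePair
    is_direct: bool
    rationale: Rationale
    exception_used: ExceptionCase = ExceptionCase.NONE
    time_projection: Optional[Projection] = None
    event_projection: Optional[Projection] = None
    predicate_index: Optional[int] = None
    used_dependency_fallback: bool = False

    def __post_init__(self) -> None:
        direct_rationales = {Rationale.MODIFICATION, Rationale.SAME_PREDICATE}
        assert self.is_direct == (self.rationale in direct_rationales)


_EXCEPTION_PRIORITY = (
    ExceptionCase.TYPE_PRESERVING_CASE,
    ExceptionCase.COORD_CASE,
    ExceptionCase.PP_CASE,
)


def _combined_exception(*projections: Projection) -> ExceptionCase:
    used = {exc for proj in projections for exc in proj.exceptions}
    for case in _EXCEPTION_PRIORITY:
        if case in used:
            return case
    return ExceptionCase.NONE


def _near_miss(proj: Projection, other_tokens: Span) -> bool:
    """A within-clause phrase links the projection to the other mention.

    Used only to distinguish NOT_HEAD (a syntactic configuration exists
    but the head requirement failed) from NO_SYNTACTIC_LINK.
    """
    node = proj.node.parent
    while node is not None and node.label not in _CLAUSE_LABELS:
        if Span(node.start, node.end).contains(other_tokens):
            return True
        node = node.parent
    return False


def classify_pair(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    lexicon: Optional[TypePreservingLexicon] = None,
    head_table: Optional[HeadTable] = None,
    enabled_exceptions: frozenset[ExceptionCase] = ALL_EXCEPTIONS,
    dependency_fallback: bool = True,
) -> DirectDecision:
    """Decide direct vs. non-direct for one intra-sentential pair.

    Pure function of its inputs; the rationale records the first rule that
    licensed (or blocked) the decision, and ``exception_used`` the
    strongest exception that widened either projection.
    """
    lexicon = lexicon if lexicon is not None else TypePreservingLexicon.default()
    table = head_table or HeadTable()
    time_proj = maximal_head_projection(
        pair.time, sentence, lexicon, table, enabled_exceptions
    )
    event_proj = maximal_head_projection(
        pair.event, sentence, lexicon, table, enabled_exceptions
    )

    if (
        time_proj.aligned
        and event_proj.aligned
        and detect_modification(time_proj, event_proj, sentence, table)
    ):
        return DirectDecision(
            pair,
            True,
            Rationale.MODIFICATION,
            _combined_exception(time_proj, event_proj),
            time_proj,
            event_proj,
        )

    shared = detect_shared_predicate(
        pair.time, pair.event, sentence, dependency_fallback=dependency_fallback
    )
    if shared is not None:
        if shared.via_dependency_fallback:
            head_ok = time_proj.aligned and event_proj.aligned
        else:
            head_ok = (
                time_proj.aligned
                and event_proj.aligned
                and time_proj.span == shared.time_span
                and event_proj.span == shared.event_span
            )
        if head_ok:
            return DirectDecision(
                pair,
                True,
                Rationale.SAME_PREDICATE,
                _combined_exception(time_proj, event_proj),
                time_proj,
                event_proj,
                predicate_index=shared.predicate_index,
                used_dependency_fallback=shared.via_dependency_fallback,
            )
        return DirectDecision(
            pair,
            False,
            Rationale.NOT_HEAD,
            ExceptionCase.NONE,
            time_proj,
            event_proj,
            predicate_index=shared.predicate_index,
            used_dependency_fallback=shared.via_dependency_fallback,
        )

    if _near_miss(time_proj, event_proj.mention_tokens) or _near_miss(
        event_proj, time_proj.mention_tokens
    ):
        return DirectDecision(
            pair, False, Rationale.NOT_HEAD, ExceptionCase.NONE, time_proj, event_proj
        )
    return DirectDecision(
        pair, False, Rationale.NO_SYNTACTIC_LINK, ExceptionCase.NONE, time_proj, event_proj
    )


_ADJ_LABELS = frozenset({"JJ", "JJR", "JJS"})


def _dep_label(child: ConstituencyNode, parent: ConstituencyNode, after_head: bool) -> str:
    if child.is_terminal:
        pos = child.label
        if pos in ("DT", "PRP$", "EX"):
            return "det"
        if pos in _ADJ_LABELS:
            return "amod"
        if pos == "CD":
            return "nummod"
        if pos == "CC":
            return "cc"
        if pos in (".", ",", ":", "POS", "LS"):
            return "punct"
        if pos.startswith("RB"):
            return "advmod"
        if pos.startswith("NN"):
            return "compound"
        return "dep"
    if child.label in ("NP", "NX", "QP"):
        if parent.label in ("S", "SBAR", "SINV") and not after_head:
            return "nsubj"
        if parent.label == "VP":
            return "obj" if after_head else "nsubj"
        if parent.label == "PP":
            return "pobj"
        return "nmod"
    if child.label == "PP":
        return "prep"
    if child.label in ("ADVP", "ADJP"):
        return "advmod"
    if child.label in ("S", "SBAR"):
        return "ccomp"
    return "dep"


def tree_to_dependencies(
    tree: ConstituencyNode, head_table: Optional[HeadTable] = None
) -> list[tuple[int, int, str]]:
    """Head-percolated dependency triples (head index, dependent, label).

    Each non-head child's lexical head attaches to the head child's
    lexical head; the root attaches to -1.  Prepositions head their PPs
    (Stanford-style), matching the fallback path logic in
    :func:`detect_shared_predicate`.
    """
    table = head_table or HeadTable()
    deps: list[tuple[int, int, str]] = []

    def walk(node: ConstituencyNode) -> int:
        if node.is_terminal:
            return node.start
        head_child = table.head_child(node)
        head_index = walk(head_child)
        seen_head = False
        for child in node.children:
            if child is head_child:
                seen_head = True
                continue
            child_index = walk(child)
            deps.append((head_index, child_index, _dep_label(child, node, seen_head)))
        return head_index

    root = walk(tree)
    deps.append((-1, root, "root"))
    deps.sort(key=lambda d: d[1])
    return deps


class DirectRuleEngine:
    """Configured wrapper: decide every candidate pair of a document."""

    def __init__(
        self,
        lexicon: Optional[TypePreservingLexicon] = None,
        head_table: Optional[HeadTable] = None,
        enabled_exceptions: frozenset[ExceptionCase] = ALL_EXCEPTIONS,
        dependency_fallback: bool = True,
    ):
        self.lexicon = lexicon if lexicon is not None else TypePreservingLexicon.default()
        self.head_table = head_table or HeadTable()
        self.enabled_exceptions = enabled_exceptions
        self.dependency_fallback = dependency_fallback

    def decide(self, pair: CandidatePair, sentence: AnnotatedSentence) -> DirectDecision:
        return classify_pair(
            pair,
            sentence,
            self.lexicon,
            self.head_table,
            self.enabled_exceptions,
            self.dependency_fallback,
        )

    def decide_document(self, doc) -> list[DirectDecision]:
        from .model import enumerate_candidates

        return [
            self.decide(pair, doc.sentences[pair.sentence_index])
            for pair in enumerate_candidates(doc)
        ]
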