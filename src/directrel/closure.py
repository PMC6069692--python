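"""Temporal-relation algebra: inverses, composition, transitive closure.

The algebra is deliberately minimal.  Only four compositions are licensed:

    BEFORE  . BEFORE  = BEFORE
    BEFORE  . OVERLAP = BEFORE
    OVERLAP . BEFORE  = BEFORE
    OVERLAP . OVERLAP = OVERLAP

AFTER chains need no table entries of their own: the closure is kept
inverse-closed each pass, so ``{A after B, B after C}`` yields ``A after C``
through the BEFORE entries.  No Allen-style disjunctive inferences are
made; compositions outside the table infer nothing.

The OVERLAP.OVERLAP entry is not sound in general (A and C may fail to
overlap even when both overlap B), so contradictions produced during
closure are retained and surfaced via :func:`find_contradictions` rather
than resolved automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .model import (
    Document,
    RelationGraph,
    RelType,
    StructuralError,
    TemporalRelation,
)

logger = logging.getLogger(__name__)

_INVERSE = {
    RelType.BEFORE: RelType.AFTER,
    RelType.AFTER: RelType.BEFORE,
    RelType.OVERLAP: RelType.OVERLAP,
}

#: The minimal composition table; pairs absent from it compose to nothing.
COMPOSITION_TABLE: dict[tuple[RelType, RelType], RelType] = {
    (RelType.BEFORE, RelType.BEFORE): RelType.BEFORE,
    (RelType.BEFORE, RelType.OVERLAP): RelType.BEFORE,
    (RelType.OVERLAP, RelType.BEFORE): RelType.BEFORE,
    (RelType.OVERLAP, RelType.OVERLAP): RelType.OVERLAP,
}


def invert(relation: TemporalRelation) -> TemporalRelation:
    """Mirror a relation: A before B <-> B after A; overlap is symmetric."""
    return TemporalRelation(
        source=relation.target,
        target=relation.source,
        rel_type=_INVERSE[relation.rel_type],
    )


def compose(first: RelType, second: RelType) -> Optional[RelType]:
    """Type of (A, C) entailed by (A, first, B) and (B, second, C), if any."""
    return COMPOSITION_TABLE.get((first, second))


def transitive_closure(graph: RelationGraph) -> RelationGraph:
    """Smallest superset of ``graph`` closed under inversion and composition.

    Iterates to a fixed point: each pass first closes under inversion, then
    adds every licensed composition along shared middle mentions.  The
    iteration order is deterministic (relations sorted each pass), and the
    result is idempotent and monotone in the input.
    """
    closed: set[TemporalRelation] = set(graph.relations)
    while True:
        added = False
        for rel in sorted(closed):
            inv = invert(rel)
            if inv not in closed:
                closed.add(inv)
                added = True
        by_source: dict[str, list[TemporalRelation]] = {}
        for rel in closed:
            by_source.setdefault(rel.source, []).append(rel)
        new: set[TemporalRelation] = set()
        for first in closed:
            for second in by_source.get(first.target, ()):
                if second.target == first.source:
                    continue
                inferred = compose(first.rel_type, second.rel_type)
                if inferred is None:
                    continue
                candidate = TemporalRelation(first.source, second.target, inferred)
                if candidate not in closed:
                    new.add(candidate)
        if new:
            closed |= new
            added = True
        if not added:
            break
    return RelationGraph(closed, graph.mentions)


@dataclass(frozen=True)
class Contradiction:
    """An ordered mention pair carrying more than one relation type."""

    source: str
    target: str
    rel_types: frozenset[RelType]


def find_contradictions(graph: RelationGraph, close: bool = True) -> list[Contradiction]:
    """Ordered pairs with >= 2 distinct relation types, each reported once.

    The graph is closed first (unless ``close=False``), so e.g. a BEFORE
    cycle surfaces as BEFORE+AFTER on every pair along the cycle.
    """
    relations = transitive_closure(graph).relations if close else graph.relations
    by_pair: dict[tuple[str, str], set[RelType]] = {}
    for rel in relations:
        by_pair.setdefault((rel.source, rel.target), set()).add(rel.rel_type)
    out = [
        Contradiction(source, target, frozenset(types))
        for (source, target), types in sorted(by_pair.items())
        if len(types) > 1
    ]
    if out:
        logger.warning("closure produced %d contradictory pairs", len(out))
    return out


def canonicalize_time_event(
    relation: TemporalRelation, graph: RelationGraph
) -> TemporalRelation:
    """Orient a time-event relation with the time expression as source."""
    source = graph.resolve(relation.source)
    if source.is_time:
        return relation
    return invert(relation)


def filter_intra_sentential_time_event(
    graph: RelationGraph, doc: Document
) -> RelationGraph:
    """Keep relations with one TIME and one EVENT endpoint in one sentence.

    Surviving relations are canonicalized so the time expression is the
    source mention (inverting where needed); everything else — event-event,
    time-time, and cross-sentence links — is dropped.
    """
    mentions = dict(graph.mentions or doc.mentions)
    working = RelationGraph(graph.relations, mentions)
    kept: set[TemporalRelation] = set()
    for rel in working.sorted():
        a = working.resolve(rel.source)
        b = working.resolve(rel.target)
        if {a.category.value, b.category.value} != {"TIME", "EVENT"}:
            continue
        if a.sentence_index != b.sentence_index:
            continue
        kept.add(canonicalize_time_event(rel, working))
    logger.info(
        "intra-sentential time-event filter: kept %d of %d relations",
        len(kept),
        len(graph),
    )
    return RelationGraph(kept, mentions)
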