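import itertools
import random

import pytest

from conftest import (
    REL_NAMES,
    graph_from_triples,
    naive_closure_oracle,
    random_relation_triples,
    triples_from_graph,
)
from directrel.closure import (
    canonicalize_time_event,
    compose,
    filter_intra_sentential_time_event,
    find_contradictions,
    invert,
    transitive_closure,
)
from directrel.model import RelationGraph, RelType, TemporalRelation
from directrel.synthesis import GeneratorConfig, generate_corpus


class TestInvert:
    @pytest.mark.parametrize(
        "rel_type,expected",
        [
            (RelType.BEFORE, RelType.AFTER),
            (RelType.AFTER, RelType.BEFORE),
            (RelType.OVERLAP, RelType.OVERLAP),
        ],
    )
    def test_inverse_types(self, rel_type, expected):
        inverted = invert(TemporalRelation("A", "B", rel_type))
        assert inverted == TemporalRelation("B", "A", expected)

    @pytest.mark.parametrize("rel_type", list(RelType))
    def test_involution(self, rel_type):
        relation = TemporalRelation("A", "B", rel_type)
        assert invert(invert(relation)) == relation


class TestCompose:
    @pytest.mark.parametrize(
        "first,second,expected",
        [
            (RelType.BEFORE, RelType.BEFORE, RelType.BEFORE),
            (RelType.BEFORE, RelType.OVERLAP, RelType.BEFORE),
            (RelType.OVERLAP, RelType.BEFORE, RelType.BEFORE),
            (RelType.OVERLAP, RelType.OVERLAP, RelType.OVERLAP),
        ],
    )
    def test_licensed_compositions(self, first, second, expected):
        assert compose(first, second) is expected

    @pytest.mark.parametrize(
        "first,second",
        [
            (RelType.BEFORE, RelType.AFTER),
            (RelType.AFTER, RelType.BEFORE),
            (RelType.AFTER, RelType.AFTER),
            (RelType.AFTER, RelType.OVERLAP),
            (RelType.OVERLAP, RelType.AFTER),
        ],
    )
    def test_unlicensed_compositions_infer_nothing(self, first, second):
        assert compose(first, second) is None


class TestTransitiveClosure:
    def test_before_overlap_chain(self):
        closed = triples_from_graph(
            transitive_closure(
                graph_from_triples({("A", "B", "BEFORE"), ("B", "C", "OVERLAP")})
            )
        )
        assert {
            ("A", "C", "BEFORE"),
            ("B", "A", "AFTER"),
            ("C", "B", "OVERLAP"),
            ("C", "A", "AFTER"),
        } <= closed

    def test_empty_graph_fixed_point(self):
        assert len(transitive_closure(RelationGraph())) == 0

    def test_after_chains_via_inverse_closure(self):
        # AFTER needs no composition entries of its own
        closed = triples_from_graph(
            transitive_closure(
                graph_from_triples({("A", "B", "AFTER"), ("B", "C", "AFTER")})
            )
        )
        assert ("A", "C", "AFTER") in closed

    def test_matches_oracle_on_200_random_graphs(self):
        rng = random.Random(20240601)
        for _ in range(200):
            seeds = random_relation_triples(rng, max_mentions=8, max_seeds=12)
            closed = triples_from_graph(transitive_closure(graph_from_triples(seeds)))
            assert closed == naive_closure_oracle(seeds)

    def test_matches_oracle_exhaustively_small(self):
        # all graphs over 5 mentions with seed sets of size <= 3
        universe = [
            (a, b, r)
            for a, b in itertools.permutations("ABCDE", 2)
            for r in REL_NAMES
        ]
        for size in (0, 1, 2, 3):
            for seeds in itertools.combinations(universe, size):
                closed = triples_from_graph(
                    transitive_closure(graph_from_triples(seeds))
                )
                assert closed == naive_closure_oracle(set(seeds))

    def test_idempotent_inverse_closed_and_monotone(self):
        rng = random.Random(99)
        for _ in range(50):
            seeds = random_relation_triples(rng, max_mentions=6, max_seeds=8)
            graph = graph_from_triples(seeds)
            closed = transitive_closure(graph)
            assert transitive_closure(closed).relations == closed.relations
            for relation in closed:
                assert invert(relation) in closed
            subset = set(list(seeds)[: len(seeds) // 2])
            sub_closed = transitive_closure(graph_from_triples(subset))
            assert sub_closed.relations <= closed.relations
            assert graph.relations <= closed.relations


class TestFindContradictions:
    def test_direct_conflict_reported_once(self):
        graph = graph_from_triples({("A", "B", "BEFORE"), ("A", "B", "OVERLAP")})
        conflicts = find_contradictions(graph)
        on_ab = [c for c in conflicts if (c.source, c.target) == ("A", "B")]
        assert len(on_ab) == 1
        assert on_ab[0].rel_types == frozenset({RelType.BEFORE, RelType.OVERLAP})

    def test_consistent_chain_has_no_contradictions(self):
        graph = graph_from_triples({("A", "B", "BEFORE"), ("B", "C", "BEFORE")})
        assert find_contradictions(graph) == []

    def test_before_cycle_contradicts_every_pair(self):
        graph = graph_from_triples(
            {("A", "B", "BEFORE"), ("B", "C", "BEFORE"), ("C", "A", "BEFORE")}
        )
        conflicts = find_contradictions(graph)
        pairs = {(c.source, c.target) for c in conflicts}
        # every ordered pair gains both BEFORE and AFTER
        assert pairs == {
            (a, b) for a in "ABC" for b in "ABC" if a != b
        }
        for c in conflicts:
            assert c.rel_types == frozenset({RelType.BEFORE, RelType.AFTER})


class TestIntraSententialFilter:
    @pytest.fixture()
    def doc(self):
        return generate_corpus(GeneratorConfig(n_documents=1, seed=2))[0]

    def _two_events_same_sentence(self, doc):
        events = [m for m in doc.mentions.values() if m.is_event]
        return events[0], events[1]

    def test_event_event_relation_dropped(self, doc):
        e1, e2 = self._two_events_same_sentence(doc)
        e2.sentence_index = e1.sentence_index
        graph = RelationGraph(
            [TemporalRelation(e1.id, e2.id, RelType.OVERLAP)], doc.mentions
        )
        assert len(filter_intra_sentential_time_event(graph, doc)) == 0

    def test_cross_sentence_time_event_dropped(self, doc):
        times = [m for m in doc.mentions.values() if m.is_time]
        events = [m for m in doc.mentions.values() if m.is_event]
        pair = next(
            (t, e)
            for t in times
            for e in events
            if t.sentence_index != e.sentence_index
        )
        graph = RelationGraph(
            [TemporalRelation(pair[0].id, pair[1].id, RelType.BEFORE)], doc.mentions
        )
        assert len(filter_intra_sentential_time_event(graph, doc)) == 0

    def test_orientation_canonicalized_to_time_source(self, doc):
        time = next(m for m in doc.mentions.values() if m.is_time)
        event = next(
            m
            for m in doc.mentions.values()
            if m.is_event and m.sentence_index == time.sentence_index
        )
        graph = RelationGraph(
            [TemporalRelation(event.id, time.id, RelType.AFTER)], doc.mentions
        )
        kept = filter_intra_sentential_time_event(graph, doc)
        assert kept.relations == {TemporalRelation(time.id, event.id, RelType.BEFORE)}

    def test_canonicalize_keeps_time_sourced_relations(self, doc):
        time = next(m for m in doc.mentions.values() if m.is_time)
        event = next(m for m in doc.mentions.values() if m.is_event)
        graph = RelationGraph([], doc.mentions)
        relation = TemporalRelation(time.id, event.id, RelType.BEFORE)
        assert canonicalize_time_event(relation, RelationGraph([], doc.mentions)) == relation
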