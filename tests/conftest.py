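import itertools
import random

import pytest

from directrel.model import RelationGraph, RelType, TemporalRelation
from directrel.rules import DirectRuleEngine
from directrel.synthesis import GeneratorConfig, generate_corpus

REL_NAMES = ("BEFORE", "AFTER", "OVERLAP")


def naive_closure_oracle(relations: set[tuple[str, str, str]]) -> set[tuple[str, str, str]]:
    """Independent fixed-point oracle: literally apply the seven closure
    rules (three inverse rules, four compositions) until nothing changes."""
    inverse = {"BEFORE": "AFTER", "AFTER": "BEFORE", "OVERLAP": "OVERLAP"}
    composition = {
        ("BEFORE", "BEFORE"): "BEFORE",
        ("BEFORE", "OVERLAP"): "BEFORE",
        ("OVERLAP", "BEFORE"): "BEFORE",
        ("OVERLAP", "OVERLAP"): "OVERLAP",
    }
    closed = set(relations)
    while True:
        new = {(b, a, inverse[r]) for (a, b, r) in closed}
        for (a, b, r1) in closed:
            for (b2, c, r2) in closed:
                if b2 == b and c != a and (r1, r2) in composition:
                    new.add((a, c, composition[(r1, r2)]))
        if new <= closed:
            return closed
        closed |= new


def graph_from_triples(triples) -> RelationGraph:
    return RelationGraph(
        TemporalRelation(a, b, RelType(r)) for a, b, r in triples
    )


def triples_from_graph(graph: RelationGraph) -> set[tuple[str, str, str]]:
    return {(r.source, r.target, r.rel_type.value) for r in graph}


def random_relation_triples(rng: random.Random, max_mentions=8, max_seeds=12):
    n = rng.randint(2, max_mentions)
    mentions = "ABCDEFGH"[:n]
    universe = [
        (a, b, r)
        for a, b in itertools.permutations(mentions, 2)
        for r in REL_NAMES
    ]
    k = min(rng.randint(0, max_seeds), len(universe))
    return set(rng.sample(universe, k))


@pytest.fixture(scope="session")
def rule_engine():
    return DirectRuleEngine()


@pytest.fixture(scope="session")
def small_corpus():
    """A compact deterministic synthetic corpus shared across tests."""
    return generate_corpus(GeneratorConfig(n_documents=60, seed=11))


@pytest.fixture(scope="session")
def training_corpus():
    """The full-size synthetic corpus (~2000 candidate pairs)."""
    return generate_corpus(GeneratorConfig(n_documents=500, seed=7))
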