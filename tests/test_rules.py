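import pytest

from directrel.model import (
    Document,
    EventAttrs,
    EventType,
    Mention,
    MentionCategory,
    Span,
    TimeAttrs,
    TimeType,
    enumerate_candidates,
)
from directrel.examples import (
    construction_examples,
    snapshot_examples,
    load_examples,
)
from directrel.rules import (
    ALL_EXCEPTIONS,
    DirectRuleEngine,
    ExceptionCase,
    HeadTable,
    Rationale,
    TypePreservingLexicon,
    classify_pair,
    find_head,
    maximal_head_projection,
    tree_to_dependencies,
)
from directrel.synthesis import SentenceSpec, build_document
from directrel.trees import parse_bracketed_tree


class TestHeadFinding:
    def test_np_head_is_rightmost_nominal(self):
        table = HeadTable()
        tree = parse_bracketed_tree(
            "(NP (NP (NN resection)) (PP (IN of) (NP (DT the) (NN cancer))))"
        )
        assert table.lexical_head(tree).token == "resection"

    def test_pp_head_is_the_preposition(self):
        tree = parse_bracketed_tree("(PP (IN of) (NP (NN diarrhea)))")
        assert find_head(tree).token == "of"

    def test_single_child_node(self):
        tree = parse_bracketed_tree("(NP (NN fever))")
        assert find_head(tree).token == "fever"

    def test_unknown_label_falls_back_to_leftmost(self):
        tree = parse_bracketed_tree("(WEIRD (NN a) (NN b))")
        assert find_head(tree).token == "a"

    def test_vp_head_is_leftmost_verb(self):
        tree = parse_bracketed_tree(
            "(VP (VBD had) (NP (NN fever)) (PP (IN at) (NP (NN noon))))"
        )
        assert HeadTable().lexical_head(tree).token == "had"


def _single_pair(fixture):
    pairs = enumerate_candidates(fixture.doc)
    assert len(pairs) == 1
    return pairs[0], fixture.doc.sentences[0]


class TestWorkedExampleFidelity:
    """The engine reproduces the worked examples' direct/non-direct labels."""

    @pytest.mark.parametrize(
        "fixture", construction_examples(), ids=lambda f: f.name
    )
    def test_construction_verdicts(self, rule_engine, fixture):
        pair, sentence = _single_pair(fixture)
        decision = rule_engine.decide(pair, sentence)
        assert decision.is_direct == fixture.is_direct
        if fixture.expected_rationale is not None:
            assert decision.rationale is fixture.expected_rationale
        if fixture.expected_exception is not None:
            assert decision.exception_used is fixture.expected_exception

    def test_five_direct_four_nondirect(self):
        verdicts = [f.is_direct for f in construction_examples()]
        assert sum(verdicts) == 5 and len(verdicts) == 9

    @pytest.mark.parametrize(
        "fixture", snapshot_examples(), ids=lambda f: f.name
    )
    def test_example_output_directness(self, rule_engine, fixture):
        pair, sentence = _single_pair(fixture)
        decision = rule_engine.decide(pair, sentence)
        assert decision.is_direct == fixture.is_direct

    def test_enumerated_hypotension_sentence_is_nondirect(self, rule_engine):
        fixture = next(f for f in load_examples() if f.name == "snapshot_s3")
        pair, sentence = _single_pair(fixture)
        decision = rule_engine.decide(pair, sentence)
        assert not decision.is_direct
        assert decision.rationale is Rationale.NOT_HEAD

    def test_example_output_gold_labels(self):
        gold = {
            f.name: (f.gold_rel.value if f.gold_rel else None)
            for f in snapshot_examples()
        }
        assert gold == {
            "snapshot_s1": "OVERLAP",
            "snapshot_s2": "OVERLAP",
            "snapshot_s3": None,
            "snapshot_s4": "OVERLAP",
            "snapshot_s5": "AFTER",
            "snapshot_s6": "AFTER",
        }

    def test_decisions_are_deterministic(self, rule_engine):
        for fixture in load_examples():
            pair, sentence = _single_pair(fixture)
            first = rule_engine.decide(pair, sentence)
            second = rule_engine.decide(pair, sentence)
            assert (first.is_direct, first.rationale, first.exception_used) == (
                second.is_direct,
                second.rationale,
                second.exception_used,
            )


def _decide_all(engine):
    out = {}
    for fixture in load_examples():
        pair, sentence = _single_pair(fixture)
        out[fixture.name] = engine.decide(pair, sentence)
    return out


class TestExceptionAblation:
    def test_empty_lexicon_flips_exactly_type_preserving_fixtures(self):
        baseline = _decide_all(DirectRuleEngine())
        ablated = _decide_all(DirectRuleEngine(lexicon=TypePreservingLexicon.empty()))
        flipped = {
            name
            for name in baseline
            if baseline[name].is_direct != ablated[name].is_direct
        }
        used_tp = {
            name
            for name, d in baseline.items()
            if ExceptionCase.TYPE_PRESERVING_CASE
            in d.time_projection.exceptions + d.event_projection.exceptions
        }
        assert flipped == used_tp == {"direct_e"}

    @pytest.mark.parametrize(
        "disabled,expected_construction",
        [
            (ExceptionCase.PP_CASE, "direct_c"),
            (ExceptionCase.COORD_CASE, "direct_d"),
        ],
    )
    def test_disabling_an_exception_flips_exactly_its_users(
        self, disabled, expected_construction
    ):
        baseline = _decide_all(DirectRuleEngine())
        ablated = _decide_all(
            DirectRuleEngine(enabled_exceptions=ALL_EXCEPTIONS - {disabled})
        )
        flipped = {
            name
            for name in baseline
            if baseline[name].is_direct != ablated[name].is_direct
        }
        users = {
            name
            for name, d in baseline.items()
            if d.is_direct
            and disabled
            in d.time_projection.exceptions + d.event_projection.exceptions
        }
        assert flipped == users
        construction_flips = {n for n in flipped if not n.startswith("snapshot")}
        assert construction_flips == {expected_construction}

    def test_exceptions_only_widen_never_flip_direct_to_nondirect(self, small_corpus):
        # monotonicity: enabling exceptions can only add direct verdicts
        restricted = DirectRuleEngine(enabled_exceptions=frozenset())
        full = DirectRuleEngine()
        for doc in small_corpus[:20]:
            for pair in enumerate_candidates(doc):
                sentence = doc.sentences[pair.sentence_index]
                if restricted.decide(pair, sentence).is_direct:
                    assert full.decide(pair, sentence).is_direct


class TestProjections:
    def test_pp_case_widens_to_the_prepositional_phrase(self):
        fixture = next(f for f in load_examples() if f.name == "direct_c")
        pair, sentence = _single_pair(fixture)
        projection = maximal_head_projection(pair.event, sentence)
        assert projection.node.label == "PP"
        assert projection.exceptions == [ExceptionCase.PP_CASE]

    def test_exception_chaining_type_preserving_inside_pp(self):
        # "two days of episodes of vomiting": the type-preserving phrase
        # itself sits inside a PP; widening chains to a fixed point
        spec = SentenceSpec(
            tokens="The patient had two days of episodes of vomiting .".split(),
            tree=(
                "(S (NP (DT The) (NN patient)) (VP (VBD had) "
                "(NP (NP (CD two) (NNS days)) (PP (IN of) "
                "(NP (NP (NNS episodes)) (PP (IN of) (NP (NN vomiting))))))) (. .))"
            ),
            frames=[(2, [("A0", 0, 2, "ARGUMENT"), ("A1", 3, 9, "ARGUMENT")])],
            time_span=Span(3, 5),
            time_type=TimeType.DURATION,
            event_span=Span(8, 9),
            event_type=EventType.PROBLEM,
            rel_type=None,
            construction="chaining",
        )
        doc = build_document("chaining", [spec])
        pair = enumerate_candidates(doc)[0]
        sentence = doc.sentences[0]
        projection = maximal_head_projection(pair.event, sentence)
        assert sentence.tokens[projection.node.start].text == "of"
        assert projection.node.end == 9
        assert ExceptionCase.TYPE_PRESERVING_CASE in projection.exceptions
        assert ExceptionCase.PP_CASE in projection.exceptions
        decision = classify_pair(pair, sentence)
        assert decision.is_direct
        assert decision.rationale is Rationale.MODIFICATION

    def test_crossing_brackets_yield_not_aligned_covering_node(self):
        fixture = next(f for f in load_examples() if f.name == "direct_c")
        doc = fixture.doc
        sentence = doc.sentences[0]
        # a mention spanning "months of" crosses constituent brackets
        start = sentence.tokens[4].span.start
        end = sentence.tokens[5].span.end
        crossing = Mention(
            id="T9",
            doc_id=doc.doc_id,
            span=Span(start, end),
            text=doc.text[start:end],
            category=MentionCategory.TIME,
            sentence_index=0,
            time_attrs=TimeAttrs(TimeType.DURATION),
        )
        projection = maximal_head_projection(crossing, sentence)
        assert not projection.aligned
        assert projection.node.covers(4, 6)


class TestSharedPredicateFallback:
    def test_dependency_fallback_used_when_frames_missing(self, rule_engine):
        fixture = next(f for f in load_examples() if f.name == "direct_b")
        pair, sentence = _single_pair(fixture)
        stripped = Document(
            doc_id="nf",
            text=fixture.doc.text,
            sentences=[sentence],
            mentions=fixture.doc.mentions,
        )
        sentence_nf = stripped.sentences[0]
        frames, sentence_nf.frames = sentence_nf.frames, []
        try:
            decision = rule_engine.decide(pair, sentence_nf)
            assert decision.is_direct
            assert decision.used_dependency_fallback
        finally:
            sentence_nf.frames = frames

    def test_no_frames_no_deps_means_no_shared_predicate(self, rule_engine):
        fixture = next(f for f in load_examples() if f.name == "direct_b")
        pair, sentence = _single_pair(fixture)
        frames, deps = sentence.frames, sentence.dependencies
        sentence.frames, sentence.dependencies = [], []
        try:
            decision = rule_engine.decide(pair, sentence)
            assert not decision.is_direct
        finally:
            sentence.frames, sentence.dependencies = frames, deps


class TestTypePreservingLexicon:
    def test_default_lexicon_parses_published_templates(self):
        lexicon = TypePreservingLexicon.default()
        classes = {(t.category.value, t.subtype) for t in lexicon.templates}
        assert ("EVENT", "TREATMENT") in classes
        assert ("EVENT", "PROBLEM") in classes
        assert ("TIME", "DATE") in classes
        assert ("TIME", "DURATION") in classes

    def test_template_requires_exactly_one_placeholder(self):
        with pytest.raises(ValueError):
            TypePreservingLexicon.from_lines(["episodes of problems"])
        with pytest.raises(ValueError):
            TypePreservingLexicon.from_lines(
                ["[Time-Date] of [Event-Problem]"]
            )

    def test_comments_and_blanks_ignored(self):
        lexicon = TypePreservingLexicon.from_lines(
            ["# comment", "", "flares of [Event-Problem]  # trailing"]
        )
        assert len(lexicon.templates) == 1


class TestDependencyConversion:
    def test_every_token_has_exactly_one_head(self):
        tree = parse_bracketed_tree(
            "(S (NP (DT The) (NN patient)) (VP (VBD had) (NP (NN fever))) (. .))"
        )
        deps = tree_to_dependencies(tree)
        assert sorted(d[1] for d in deps) == list(range(5))
        roots = [d for d in deps if d[0] == -1]
        assert len(roots) == 1 and roots[0][2] == "root"

    def test_verb_is_root_and_subject_attaches_to_it(self):
        tree = parse_bracketed_tree(
            "(S (NP (DT The) (NN patient)) (VP (VBD had) (NP (NN fever))) (. .))"
        )
        deps = {d[1]: (d[0], d[2]) for d in tree_to_dependencies(tree)}
        assert deps[2] == (-1, "root")  # "had"
        assert deps[1] == (2, "nsubj")  # "patient" -> "had"
        assert deps[3] == (2, "obj")  # "fever" -> "had"
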