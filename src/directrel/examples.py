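"""Hand-encoded worked examples of the direct / non-direct definition.

Nine construction fixtures cover the five direct patterns (plain
modification, shared predicate, and the PP / coordination /
type-preserving exception cases) and four non-direct patterns (two
head-requirement violations and two cross-clause configurations), plus
six longer example sentences with known gold relation labels used as
regression snapshots for the classifier.

Trees and predicate frames are hand-built gold readings, not parser
output.  The cross-clause sentences are synthetic constructions of
their configuration (flagged in their notes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import Document, EventType, RelType, Span, TimeType
from .rules import ExceptionCase, Rationale
from .synthesis import SentenceSpec, build_document


@dataclass
class WorkedExample:
    name: str
    provenance: str
    doc: Document
    time_id: str
    event_id: str
    is_direct: bool
    gold_rel: Optional[RelType]
    expected_rationale: Optional[Rationale] = None
    expected_exception: Optional[ExceptionCase] = None
    starts_with_enumeration: bool = False


def _fixture(
    name: str,
    provenance: str,
    tokens: list[str],
    tree: str,
    frames,
    time_span: tuple[int, int],
    time_type: TimeType,
    event_span: tuple[int, int],
    event_type: EventType,
    is_direct: bool,
    gold_rel: Optional[RelType],
    rationale: Optional[Rationale] = None,
    exception: Optional[ExceptionCase] = None,
    enumeration: bool = False,
) -> WorkedExample:
    spec = SentenceSpec(
        tokens=tokens,
        tree=tree,
        frames=frames,
        time_span=Span(*time_span),
        time_type=time_type,
        event_span=Span(*event_span),
        event_type=event_type,
        rel_type=gold_rel if is_direct else None,
        construction=name,
    )
    doc = build_document(name, [spec])
    if enumeration:
        doc.sentences[0].starts_with_enumeration = True
    return WorkedExample(
        name=name,
        provenance=provenance,
        doc=doc,
        time_id="T0",
        event_id="E0",
        is_direct=is_direct,
        gold_rel=gold_rel,
        expected_rationale=rationale,
        expected_exception=exception,
        starts_with_enumeration=enumeration,
    )


def _construction_examples() -> list[WorkedExample]:
    fixtures = []

    # direct (a): time ADVP modifies the event's NP
    fixtures.append(
        _fixture(
            "direct_a",
            "direct example (a): adverbial time phrase modifying the event NP",
            "The patient underwent laparoscopic cholecystectomy 7 weeks prior to admission .".split(),
            "(S (NP (DT The) (NN patient)) (VP (VBD underwent) "
            "(NP (NP (JJ laparoscopic) (NN cholecystectomy)) "
            "(ADVP (NP (CD 7) (NNS weeks)) (JJ prior) (PP (TO to) (NP (NN admission)))))) (. .))",
            [(2, [("A0", 0, 2, "ARGUMENT"), ("A1", 3, 10, "ARGUMENT")])],
            (5, 10),
            TimeType.DURATION,
            (3, 5),
            EventType.TREATMENT,
            True,
            RelType.OVERLAP,
            Rationale.MODIFICATION,
            ExceptionCase.NONE,
        )
    )
    # direct (b): argument and adjunct of the same verb
    fixtures.append(
        _fixture(
            "direct_b",
            "direct example (b): event object and time adjunct of the verb 'check'",
            "Will check creatinine this afternoon .".split(),
            "(S (VP (MD Will) (VP (VB check) (NP (NN creatinine)) "
            "(NP (DT this) (NN afternoon)))) (. .))",
            [(1, [("A1", 2, 3, "ARGUMENT"), ("AM-TMP", 3, 5, "ADJUNCT")])],
            (3, 5),
            TimeType.TIME,
            (2, 3),
            EventType.TEST,
            True,
            RelType.OVERLAP,
            Rationale.SAME_PREDICATE,
            ExceptionCase.NONE,
        )
    )
    # direct (c): PP exception — event heads the NP inside "of <problem>"
    fixtures.append(
        _fixture(
            "direct_c",
            "direct example (c): 'two months of diarrhea', PP exception case",
            "The patient had two months of diarrhea .".split(),
            "(S (NP (DT The) (NN patient)) (VP (VBD had) "
            "(NP (NP (CD two) (NNS months)) (PP (IN of) (NP (NN diarrhea))))) (. .))",
            [(2, [("A0", 0, 2, "ARGUMENT"), ("A1", 3, 7, "ARGUMENT")])],
            (3, 5),
            TimeType.DURATION,
            (6, 7),
            EventType.PROBLEM,
            True,
            RelType.OVERLAP,
            Rationale.MODIFICATION,
            ExceptionCase.PP_CASE,
        )
    )
    # direct (d): coordination exception — event heads one coordinate
    fixtures.append(
        _fixture(
            "direct_d",
            "direct example (d): 'epigastric pain and fever', coordination exception",
            "The patient had epigastric pain and fever this morning .".split(),
            "(S (NP (DT The) (NN patient)) (VP (VBD had) "
            "(NP (NP (JJ epigastric) (NN pain)) (CC and) (NP (NN fever))) "
            "(NP (DT this) (NN morning))) (. .))",
            [
                (
                    2,
                    [
                        ("A0", 0, 2, "ARGUMENT"),
                        ("A1", 3, 7, "ARGUMENT"),
                        ("AM-TMP", 7, 9, "ADJUNCT"),
                    ],
                )
            ],
            (7, 9),
            TimeType.TIME,
            (3, 5),
            EventType.PROBLEM,
            True,
            RelType.OVERLAP,
            Rationale.SAME_PREDICATE,
            ExceptionCase.COORD_CASE,
        )
    )
    # direct (e): type-preserving exception — "an episode of <problem>"
    fixtures.append(
        _fixture(
            "direct_e",
            "direct example (e): 'an episode of epigastric pain', type-preserving exception",
            "She had an episode of epigastric pain this morning .".split(),
            "(S (NP (PRP She)) (VP (VBD had) "
            "(NP (NP (DT an) (NN episode)) (PP (IN of) (NP (JJ epigastric) (NN pain)))) "
            "(NP (DT this) (NN morning))) (. .))",
            [
                (
                    1,
                    [
                        ("A0", 0, 1, "ARGUMENT"),
                        ("A1", 2, 7, "ARGUMENT"),
                        ("AM-TMP", 7, 9, "ADJUNCT"),
                    ],
                )
            ],
            (7, 9),
            TimeType.TIME,
            (5, 7),
            EventType.PROBLEM,
            True,
            RelType.OVERLAP,
            Rationale.SAME_PREDICATE,
            ExceptionCase.TYPE_PRESERVING_CASE,
        )
    )
    # non-direct (a): event is not the head ('resection' is)
    fixtures.append(
        _fixture(
            "nondirect_a",
            "non-direct example (a): time PP modifies 'resection of ...', "
            "whose head is not the event",
            "The patient underwent resection of the left face squamous cell cancer on 2016-03-13 .".split(),
            "(S (NP (DT The) (NN patient)) (VP (VBD underwent) "
            "(NP (NP (NP (NN resection)) (PP (IN of) "
            "(NP (DT the) (JJ left) (NN face) (JJ squamous) (NN cell) (NN cancer)))) "
            "(PP (IN on) (NP (CD 2016-03-13))))) (. .))",
            [(2, [("A0", 0, 2, "ARGUMENT"), ("A1", 3, 13, "ARGUMENT")])],
            (12, 13),
            TimeType.DATE,
            (5, 11),
            EventType.PROBLEM,
            False,
            None,
            Rationale.NOT_HEAD,
        )
    )
    # non-direct (b): time is not the head of the subject NP ('repeat CBC' is)
    fixtures.append(
        _fixture(
            "nondirect_b",
            "non-direct example (b): 'repeat CBC on day of life two showed 41% "
            "neutrophils' — time not head of its NP",
            "Repeat CBC on day of life two showed 41 % neutrophils .".split(),
            "(S (NP (NP (JJ Repeat) (NN CBC)) (PP (IN on) "
            "(NP (NP (NN day)) (PP (IN of) (NP (NN life) (CD two)))))) "
            "(VP (VBD showed) (NP (CD 41) (NN %) (NNS neutrophils))) (. .))",
            [(7, [("A0", 0, 7, "ARGUMENT"), ("A1", 8, 11, "ARGUMENT")])],
            (3, 7),
            TimeType.DATE,
            (10, 11),
            EventType.TEST,
            False,
            None,
            Rationale.NOT_HEAD,
        )
    )
    # non-direct (c)/(d): cross-clause configurations (synthetic
    # reconstructions of the more complex published patterns)
    fixtures.append(
        _fixture(
            "nondirect_c",
            "non-direct example (c): time and event in different coordinated "
            "clauses (synthetic reconstruction)",
            "The patient was admitted on 10-22 , and a chest x-ray showed pneumonia .".split(),
            "(S (S (NP (DT The) (NN patient)) (VP (VBD was) (VP (VBN admitted) "
            "(PP (IN on) (NP (CD 10-22)))))) (, ,) (CC and) "
            "(S (NP (DT a) (NN chest) (NN x-ray)) (VP (VBD showed) (NP (NN pneumonia)))) (. .))",
            [
                (3, [("A1", 0, 2, "ARGUMENT"), ("AM-TMP", 4, 6, "ADJUNCT")]),
                (11, [("A0", 8, 11, "ARGUMENT"), ("A1", 12, 13, "ARGUMENT")]),
            ],
            (5, 6),
            TimeType.DATE,
            (12, 13),
            EventType.PROBLEM,
            False,
            None,
            Rationale.NO_SYNTACTIC_LINK,
        )
    )
    fixtures.append(
        _fixture(
            "nondirect_d",
            "non-direct example (d): event in first clause, time adjunct of "
            "second clause (synthetic reconstruction)",
            "The patient received antibiotics , and on 11-03 she remained stable .".split(),
            "(S (S (NP (DT The) (NN patient)) (VP (VBD received) (NP (NNS antibiotics)))) "
            "(, ,) (CC and) (S (PP (IN on) (NP (CD 11-03))) (NP (PRP she)) "
            "(VP (VBD remained) (ADJP (JJ stable)))) (. .))",
            [
                (2, [("A0", 0, 2, "ARGUMENT"), ("A1", 3, 4, "ARGUMENT")]),
                (9, [("AM-TMP", 6, 8, "ADJUNCT"), ("A0", 8, 9, "ARGUMENT")]),
            ],
            (7, 8),
            TimeType.DATE,
            (3, 4),
            EventType.TREATMENT,
            False,
            None,
            Rationale.NO_SYNTACTIC_LINK,
        )
    )
    return fixtures


def _snapshot_examples() -> list[WorkedExample]:
    """Six longer sentences with known gold labels (classifier snapshots)."""
    fixtures = []
    fixtures.append(
        _fixture(
            "snapshot_s1",
            "example output 1: 'his creatinine rose for three days' — gold overlap",
            "Subsequently his creatinine rose for three days and then stabilized at 10 .".split(),
            "(S (ADVP (RB Subsequently)) (NP (PRP his) (NN creatinine)) "
            "(VP (VP (VBD rose) (PP (IN for) (NP (CD three) (NNS days)))) (CC and) "
            "(VP (ADVP (RB then)) (VBD stabilized) (PP (IN at) (NP (CD 10))))) (. .))",
            [(3, [("A1", 1, 3, "ARGUMENT"), ("AM-TMP", 4, 7, "ADJUNCT")])],
            (5, 7),
            TimeType.DURATION,
            (1, 3),
            EventType.TEST,
            True,
            RelType.OVERLAP,
            Rationale.SAME_PREDICATE,
        )
    )
    fixtures.append(
        _fixture(
            "snapshot_s2",
            "example output 2: 'cardiac catheterization was performed ... on the day "
            "of admission' — gold overlap",
            "Cardiac catheterization was performed without complication on the day of admission .".split(),
            "(S (NP (JJ Cardiac) (NN catheterization)) (VP (VBD was) (VP (VBN performed) "
            "(PP (IN without) (NP (NN complication))) "
            "(PP (IN on) (NP (NP (DT the) (NN day)) (PP (IN of) (NP (NN admission))))))) (. .))",
            [
                (
                    3,
                    [
                        ("A1", 0, 2, "ARGUMENT"),
                        ("AM-MNR", 4, 6, "ADJUNCT"),
                        ("AM-TMP", 6, 11, "ADJUNCT"),
                    ],
                )
            ],
            (7, 9),
            TimeType.DATE,
            (0, 2),
            EventType.TEST,
            True,
            RelType.OVERLAP,
            Rationale.SAME_PREDICATE,
        )
    )
    fixtures.append(
        _fixture(
            "snapshot_s3",
            "example output 3: 'episodes of hypotension with SBPs in the 70s' — "
            "gold non-direct (the event heads neither an argument nor an adjunct)",
            "3. On the morning of 12-01 , the patient had some transient episodes "
            "of hypotension with SBP s in the 70 s .".split(),
            "(S (LST (LS 3.)) (PP (IN On) (NP (NP (DT the) (NN morning)) "
            "(PP (IN of) (NP (CD 12-01))))) (, ,) (NP (DT the) (NN patient)) "
            "(VP (VBD had) (NP (NP (DT some) (JJ transient) (NNS episodes)) "
            "(PP (IN of) (NP (NP (NN hypotension)) (PP (IN with) "
            "(NP (NP (NN SBP) (NNS s)) (PP (IN in) (NP (DT the) (CD 70) (NNS s))))))))) (. .))",
            [
                (
                    9,
                    [
                        ("A0", 7, 9, "ARGUMENT"),
                        ("A1", 10, 22, "ARGUMENT"),
                        ("AM-TMP", 1, 6, "ADJUNCT"),
                    ],
                )
            ],
            (2, 6),
            TimeType.DATE,
            (16, 18),
            EventType.TEST,
            False,
            None,
            Rationale.NOT_HEAD,
            enumeration=True,
        )
    )
    fixtures.append(
        _fixture(
            "snapshot_s4",
            "example output 4: 'Initially on Vanc and Cipro on Friday' — gold "
            "overlap under the reading attaching 'on Friday' to the coordination",
            "Initially on Vanc and Cipro on Friday but then seen by ID .".split(),
            "(S (FRAG (ADVP (RB Initially)) (PP (IN on) "
            "(NP (NP (NP (NN Vanc)) (CC and) (NP (NN Cipro))) "
            "(PP (IN on) (NP (NN Friday)))))) (CC but) "
            "(VP (ADVP (RB then)) (VBN seen) (PP (IN by) (NP (NN ID)))) (. .))",
            [],
            (6, 7),
            TimeType.DATE,
            (2, 3),
            EventType.TREATMENT,
            True,
            RelType.OVERLAP,
            Rationale.MODIFICATION,
            ExceptionCase.COORD_CASE,
        )
    )
    fixtures.append(
        _fixture(
            "snapshot_s5",
            "example output 5: 'a plan for cardioversion in 6 weeks' — gold after "
            "(shortened clinical sentence)",
            "There was a plan for cardioversion in 6 weeks .".split(),
            "(S (NP (EX There)) (VP (VBD was) (NP (NP (DT a) (NN plan)) "
            "(PP (IN for) (NP (NP (NN cardioversion)) (PP (IN in) (NP (CD 6) (NNS weeks))))))) (. .))",
            [],
            (7, 9),
            TimeType.DURATION,
            (5, 6),
            EventType.TREATMENT,
            True,
            RelType.AFTER,
            Rationale.MODIFICATION,
        )
    )
    fixtures.append(
        _fixture(
            "snapshot_s6",
            "example output 6: 'POD# 15/6 , she resumed TF's' — gold after",
            "POD# 15/6 , she resumed TF 's and TPN was tapered again .".split(),
            "(S (S (NP (NN POD#) (CD 15/6)) (, ,) (NP (PRP she)) "
            "(VP (VBD resumed) (NP (NP (NN TF)) (POS 's)))) (CC and) "
            "(S (NP (NN TPN)) (VP (VBD was) (VP (VBN tapered) (ADVP (RB again))))) (. .))",
            [
                (
                    4,
                    [
                        ("A0", 3, 4, "ARGUMENT"),
                        ("A1", 5, 7, "ARGUMENT"),
                        ("AM-TMP", 0, 2, "ADJUNCT"),
                    ],
                )
            ],
            (0, 2),
            TimeType.DATE,
            (5, 6),
            EventType.TREATMENT,
            True,
            RelType.AFTER,
            Rationale.SAME_PREDICATE,
        )
    )
    return fixtures


def load_examples() -> list[WorkedExample]:
    """All hand-encoded fixtures: 9 construction examples + 6 snapshots."""
    return _construction_examples() + _snapshot_examples()


def construction_examples() -> list[WorkedExample]:
    return [f for f in load_examples() if not f.name.startswith("snapshot")]


def snapshot_examples() -> list[WorkedExample]:
    return [f for f in load_examples() if f.name.startswith("snapshot")]
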