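"""Closure-extended evaluation and inter-annotator agreement.

Predicted and gold relation sets are compared as sets after (optionally)
extending each to its transitive closure and restricting both to
canonical intra-sentential time-event relations — so relations entailed
by either side are credited rather than penalized.  Metrics are on the
0-100 percent scale.  Detection-only scores ignore the relation type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from sklearn.metrics import cohen_kappa_score

from .closure import filter_intra_sentential_time_event, transitive_closure
from .model import Document, RelationGraph, RelType


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


@dataclass
class LabelScores:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return _prf(self.tp, self.fp, self.fn)[2]


@dataclass
class EvalReport:
    per_label: dict[str, LabelScores] = field(default_factory=dict)
    micro: LabelScores = field(default_factory=LabelScores)
    detection: LabelScores = field(default_factory=LabelScores)
    gold_contradiction_pairs: int = 0

    @property
    def macro_f1(self) -> float:
        if not self.per_label:
            return 0.0
        return sum(s.f1 for s in self.per_label.values()) / len(self.per_label)

    def to_dict(self) -> dict:
        def scores(s: LabelScores) -> dict:
            return {
                "P": s.precision,
                "R": s.recall,
                "F1": s.f1,
                "TP": s.tp,
                "FP": s.fp,
                "FN": s.fn,
            }

        return {
            "per_label": {label: scores(s) for label, s in self.per_label.items()},
            "micro": scores(self.micro),
            "macro_F1": self.macro_f1,
            "detection": scores(self.detection),
            "gold_contradiction_pairs": self.gold_contradiction_pairs,
        }

    def format(self) -> str:
        lines = [f"{'label':<10} {'P':>7} {'R':>7} {'F1':>7} {'TP':>5} {'FP':>5} {'FN':>5}"]
        for label in sorted(self.per_label):
            s = self.per_label[label]
            lines.append(
                f"{label:<10} {s.precision:7.2f} {s.recall:7.2f} {s.f1:7.2f} "
                f"{s.tp:5d} {s.fp:5d} {s.fn:5d}"
            )
        s = self.micro
        lines.append(
            f"{'micro':<10} {s.precision:7.2f} {s.recall:7.2f} {s.f1:7.2f} "
            f"{s.tp:5d} {s.fp:5d} {s.fn:5d}"
        )
        d = self.detection
        lines.append(
            f"{'detection':<10} {d.precision:7.2f} {d.recall:7.2f} {d.f1:7.2f} "
            f"{d.tp:5d} {d.fp:5d} {d.fn:5d}"
        )
        return "\n".join(lines)


def _processed_set(
    graph: RelationGraph, doc: Document, extend: bool
) -> set[tuple[str, str, str, RelType]]:
    working = RelationGraph(graph.relations, dict(graph.mentions) or dict(doc.mentions))
    if extend:
        working = transitive_closure(working)
    working = filter_intra_sentential_time_event(working, doc)
    return {(doc.doc_id, r.source, r.target, r.rel_type) for r in working}


def evaluate(
    pred: RelationGraph | Sequence[RelationGraph],
    gold: RelationGraph | Sequence[RelationGraph],
    doc: Document | Sequence[Document],
    extend: bool = True,
) -> EvalReport:
    """Score predictions against gold over one document or a corpus.

    With ``extend=True`` (the standard protocol) both sides are closed
    under the relation algebra, then restricted to canonical
    intra-sentential time-event relations, before set comparison.  A
    predicted relation is a typed TP iff the identically oriented
    relation with the same type is in the processed gold set.  When a
    closed gold set carries contradictory types on a pair, all are kept
    (a prediction matching any counts as a TP) and the pair count is
    surfaced in the report.
    """
    preds = [pred] if isinstance(pred, RelationGraph) else list(pred)
    golds = [gold] if isinstance(gold, RelationGraph) else list(gold)
    docs = [doc] if isinstance(doc, Document) else list(doc)
    if not len(preds) == len(golds) == len(docs):
        raise ValueError("pred, gold and doc sequences must align")

    pred_set: set[tuple[str, str, str, RelType]] = set()
    gold_set: set[tuple[str, str, str, RelType]] = set()
    for p, g, d in zip(preds, golds, docs):
        pred_set |= _processed_set(p, d, extend)
        gold_set |= _processed_set(g, d, extend)

    report = EvalReport()
    gold_pairs: dict[tuple[str, str, str], set[RelType]] = {}
    for doc_id, source, target, rel_type in gold_set:
        gold_pairs.setdefault((doc_id, source, target), set()).add(rel_type)
    report.gold_contradiction_pairs = sum(
        1 for types in gold_pairs.values() if len(types) > 1
    )

    labels = sorted({item[3] for item in pred_set | gold_set}, key=lambda r: r.value)
    for label in labels:
        p_l = {item for item in pred_set if item[3] == label}
        g_l = {item for item in gold_set if item[3] == label}
        scores = LabelScores(
            tp=len(p_l & g_l), fp=len(p_l - g_l), fn=len(g_l - p_l)
        )
        report.per_label[label.value] = scores
        report.micro.tp += scores.tp
        report.micro.fp += scores.fp
        report.micro.fn += scores.fn

    pred_untyped = {item[:3] for item in pred_set}
    gold_untyped = {item[:3] for item in gold_set}
    report.detection = LabelScores(
        tp=len(pred_untyped & gold_untyped),
        fp=len(pred_untyped - gold_untyped),
        fn=len(gold_untyped - pred_untyped),
    )
    return report


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two raters, on the 0-100 scale.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from the
    marginal products; degenerate p_e = 1 returns 100 for perfect
    agreement.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("label sequences are empty")
    n = len(a)
    alphabet = sorted({*a, *b}, key=str)
    p_e = sum(
        (a.count(label) / n) * (b.count(label) / n) for label in alphabet
    )
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    if p_e >= 1.0 - 1e-12:
        return 100.0 if p_o >= 1.0 - 1e-12 else 0.0
    return 100.0 * float(cohen_kappa_score(a, b))


def kappa_direct_pairs(
    decisions_a: Sequence[tuple[bool, Optional[RelType]]],
    decisions_b: Sequence[tuple[bool, Optional[RelType]]],
) -> dict[str, float]:
    """Agreement over reviewed pairs, binary and 4-way (typed) variants.

    Each decision is (is_direct, rel_type or None); the 4-way alphabet is
    {direct:before, direct:after, direct:overlap, non-direct}.
    """

    def typed(decision: tuple[bool, Optional[RelType]]) -> str:
        is_direct, rel = decision
        return f"direct:{rel.value.lower()}" if is_direct and rel else "non-direct"

    binary_a = [d[0] for d in decisions_a]
    binary_b = [d[0] for d in decisions_b]
    return {
        "binary": cohens_kappa(binary_a, binary_b),
        "typed": cohens_kappa([typed(d) for d in decisions_a], [typed(d) for d in decisions_b]),
    }
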