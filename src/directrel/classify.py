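"""Cost-sensitive four-way classification of candidate time-event pairs.

The classifier decides, for each intra-sentential (time expression,
event mention) pair, one of BEFORE / AFTER / OVERLAP / NO_RELATION.
Because overlap dominates the direct-relation label distribution
(roughly two thirds of typed pairs), training is cost-sensitive: each
class receives a weight inversely proportional to its frequency,

    w(t) = N / (K * count(t)),

normalized so the balanced case gives weight 1 for every class (which
keeps the meaning of the regularization constant stable).  The model is
a linear one-vs-rest SVM; decision-value ties are broken by a fixed
label priority (majority class first).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_extraction import DictVectorizer
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .features import extract_features
from .io_formats import default_medication_frequencies
from .model import (
    NO_RELATION,
    CandidatePair,
    Document,
    EventType,
    RelationGraph,
    RelType,
    TemporalRelation,
    TimeType,
    enumerate_candidates,
)
from .rules import DirectRuleEngine

LABELS = (RelType.OVERLAP.value, RelType.BEFORE.value, RelType.AFTER.value, NO_RELATION)

#: Tie-break priority for equal decision values: majority class first.
DEFAULT_TIE_PRIORITY = LABELS

MODEL_FORMAT_VERSION = 1


def _as_int32_csr(matrix):
    # liblinear accepts only 32-bit sparse indices
    matrix = matrix.tocsr()
    matrix.indices = matrix.indices.astype(np.int32)
    matrix.indptr = matrix.indptr.astype(np.int32)
    return matrix


def compute_class_weights(label_counts: dict[str, int]) -> dict[str, float]:
    """Weights inversely proportional to class frequency.

    ``w(t) = N / (K * count(t))`` with K the number of labels, so equal
    counts give 1.0 for every class and ``sum count(t) * w(t) = N``.
    """
    for label, count in label_counts.items():
        if count <= 0:
            raise ValueError(f"degenerate training set: class {label!r} has count {count}")
    total = sum(label_counts.values())
    k = len(label_counts)
    return {label: total / (k * count) for label, count in label_counts.items()}


class DirectRelationClassifier(BaseEstimator, ClassifierMixin):
    """Linear one-vs-rest SVM over sparse feature dicts.

    Parameters
    ----------
    C : float or None
        Fixed regularization constant; when None, selected from
        ``c_grid`` by stratified ``cv``-fold cross-validation on the
        training data (seeded by ``random_state``).
    class_weighting : bool
        Apply inverse-frequency class weights (cost-sensitive learning).
    tie_priority : sequence of str
        Label order used to resolve exact decision-value ties.
    """

    def __init__(
        self,
        C: Optional[float] = None,
        c_grid: Sequence[float] = (0.1, 1.0, 10.0),
        cv: int = 5,
        class_weighting: bool = True,
        tie_priority: Sequence[str] = DEFAULT_TIE_PRIORITY,
        random_state: int = 0,
        max_iter: int = 5000,
    ):
        self.C = C
        self.c_grid = c_grid
        self.cv = cv
        self.class_weighting = class_weighting
        self.tie_priority = tie_priority
        self.random_state = random_state
        self.max_iter = max_iter

    def _make_svc(self, C: float, class_weight: Optional[dict[str, float]]) -> LinearSVC:
        return LinearSVC(
            C=C,
            class_weight=class_weight,
            random_state=self.random_state,
            max_iter=self.max_iter,
        )

    def fit(self, X: Sequence[dict[str, float]], y: Sequence[str]) -> "DirectRelationClassifier":
        y = list(y)
        if len(set(y)) < 2:
            raise ValueError("training data must contain at least 2 distinct labels")
        self.vectorizer_ = DictVectorizer(sparse=True)
        matrix = _as_int32_csr(self.vectorizer_.fit_transform(X))
        counts = {label: y.count(label) for label in sorted(set(y))}
        self.class_weight_ = compute_class_weights(counts) if self.class_weighting else None
        if self.C is not None:
            self.C_ = float(self.C)
        else:
            best = None
            n_splits = min(self.cv, min(counts.values()))
            for c in self.c_grid:
                if n_splits >= 2:
                    folds = StratifiedKFold(
                        n_splits=n_splits, shuffle=True, random_state=self.random_state
                    )
                    score = cross_val_score(
                        self._make_svc(c, self.class_weight_),
                        matrix,
                        np.asarray(y),
                        cv=folds,
                        scoring="f1_macro",
                    ).mean()
                else:
                    score = 0.0
                if best is None or score > best[0] + 1e-12:
                    best = (score, c)
            self.C_ = float(best[1])
        self.model_ = self._make_svc(self.C_, self.class_weight_)
        self.model_.fit(matrix, np.asarray(y))
        self.classes_ = self.model_.classes_
        return self

    def decision_function(self, X: Sequence[dict[str, float]]) -> np.ndarray:
        check_is_fitted(self, "model_")
        matrix = _as_int32_csr(self.vectorizer_.transform(X))
        scores = self.model_.decision_function(matrix)
        if scores.ndim == 1:  # binary case: expand to per-class columns
            scores = np.column_stack([-scores, scores])
        return scores

    def predict(self, X: Sequence[dict[str, float]]) -> np.ndarray:
        scores = self.decision_function(X)
        priority = {label: i for i, label in enumerate(self.tie_priority)}
        rank = np.array([priority.get(c, len(priority)) for c in self.classes_])
        out = []
        for row in scores:
            best = max(
                range(len(self.classes_)), key=lambda k: (row[k], -rank[k])
            )
            out.append(self.classes_[best])
        return np.asarray(out)

    # -- persistence (versioned JSON, documented in docs/formats.md) ------

    def save(self, path) -> None:
        check_is_fitted(self, "model_")
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "params": {
                "C": self.C,
                "c_grid": list(self.c_grid),
                "cv": self.cv,
                "class_weighting": self.class_weighting,
                "tie_priority": list(self.tie_priority),
                "random_state": self.random_state,
                "max_iter": self.max_iter,
            },
            "C_": self.C_,
            "class_weight_": self.class_weight_,
            "feature_names": list(self.vectorizer_.get_feature_names_out()),
            "classes": [str(c) for c in self.classes_],
            "coef": np.atleast_2d(self.model_.coef_).tolist(),
            "intercept": np.atleast_1d(self.model_.intercept_).tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "DirectRelationClassifier":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {payload.get('format_version')}"
            )
        clf = cls(**payload["params"])
        clf.C_ = payload["C_"]
        clf.class_weight_ = payload["class_weight_"]
        clf.vectorizer_ = DictVectorizer(sparse=True)
        clf.vectorizer_.fit([{name: 1.0 for name in payload["feature_names"]}])
        clf.classes_ = np.asarray(payload["classes"])
        model = clf._make_svc(clf.C_, clf.class_weight_)
        model.coef_ = np.asarray(payload["coef"])
        model.intercept_ = np.asarray(payload["intercept"])
        model.classes_ = clf.classes_
        clf.model_ = model
        return clf


# ---------------------------------------------------------------------------
# Instance construction


@dataclass
class LabeledInstance:
    pair: CandidatePair
    features: dict[str, float]
    label: str
    doc_id: str = ""


def gold_label_index(doc: Document) -> dict[tuple[str, str], str]:
    """(time id, event id) -> relation type for the gold direct set."""
    index: dict[tuple[str, str], str] = {}
    if doc.gold_relations is None:
        return index
    for rel in doc.gold_relations:
        source = doc.mention(rel.source)
        if source.is_time:
            index[(rel.source, rel.target)] = rel.rel_type.value
        else:
            from .closure import invert

            flipped = invert(rel)
            index[(flipped.source, flipped.target)] = flipped.rel_type.value
    return index


def build_instances(
    docs: Sequence[Document],
    rule_engine: Optional[DirectRuleEngine] = None,
    include_rule_features: bool = True,
    negative_ratio: Optional[float] = None,
    seed: int = 0,
) -> list[LabeledInstance]:
    """Labeled instances for every candidate pair of every document.

    Pairs absent from the gold direct set are NO_RELATION instances; all
    negatives are kept unless ``negative_ratio`` caps them at that
    multiple of the positive count (sampled deterministically by seed).
    """
    engine = rule_engine or DirectRuleEngine()
    instances: list[LabeledInstance] = []
    for doc in docs:
        gold = gold_label_index(doc)
        for pair in enumerate_candidates(doc):
            sentence = doc.sentences[pair.sentence_index]
            decision = engine.decide(pair, sentence) if include_rule_features else None
            instances.append(
                LabeledInstance(
                    pair=pair,
                    features=extract_features(pair, sentence, decision),
                    label=gold.get(pair.key, NO_RELATION),
                    doc_id=doc.doc_id,
                )
            )
    if negative_ratio is not None:
        positives = [inst for inst in instances if inst.label != NO_RELATION]
        negatives = [inst for inst in instances if inst.label == NO_RELATION]
        cap = int(negative_ratio * len(positives))
        if len(negatives) > cap:
            rng = random.Random(seed)
            negatives = rng.sample(negatives, cap)
        instances = positives + negatives
    return instances


def train(
    instances: Sequence[LabeledInstance], **params
) -> DirectRelationClassifier:
    """Fit a cost-sensitive classifier on labeled instances."""
    clf = DirectRelationClassifier(**params)
    clf.fit([inst.features for inst in instances], [inst.label for inst in instances])
    return clf


# ---------------------------------------------------------------------------
# Post-processing


def _tokens_between(doc: Document, pair: CandidatePair) -> list[str]:
    sentence = doc.sentences[pair.sentence_index]
    lo = min(pair.time.span.end, pair.event.span.end)
    hi = max(pair.time.span.start, pair.event.span.start)
    return [t.text for t in sentence.tokens if lo <= t.span.start and t.span.end <= hi]


def postprocess(
    predictions: Sequence[tuple[CandidatePair, str]],
    doc: Document,
    medication_frequency_lexicon: Optional[Sequence[str]] = None,
) -> list[tuple[CandidatePair, str]]:
    """Remove two known false-positive patterns from predicted relations.

    A predicted relation is reset to NO_RELATION when (a) the event is a
    problem, the time expression is of frequency type and its text is a
    medication-frequency form ("bid", "prn", "q2h", ...), or (b) the word
    "where" occurs strictly between the two mentions.  The filter only
    ever removes and is idempotent.
    """
    lexicon = {
        entry.lower()
        for entry in (
            medication_frequency_lexicon
            if medication_frequency_lexicon is not None
            else default_medication_frequencies()
        )
    }
    out: list[tuple[CandidatePair, str]] = []
    for pair, label in predictions:
        if label != NO_RELATION:
            event_attrs = pair.event.event_attrs
            time_attrs = pair.time.time_attrs
            med_freq = (
                event_attrs is not None
                and event_attrs.event_type is EventType.PROBLEM
                and time_attrs is not None
                and time_attrs.time_type is TimeType.FREQUENCY
                and pair.time.text.lower() in lexicon
            )
            where_between = any(
                tok.lower() == "where" for tok in _tokens_between(doc, pair)
            )
            if med_freq or where_between:
                label = NO_RELATION
        out.append((pair, label))
    return out


def predict_document(
    clf: DirectRelationClassifier,
    doc: Document,
    rule_engine: Optional[DirectRuleEngine] = None,
    include_rule_features: bool = True,
    apply_postprocessing: bool = True,
    medication_frequency_lexicon: Optional[Sequence[str]] = None,
) -> tuple[list[tuple[CandidatePair, str]], RelationGraph]:
    """Classify every candidate pair of a document.

    Returns the per-pair labels (after post-processing) and the typed
    relations as a graph with the time expression as source.
    """
    engine = rule_engine or DirectRuleEngine()
    pairs = enumerate_candidates(doc)
    if not pairs:
        return [], RelationGraph(mentions=doc.mentions)
    feats = []
    for pair in pairs:
        sentence = doc.sentences[pair.sentence_index]
        decision = engine.decide(pair, sentence) if include_rule_features else None
        feats.append(extract_features(pair, sentence, decision))
    labels = clf.predict(feats)
    predictions = list(zip(pairs, (str(label) for label in labels)))
    if apply_postprocessing:
        predictions = postprocess(predictions, doc, medication_frequency_lexicon)
    graph = RelationGraph(mentions=doc.mentions)
    for pair, label in predictions:
        if label != NO_RELATION:
            graph.add(TemporalRelation(pair.time.id, pair.event.id, RelType(label)))
    return predictions, graph
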