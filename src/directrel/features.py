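"""Sparse feature extraction for candidate time-event pairs.

Feature families (binary indicators unless noted):

* mention attributes — time-expression type; event type, polarity,
  modality;
* lexical context — bags of mention tokens, the three preceding and
  following tokens of each mention, the bag and count (numeric) of
  in-between tokens;
* shallow syntax — POS tags of mention tokens, number of in-between
  punctuation tokens (numeric), tense and position (before / between /
  after the pair) of the sentence's verbs;
* discourse — section label, enumeration-start and colon-end flags;
* dependency — surface form and POS of the lowest common ancestor of the
  two mentions in the dependency tree, and whether a noun lies on the
  path between them;
* semantic roles — the predicate of each mention and a shared-predicate
  indicator;
* optional rule-engine aids — the deterministic direct/non-direct
  verdict, its rationale and exception case.

Extraction is a pure function of the pair and its sentence analysis;
families whose analysis layer is missing are simply omitted.
"""

from __future__ import annotations

import string
from typing import Optional

from .model import AnnotatedSentence, CandidatePair, Span
from .rules import DirectDecision

_PUNCT = set(string.punctuation)

_TENSE_BY_POS = {
    "VBD": "past",
    "VBN": "past",
    "VBZ": "present",
    "VBP": "present",
    "MD": "modal",
    "VB": "base",
    "VBG": "gerund",
}


def _bag(features: dict, prefix: str, tokens) -> None:
    for token in tokens:
        features[f"{prefix}={token.lower()}"] = 1.0


def _context(features: dict, prefix: str, sentence: AnnotatedSentence, span: Span) -> None:
    for offset in range(1, 4):
        i = span.start - offset
        if i >= 0:
            features[f"{prefix}_prev{offset}={sentence.tokens[i].text.lower()}"] = 1.0
        j = span.end + offset - 1
        if j < len(sentence.tokens):
            features[f"{prefix}_next{offset}={sentence.tokens[j].text.lower()}"] = 1.0


def _dependency_features(
    features: dict, sentence: AnnotatedSentence, t_span: Span, e_span: Span
) -> None:
    head_of = {dep: head for head, dep, _ in sentence.dependencies}
    if not head_of:
        return

    def chain(start: int) -> list[int]:
        out = [start]
        seen = {start}
        node = start
        while True:
            node = head_of.get(node, -1)
            if node < 0 or node in seen:
                break
            out.append(node)
            seen.add(node)
        return out

    def representative(span: Span) -> int:
        for i in range(span.start, span.end):
            head = head_of.get(i, -1)
            if head < 0 or not span.start <= head < span.end:
                return i
        return span.end - 1

    t_chain = chain(representative(t_span))
    e_chain = chain(representative(e_span))
    common = next((n for n in t_chain if n in set(e_chain)), None)
    if common is None:
        return
    token = sentence.tokens[common]
    features[f"dep_lca={token.text.lower()}"] = 1.0
    features[f"dep_lca_pos={token.pos}"] = 1.0
    path = t_chain[1 : t_chain.index(common)] + e_chain[1 : e_chain.index(common)]
    noun_on_path = any(
        sentence.tokens[i].pos.startswith("NN")
        and not t_span.start <= i < t_span.end
        and not e_span.start <= i < e_span.end
        for i in path + [common]
    )
    features["dep_noun_on_path"] = 1.0 if noun_on_path else 0.0


def extract_features(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    decision: Optional[DirectDecision] = None,
) -> dict[str, float]:
    features: dict[str, float] = {}
    time, event = pair.time, pair.event

    if time.time_attrs is not None:
        features[f"time_type={time.time_attrs.time_type.value.lower()}"] = 1.0
    if event.event_attrs is not None:
        attrs = event.event_attrs
        features[f"event_type={attrs.event_type.value.lower()}"] = 1.0
        features[f"event_polarity={attrs.polarity.lower()}"] = 1.0
        features[f"event_modality={attrs.modality.lower()}"] = 1.0

    t_span = sentence.token_span_for_chars(time.span)
    e_span = sentence.token_span_for_chars(event.span)
    t_tokens = sentence.tokens[t_span.start : t_span.end]
    e_tokens = sentence.tokens[e_span.start : e_span.end]

    _bag(features, "t_tok", (t.text for t in t_tokens))
    _bag(features, "e_tok", (t.text for t in e_tokens))
    _context(features, "t", sentence, t_span)
    _context(features, "e", sentence, e_span)

    lo = min(t_span.end, e_span.end)
    hi = max(t_span.start, e_span.start)
    between = sentence.tokens[lo:hi]
    _bag(features, "between", (t.text for t in between))
    features["between_count"] = float(len(between))
    features["between_punct_count"] = float(
        sum(1 for t in between if all(c in _PUNCT for c in t.text))
    )

    _bag(features, "t_pos", (t.pos for t in t_tokens))
    _bag(features, "e_pos", (t.pos for t in e_tokens))

    for i, token in enumerate(sentence.tokens):
        tense = _TENSE_BY_POS.get(token.pos)
        if tense is None:
            continue
        if i < min(t_span.start, e_span.start):
            position = "before"
        elif i >= max(t_span.end, e_span.end):
            position = "after"
        else:
            position = "between"
        features[f"verb={tense}|{position}"] = 1.0

    if sentence.section_label:
        features[f"section={sentence.section_label.lower()}"] = 1.0
    if sentence.starts_with_enumeration:
        features["sent_enum_start"] = 1.0
    if sentence.ends_with_colon:
        features["sent_colon_end"] = 1.0

    _dependency_features(features, sentence, t_span, e_span)

    if sentence.frames:
        t_preds = set()
        e_preds = set()
        for frame in sentence.frames:
            spans = [Span(*a.span) for a in frame.arguments]
            lemma = sentence.tokens[frame.predicate_index].text.lower()
            if any(s.contains(t_span) for s in spans):
                t_preds.add(lemma)
            if any(s.contains(e_span) for s in spans):
                e_preds.add(lemma)
        for lemma in t_preds:
            features[f"t_pred={lemma}"] = 1.0
        for lemma in e_preds:
            features[f"e_pred={lemma}"] = 1.0
        if t_preds & e_preds:
            features["same_predicate"] = 1.0

    if decision is not None:
        features["rule_is_direct"] = 1.0 if decision.is_direct else 0.0
        features[f"rule_rationale={decision.rationale.value.lower()}"] = 1.0
        features[f"rule_exception={decision.exception_used.value.lower()}"] = 1.0

    return features
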