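# Methods

## Task and model

The package decides, for every intra-sentential pair of a time expression
and a clinical event mention, whether the pair stands in a *direct*
temporal relation, and if so of which type (before / after / overlap).
Directness is a syntactic notion: either one mention's phrase modifies the
other's, or both are arguments/adjuncts of one predicate, with each
mention required to head its phrase up to three exception cases (PP
complement, coordination, type-preserving phrase). Typing, by contrast,
often needs lexical or world knowledge ("resumed X on ⟨date⟩" implies
*after*), so it is learned by a classifier rather than decided by rules.

## Relation algebra and closure

The algebra stores only the three inverse rules and four composition
entries (BEFORE∘BEFORE, BEFORE∘OVERLAP, OVERLAP∘BEFORE → BEFORE;
OVERLAP∘OVERLAP → OVERLAP). AFTER needs no entries: the closure is kept
inverse-closed every pass, so AFTER chains are entailed through their
BEFORE mirrors. This minimal table is deliberately *not* the Allen
interval algebra — compositions outside the table infer nothing, and no
disjunctive labels exist. The fixed-point iteration is deterministic
(relations sorted each pass), idempotent and monotone; an independent
naive oracle (literal rule application to a fixed point) is kept in the
test suite and checked exhaustively on all graphs over 5 mentions with up
to 3 seed relations and on random graphs over 8 mentions.

OVERLAP∘OVERLAP is not sound in general (A and C need not overlap when
both overlap B). Human annotators repair such artifacts during review; an
automatic engine cannot, so contradictory pairs (any ordered pair carrying
two types after closure) are retained, flagged, and reported — never
silently resolved. Evaluation likewise keeps all gold types on a
contradictory pair and credits a prediction matching any of them, with the
pair count surfaced in the report.

## Head finding and projections

Constituency heads use a small per-label table of direction + priority
groups (NP: rightmost nominal, else rightmost nested NP; PP: leftmost
preposition; VP: leftmost verb; fallback: leftmost child). The table is an
operationalization choice — headedness is assumed by the definition of
directness but no procedure is prescribed — and is editable via
`HeadTable`. One deliberate deviation from Collins-style rules: possessive
`POS` is not a head candidate, so "TF 's" is headed by the noun, which is
what the head requirement needs for possessive event mentions.

A mention's *maximal head projection* is the largest constituent whose
lexical head token lies inside the mention. Widening then iterates to a
fixed point over: (a) the climb to any parent still lexically headed
inside the current projection, (b) the type-preserving lexicon (checked
first, since its placeholder is defined over the mention itself), (c) the
PP case, (d) the coordination case. Chaining of exception cases (e.g. a
type-preserving phrase inside a PP) is permitted; this is a design choice
covered by a dedicated test, as the definition is silent on it.
Coordination requires ≥ 2 same-label children joined *only* by
conjunctions/commas — a lone comma after a fronted adjunct is not
coordination. If the mention's tokens form no constituent (crossing
brackets), the smallest covering node is returned flagged `NOT_ALIGNED`
and treated as failing the head requirement.

Modification holds iff one mention's projection is a direct child of a
node on the other mention's projection chain (widened node down to base).
The shared-predicate rule accepts a frame in which both mentions lie
within role spans, at least one being a true argument; the head
requirement then demands each projection equal its role span exactly.
When a shared configuration exists but a head check fails, the decision is
`NOT_HEAD`; when no within-clause phrase links the two mentions at all, it
is `NO_SYNTACTIC_LINK`. When a sentence carries no frames, a flagged
dependency fallback approximates rule 2 (both mentions attach to the same
verb directly or through one preposition); its use is recorded on the
decision.

## Classifier

A linear one-vs-rest SVM (liblinear) over sparse binary/count features:
mention attributes, token bags and ±3-token contexts, in-between bag and
counts, POS tags, verb tense×position, section label, sentence flags,
dependency lowest-common-ancestor and noun-on-path, semantic-role
predicates and a shared-predicate flag, plus (optionally, on by default)
the rule engine's verdict as features — whether the original system fed
its rule analysis to the learner is unknown, so this is switchable for
ablation. Cost-sensitive weights are w(t) = N/(K·count(t)), normalized so
the balanced case gives 1.0 — "inversely proportional" fixes only ratios,
and this scale keeps the meaning of the regularization constant stable
(Σ count·w = N holds by construction). The regularization constant is
chosen by seeded 5-fold cross-validation over {0.1, 1, 10} unless fixed.
Exact decision-value ties break by fixed priority OVERLAP > BEFORE >
AFTER > NO_RELATION (majority class first). Every enumerated candidate
pair absent from the gold direct set is a NO_RELATION training instance;
no negative subsampling by default (a ratio option exists). Two
deterministic post-processing filters remove known false-positive
patterns: problem-type events paired with medication-frequency time
expressions ("bid", "prn", "q2h", … — a shipped, extensible lexicon), and
pairs with "where" strictly between the mentions. The filters only remove
and are idempotent.

## Evaluation

Predicted and gold sets are each closed under the algebra, restricted to
canonical intra-sentential time–event relations (time expression as
source), and compared as sets; metrics are on the 0–100 percent scale,
with typed per-label, micro, and detection-only (type-ignored) scores.
Closing both sides credits entailed relations instead of penalizing them.
Cohen's kappa is a thin wrapper over scikit-learn's implementation
(×100, with the degenerate p_e = 1 perfect-agreement case returning 100);
agreement over reviewed pairs is emitted both binary
(direct/non-direct) and 4-way (direct:before/after/overlap, non-direct),
since either convention is defensible.

## Synthetic data: what it emulates and what it does not

The generator emits documents of 2–6 template sentences, each containing
one time–event pair built from one of eight constructions: five direct
(modification via a temporal PP, shared predicate with a PP or bare-NP
adjunct, PP-exception "⟨duration⟩ of ⟨problem⟩", coordination with the
event as *first* conjunct so the exception is genuinely required,
type-preserving "an episode of ⟨problem⟩") and three non-direct (head
violation "resection of ⟨problem⟩ on ⟨date⟩", cross-clause, and a
medication-frequency distractor that also exercises the post-processing
filter). Default construction weights are 0.2/0.2/0.1/0.1/0.1 direct and
0.1/0.1/0.1 non-direct; relation types are drawn 66/18/16
overlap/before/after, matching the overlap-heavy imbalance of clinical
time–event links, sampled before the construction so the mix is exact in
expectation regardless of per-template type support. Trees, frames and
head-percolated dependencies are emitted consistently with the surface
string, so rule-engine accuracy on clean output is 100% *by construction*
— any failure is a rule-engine bug. A `tree_noise` knob flattens a
sentence's parse with the given probability (coupled across noise levels
by the shared seed), degrading accuracy monotonically.

The relation type is signalled by the planted temporal preposition
(on/at vs. before vs. after), making labels a deterministic function of
features. Consequently, perfect held-out scores on synthetic corpora
validate the pipeline's correctness and determinism — candidate
enumeration, projections, features, weighting, decoding, closure-extended
scoring — and say nothing about accuracy on real clinical text, where
parser error, attachment ambiguity and knowledge-dependent typing
dominate. The generator does not model de-identified clinical language,
misspellings, section diversity beyond a three-header rotation, or parse
errors other than the flattening knob.

Scale: the default corpus is 500 documents (~2000 candidate pairs), which
the whole pipeline (generation, rules, training with CV, scoring)
processes in a few seconds; tests and the acceptance script use this size.

## Numerical and degenerate-input choices

- Character offsets are 0-based half-open over raw text; token and frame
  spans are half-open token-index intervals. Readers convert once.
- Mentions crossing sentence boundaries are assigned to the sentence
  containing their start, with a warning; mentions outside every sentence
  are structural errors.
- TLINK labels outside the canonical three are collapsed by an explicit,
  editable map (SIMULTANEOUS/DURING/BEGUN_BY/ENDED_BY → OVERLAP,
  BEFORE_OVERLAP → BEFORE); an unmapped label is a hard error, never a
  silent skip.
- Event types beyond problem/test/treatment map to OTHER and still
  enumerate as candidates.
- Zero class counts abort weight computation (degenerate training set);
  single-label training data is rejected.
- F1 is defined as 0 when P + R = 0; kappa returns 100 for perfect
  agreement even when chance agreement is 1.

## Known limitations

- The type-preserving lexicon ships only the published example templates
  plus one variant; real coverage needs a domain-curated list (the file
  format makes that a one-line-per-template edit).
- Attachment ambiguity is resolved by trusting the provided parse; the
  engine never re-attaches, so parser errors propagate (this is the
  dominant error source on real text).
- The dependency fallback for the shared-predicate rule is a length-≤2
  path heuristic, strictly weaker than semantic role labels.
- Typing accuracy on real text is bounded by the features' ability to
  proxy for domain knowledge; the synthetic corpus cannot measure that
  gap.
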