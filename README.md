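# directrel

Identification of **direct temporal relations** between time expressions and
clinical event mentions in narrative text (e.g. discharge summaries).

## The problem

Clinical temporal-relation corpora annotate every inferable TLINK between
mentions — up to N(N−1)/2 links for N mentions — mixing relations that are
explicitly realized in the text with relations that require multi-step
inference. Systems trained on the mixed set perform poorly on both. This
package targets the *direct* subset: intra-sentential relations between a
time expression *t* (date / time / duration / frequency) and an event
mention *e* (problem / test / treatment) that are realized through local
syntax, typed as one of

> *t* **before** *e* · *t* **after** *e* · *t* **overlap** *e*.

A pair (*t*, *e*) is **direct** iff

1. the phrase headed by *t* modifies the phrase headed by *e* (or vice
   versa), or
2. *t* and *e* are arguments or adjuncts of the same predicate,

where each mention must be the *head* of its phrase, relaxed by three
exception cases: the mention heads the NP inside a PP (so the projection
widens to the PP), the mention heads one coordinate of a coordination, or
the mention sits in a *type-preserving phrase* ("an episode of
⟨problem⟩", "period of ⟨duration⟩") whose semantic type is still the
mention's. Exceptions chain to a fixed point.

The package provides, as composable library modules with a CLI on top:

- **closure algebra** — inverse rules plus the minimal composition table
  (BEFORE∘BEFORE = BEFORE, BEFORE∘OVERLAP = BEFORE, OVERLAP∘BEFORE = BEFORE,
  OVERLAP∘OVERLAP = OVERLAP), transitive closure to a fixed point,
  contradiction reporting, and the intra-sentential time–event filter used
  in corpus construction;
- **rule engine** — deterministic direct/non-direct decisions from gold or
  parsed constituency trees, predicate–argument frames and dependencies;
- **classifier** — a cost-sensitive linear SVM (scikit-learn estimator,
  `fit`/`predict`) over lexical, syntactic, discourse, dependency and
  semantic-role features, with class weights w(t) = N/(K·count(t)) and two
  deterministic post-processing filters (medication-frequency pairs,
  in-between "where");
- **evaluation** — closure-extended P/R/F1 (typed, per-type and
  detection-only, percent scale) and Cohen's kappa;
- **synthetic corpus generator** — seeded templates that emit documents
  with gold trees, frames and relations covering every rule path, with a
  66/18/16 overlap/before/after type mix.

## Worked example

```bash
directrel gen-fixtures --out-dir corpus --n-documents 30 --seed 7
directrel train   --corpus-dir corpus --model-out model.json --seed 7 --c 1.0
directrel predict --corpus-dir corpus --model model.json --out-dir preds
directrel evaluate --corpus-dir corpus --pred-dir preds
```

prints (on the generated corpus, which carries gold analyses):

```
wrote 30 documents, 113 candidate pairs, to corpus
trained on 113 instances (C=1.0); model saved to model.json
wrote 78 predicted relations to preds
label            P       R      F1    TP    FP    FN
AFTER       100.00  100.00  100.00    17     0     0
BEFORE      100.00  100.00  100.00     8     0     0
OVERLAP     100.00  100.00  100.00    53     0     0
micro       100.00  100.00  100.00    78     0     0
detection   100.00  100.00  100.00    78     0     0
```

113 candidate pairs are enumerated (every intra-sentential time–event
pair); 78 of them are direct in gold, and with gold trees/frames the
trained model recovers all of them with the correct type — by design, the
generator's labels are a deterministic function of planted features, so
perfect scores here validate the machinery, not clinical-text performance
(see `docs/methods.md` for what this does and does not show). The same
stages run from Python:

```python
from directrel import (GeneratorConfig, generate_corpus, build_instances,
                       train, predict_document, evaluate)
docs = generate_corpus(GeneratorConfig(n_documents=30, seed=7))
clf = train(build_instances(docs), C=1.0)
_, graph = predict_document(clf, docs[0])
```

For real corpora, annotation XML and per-sentence linguistic analyses
(tokens, POS, bracketed parse, dependencies, predicate frames) are read
from the formats documented in `docs/formats.md`; the package deliberately
bundles no parser or semantic role labeler.

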