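# File formats

The fixtures produced by `directrel gen-fixtures` are the normative
examples of both formats. All offsets are 0-based half-open character
intervals over the raw text unless stated otherwise.

## Annotation XML

One file per document:

```xml
<?xml version="1.0" encoding="UTF-8"?>
<ClinicalNarrativeTemporalAnnotation id="synth-0000">
  <TEXT>HOSPITAL COURSE:
The patient underwent chemotherapy on Friday .</TEXT>
  <TAGS>
    <EVENT id="E0" start="39" end="51" text="chemotherapy"
           type="TREATMENT" polarity="POS" modality="FACTUAL"/>
    <TIMEX3 id="T0" start="55" end="61" text="Friday"
            type="DATE" val="" mod=""/>
    <TLINK id="TL0" fromID="T0" fromText="Friday"
           toID="E0" toText="chemotherapy" type="OVERLAP"/>
  </TAGS>
</ClinicalNarrativeTemporalAnnotation>
```

- `TIMEX3.type` ∈ {DATE, TIME, DURATION, FREQUENCY}; `EVENT.type` is
  PROBLEM / TEST / TREATMENT (anything else is read as OTHER).
- `text` must equal the document substring at `[start, end)`; a mismatch
  is a structural error.
- `TLINK.type` is collapsed onto {BEFORE, AFTER, OVERLAP} through an
  editable label map (default: SIMULTANEOUS, DURING, BEGUN_BY, ENDED_BY →
  OVERLAP; BEFORE_OVERLAP → BEFORE). Unmapped labels are a hard error.
- TLINKs referencing unknown mention ids are structural errors.
- Prediction files are the same dialect with only `TLINK` elements.

## Sentence-analysis sidecar (`*.analyses.jsonl`)

JSON lines, one record per sentence, schema version 1:

```json
{"schema_version": 1, "start": 17, "end": 63,
 "tokens": [{"text": "The", "start": 17, "end": 20, "pos": "DT"}, ...],
 "tree": "(S (NP (DT The) (NN patient)) (VP ...) (. .))",
 "deps": [[2, 1, "nsubj"], [-1, 2, "root"], ...],
 "frames": [{"predicate": 2,
             "args": [{"role": "A1", "start": 3, "end": 4, "kind": "ARGUMENT"},
                      {"role": "AM-TMP", "start": 4, "end": 6, "kind": "ADJUNCT"}]}],
 "section": "HOSPITAL COURSE",
 "starts_with_enumeration": false, "ends_with_colon": false}
```

- `tree` is Penn-Treebank-style bracketing; its leaves must align
  one-to-one with `tokens`.
- `deps` triples are `[head, dependent, label]` token indices, `-1` for
  the root. Prepositions head their PPs (Stanford-style).
- Frame `start`/`end` and the frame `predicate` are **token indices**
  (half-open), not character offsets. `kind` is ARGUMENT or ADJUNCT.
- Analyses are inputs: any tokenizer/parser/SRL stack may populate the
  sidecar; the package bundles none.

## Lexicon files

Plain text, one entry per line, `#` starts a comment:

- `type_preserving.txt` — templates with one `[Event-…]`/`[Time-…]`
  placeholder, e.g. `episodes of [Event-Problem]`.
- `section_headers.txt` — header names matched against line-initial
  `HEADER:` lines.
- `med_frequency.txt` — medication-frequency time-expression surfaces.

## Model file

`DirectRelationClassifier.save()` writes versioned JSON
(`format_version: 1`) holding the constructor params, selected C, class
weights, feature names, class list, and the linear coefficients;
`DirectRelationClassifier.load()` restores a model that predicts
identically.
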