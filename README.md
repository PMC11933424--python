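# pktables

Classify tables from pharmacokinetic (PK) literature into three categories —
**PK** (in vivo PK parameter estimates), **DEMOGRAPHICS** (study population
characteristics), or **OTHER** — with an end-to-end pipeline:

1. **`table_io`** — parse JATS/PMC article XML into structured tables
   (caption, header rows, rectangular body grid, footer), expanding
   rowspan/colspan and excluding image-only table-wraps; JSONL corpus I/O.
2. **`serialization`** — pipe-delimited markdown serialization and the seven
   table-field variants (caption, header row, first column, first few rows,
   full table, footer, caption + table).
3. **`features`** — bag-of-words vectors over a lexicographic vocabulary, and
   a pluggable encoder contract with 512-token chunking plus mean/max pooling
   for long tables (a deterministic `HashingEncoder` ships as the reference
   backend; no pretrained weights are bundled).
4. **`classifier`** — class-weighted gradient-boosted classifier (multinomial
   cross-entropy, learning rate 0.1, macro one-vs-rest AUC-ROC early stopping
   with 10-round patience, 1000-round cap), the published 3600-candidate
   hyperparameter grid, 10-fold CV grid search selecting on mean macro-F1,
   and a persisted pipeline bundle (model + vocabulary + field config).
5. **`llm_fallback`** — zero-shot chain-of-thought classification through an
   abstract LLM backend; the prompt template is an editable text asset;
   deterministic mock backends (static / scripted / oracle) for offline use.
6. **`hybrid`** — confidence-gated routing: predictions below a threshold are
   double-checked by the fallback; threshold selection over {0.85, 0.9, 0.95}
   maximizes captured supervised errors under a routed-fraction cap (10%).
7. **`evaluation`** — largest-remainder stratified 60/20/20 splits, per-class
   precision/recall/F1 with macro/micro aggregation, Cohen's kappa.
8. **`fixtures`** — synthetic labeled tables and JATS articles with a
   controllable lexical-noise separability dial and concentration-only hard
   negatives, so everything runs and tests offline.

The boosted ensemble is realized with scikit-learn's
`GradientBoostingClassifier`; the boosted-tree hyperparameter names
(`min_child_weight`, `gamma`, `colsample_bytree`, …) map onto the equivalent
estimator settings.

## CLI

```sh
# generate a synthetic labeled corpus (and optionally a JATS article)
pktables make-fixtures --total 600 --noise 0.2 --seed 7 --out corpus.jsonl \
    --jats article.xml --image-only 2

# train the supervised pipeline (caption + table field, BoW features)
pktables train --corpus corpus.jsonl --field caption_plus_table --out model.bin

# tune hyperparameters with stratified k-fold CV ("table1" = the full grid)
pktables tune --corpus corpus.jsonl --grid small --folds 10 --seed 7 --out cv.json

# predict, and combine with a (mock) zero-shot fallback
pktables predict --model model.bin --in corpus.jsonl --out preds.jsonl
pktables classify-hybrid --model model.bin --threshold 0.9 --backend mock \
    --script responses.json --in corpus.jsonl --out decisions.jsonl

# score predictions against gold labels
pktables evaluate --pred preds.jsonl --gold corpus.jsonl --out report.json
```

A real LLM backend is any object with a `name` and `complete(prompt) -> str`;
pass it to `pktables.hybrid.hybrid_classify` programmatically. Externally
released corpora with a different JSON schema can be ingested through
`pktables.zenodo.load_external_corpus` with a configurable field mapping.

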