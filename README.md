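# delirium-nlp

Sentence-level detection of delirium in unstructured clinical notes.

Delirium — acute, fluctuating inattention and global cognitive
dysfunction in hospitalized patients — is badly under-captured by ICD
billing codes (high specificity, very low sensitivity), yet it is
described extensively in free-text notes by physicians, nurses, and
therapists.  This package implements an end-to-end pipeline for turning
those notes into patient- and day-level delirium determinations, aimed
at EHR researchers who need a delirium phenotype at scale:

1. **Corpus handling** (`delirium_nlp.corpus`) — read JSONL/CSV note
   corpora, segment sentences with exact character offsets (clinical
   abbreviation-aware), and extract every sentence containing one of 23
   delirium keywords ("delirium", "confused", "agitated", …, "waxing
   and waning mental status") via case-insensitive stem-prefix matching.
2. **Always patterns** (`delirium_nlp.patterns`) — expert-authored
   regular expressions that force a label whenever they match.
   Propagating them over unlabeled keyword sentences yields weak labels;
   disagreeing patterns route sentences to a conflict queue instead.
3. **Active learning** (`delirium_nlp.active_learning`) — an iterative
   labeling loop: propagate patterns, train a model, score the unlabeled
   pool, project sentence embeddings to a 2-D map (UMAP, or PCA for
   deterministic runs), and query the next batch half by prediction
   entropy H(p) = −Σᵢ pᵢ ln pᵢ and half by greedy farthest-point
   (k-center) coverage of the map.
4. **Classifiers** (`delirium_nlp.classifiers`) — three 3-class models
   assigning each keyword sentence POSITIVE (delirium asserted),
   NEGATIVE (explicitly denied), or NEITHER (keyword used in an
   unrelated sense):
   * a linear SVM over a bag of unigrams+bigrams, one-vs-rest margins
     softmax-calibrated to the probability simplex;
   * a 3-layer bidirectional LSTM, classifying from the hidden state at
     the keyword position;
   * a 3-layer multi-head self-attention (transformer) encoder,
     likewise keyword-anchored.
   The neural models run on an in-package NumPy autodiff core — no GPU
   or deep-learning framework required — and support fine-tuning on new
   labels at a reduced learning rate.
5. **Evaluation** (`delirium_nlp.evaluation`) — 60/20/20 splits,
   micro/macro F1, row/column-normalized confusion matrices, one-vs-rest
   ROC/AUC, percentile-bootstrap 95% CIs, and per-category pairwise
   interrater agreement.
6. **Associations** (`delirium_nlp.associations`) — aggregate sentence
   predictions to per-patient ±1 flags (+1 iff any POSITIVE sentence)
   and measure construct validity against independent indicators (ICD
   codes, deliriogenic medications, restraint/sitter orders, mortality,
   CAM assessments) with the φ coefficient; compute delirium-day burden
   and mortality-by-burden curves.
7. **Synthetic cohorts** (`delirium_nlp.synthetic`) — because real
   delirium notes are protected, a grammar-based generator produces
   multi-note patient records with known sentence labels, latent
   delirium status, and correlated binary indicators, so every stage is
   testable end to end.

## Worked example

```python
from delirium_nlp import corpus, synthetic, classifiers
from delirium_nlp.patterns import propagate
from delirium_nlp.evaluation import f1_scores
from delirium_nlp.synthetic import GeneratorConfig, default_always_patterns

# 1. generate a 200-patient synthetic cohort and pull out keyword sentences
cohort = synthetic.generate(GeneratorConfig(n_patients=200, seed=0))
sentences = corpus.extract_keyword_sentences(cohort.notes)
print(f"{len(cohort.notes)} notes -> {len(sentences)} keyword sentences")

# 2. weak labels from the bundled always patterns
labeled, conflicts = propagate(default_always_patterns(), sentences)
print(f"always patterns labeled {len(labeled)} sentences "
      f"({len(conflicts)} conflicts)")

# 3. train the self-attention classifier on the pattern labels
config = classifiers.ModelConfig(model_kind="attention", hidden_size=32,
                                 max_epochs=4, learning_rate=2e-3, seed=0)
model = classifiers.train(config, labeled)

# 4. score every keyword sentence and compare with ground truth
preds = classifiers.predict(model, sentences)
truth = cohort.truth_label_map()
report = f1_scores([truth[s.key] for s in sentences],
                   [p.predicted_label for p in preds])
print(f"micro F1 {report.micro_f1:.3f}, macro F1 {report.macro_f1:.3f}")
```

Output:

```
1091 notes -> 1041 keyword sentences
always patterns labeled 898 sentences (0 conflicts)
micro F1 1.000, macro F1 1.000
```

The always patterns cover ~86% of keyword sentences here, and the
classifier trained only on those weak labels generalizes perfectly to
the uncovered ones — on the generator's *separable* regime, which is
exactly what it is designed to verify.  The F1 of 1.000 says the
pipeline's plumbing is lossless, not that real clinical language is
this easy; the "noisy" regime and the coverage analysis exercise the
harder cases.

A `delirium-nlp` console script exposes the same pipeline as
subcommands (`synth`, `extract`, `propagate`, `coverage`, `train`,
`predict`, `finetune`, `evaluate`, `associate`, `query`, `loop`); run
`delirium-nlp --help` for details.

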