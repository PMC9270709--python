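# Methods

This note documents the models and procedures implemented in
`delirium_nlp`, the design choices that were genuinely open, and what
the synthetic experiments do and do not establish.

## Problem setting

The unit of analysis is the *keyword sentence*: any sentence in a
clinical note containing one of 23 delirium-related terms.  Each such
sentence belongs to one of three classes — POSITIVE (the note asserts
delirium or a delirium symptom is present), NEGATIVE (explicitly
denied), NEITHER (the keyword is used in an unrelated sense, e.g.
"family confused about the schedule").  Plain negation detection is not
enough for this phenotype: many non-delirium usages carry no negation
cue at all, which is why a 3-class formulation is used throughout.
Patient-level detection is then the disjunction: a patient is flagged
+1 when at least one sentence anywhere in their notes is classified
POSITIVE, −1 otherwise.

## Keyword extraction

Matching is case-insensitive, anchored at a left word boundary, and
stem-prefix: the entry `disorient` matches `disoriented` and
`disorientation`; multi-word entries ("altered mental status") allow
any whitespace run between words.  The published keyword list mixes
stems and inflected forms, and prefix matching covers both without a
morphological analyzer.  Reported spans cover the whole token run, so
the lowercased slice always begins with the lexicon entry.  Coordinates
are 0-based half-open everywhere.

Sentence segmentation is rule-based: hard newlines and `[.!?]` runs
followed by whitespace end a sentence, except after entries of a
clinical abbreviation stop-list (`Dr.`, `pt.`, `b.i.d.`, single-letter
initials, dotted shorthand).  Clinical notes are telegraphic; a trained
sentence model would add nondeterminism without materially changing the
keyword-sentence inventory.  Spans are exact offsets into the note, so
segmentation is lossless and auditable.

## Always patterns

An always pattern is a regular expression plus a label, with the
semantics "a match warrants this label unconditionally".  Patterns are
applied to sentence text only, case-insensitively, through Python's
`re` dialect; a pattern that does not compile fails loudly.  When
patterns with *different* labels match the same sentence, the sentence
goes to a conflict stream for human review rather than being labeled by
majority: any disagreement invalidates the "always" guarantee.
Coverage (the fraction of keyword sentences matched by ≥ 1 pattern,
irrespective of agreement) is monotone in the pattern set and is
tracked per active-learning round.

## Classifiers

All three kinds consume the same lowercase alphanumeric-run
tokenization and emit a `PredictionScore`: a simplex triple over
(POSITIVE, NEGATIVE, NEITHER), the argmax label (ties break in that
fixed order), and a fixed-length sentence embedding for the
active-learning map.

**Linear n-gram kind.**  Unigram+bigram count vectors (vocabulary
frozen on the training set; unseen n-grams ignored at predict time)
feed three one-vs-rest linear SVMs (`LinearSVC`, balanced class
weights, C = 1).  The signed margins to the three hyperplanes are
mapped to the simplex by a softmax — the margin-to-score link is a
design choice; softmax is monotone in each margin and needs no held-out
calibration set.  A class absent from training receives a fixed margin
of −8.  The sentence embedding is the ℓ2-normalized count vector sent
through a seeded Gaussian random projection to `hidden_size` dims.
Fine-tuning performs hinge-loss subgradient steps warm-started from the
current hyperplanes.

**Recurrent kind.**  A 3-layer bidirectional LSTM (per-direction width
`hidden_size/2`, concatenated), forget-gate bias initialized to 1,
padding handled by state freezing so batch composition cannot leak into
results.  Classification reads the final-layer hidden vector at the
*keyword anchor*: the first lexicon match of the sentence, mean-pooled
over its token span (multi-word keywords span several tokens; the first
match is the anchor because a single anchor position is required).

**Attention kind.**  A 3-layer post-norm transformer encoder
(multi-head self-attention, default 4 heads; sinusoidal positions; FFN
width 2×; pad keys masked), with the same keyword-anchor classification
head.  Word-vector initialization from a word2vec-format text file is
an optional hook (`init_vectors`); the default is seeded random
initialization so that no download or external artifact is ever
required.

Both neural kinds train with Adam on class-weighted (inverse-frequency)
cross-entropy — the label mixture is heavily skewed (~88/8/4), and
macro F1 is a headline metric, so minority classes are up-weighted.
They run on a small reverse-mode autodiff core written directly over
NumPy in float64: at the sentence lengths (~10–20 tokens) and hidden
sizes (32–128) this problem needs, a deep-learning framework adds
nothing but nondeterminism and a heavyweight dependency, and every
gradient in the core is verified against central differences in the
test suite.  Training is bitwise reproducible given the config seed.

Defaults: `hidden_size=128`, `max_len=128` tokens (right truncation
that never cuts the anchor — the window shifts left to end at the
anchor instead), `batch_size=64`, `learning_rate=2e-3`, Adam.  Tests
and the acceptance script use `hidden_size=32` and ~4 epochs: on the
synthetic regimes this reaches ceiling accuracy while keeping
single-CPU runtimes in seconds, and the problem sizes used are stated
with each experiment.  Fine-tuning copies the model and continues
optimization at `0.1×` the learning rate; zero epochs is the identity.

## Active learning

The loop mirrors iterative gold-standard construction: a seeded random
batch starts it (no model exists yet); every later round propagates the
always patterns over the unlabeled pool, trains the configured model on
all labels so far, scores the remaining pool, projects the prediction
embeddings to 2-D, and queries the next batch — ⌈k/2⌉ sentences by
prediction entropy (H = −Σ pᵢ ln pᵢ, maximal at ln 3) and ⌊k/2⌋ by
greedy farthest-point selection on the map, seeded from the point
farthest from the centroid of labeled points, ties to the lowest index.
The k-center greedy is the standard realization of a diversity query;
its selections match a from-scratch brute-force greedy on every tested
instance.  The default map is UMAP; a seeded PCA projection behind the
same interface gives fully deterministic loops for tests and small
runs.  The recurrent model is the default loop model (configurable; the
experiments below use the linear kind for speed).  An oracle failure
aborts the loop and returns the partial history.

## Evaluation

Micro F1 pools one-vs-rest counts globally (TP / (TP + (FP+FN)/2));
for single-label multiclass data it equals accuracy, and the suite
checks that identity on random label vectors rather than assuming it.
Macro F1 averages the three per-class F1s unweighted, POSITIVE
included.  Precision/recall/F1 use the 0-when-undefined convention.
One-vs-rest ROC/AUC uses threshold grouping and the trapezoidal rule,
and equals the Mann–Whitney U statistic normalized by n⁺·n⁻ (checked by
exhaustive pair counting).  Bootstrap CIs are percentile 2.5/97.5 over
seeded resamples of evaluation rows (the sentence is the resampling
unit; patients are the unit for association CIs), default
`n_boot=1000`; a metric undefined on >10% of resamples is an error.
Interrater agreement is per-category positive specific agreement,
2·|both c| / (|a=c| + |b=c|) — equivalently the between-rater F1 —
reported only for categories at least one rater used.  The 60/20/20
split gives validation and test `round(0.2·n)` items each and the
remainder to train, reproducing the corpus-scale sizes
(120,283 / 40,094 / 40,094 at n = 200,471) exactly.

## Associations

φ is computed from the 2×2 table, (ad − bc)/√((a+b)(c+d)(a+c)(b+d)),
and equals the Pearson correlation of the two ±1 vectors (property-
tested).  A zero margin returns φ = 0 with an explicit warning rather
than an error, because patient-level bootstrap resamples routinely
produce degenerate tables.  Delirium burden counts distinct calendar
days (note-local dates) with ≥ 1 POSITIVE sentence; mortality is
summarized per burden bin 0…K+ with bin counts reported.  CAM is
treated as a one-time patient-level assessment compared against
any-positive-sentence during the stay.  Medication and restraint
indicators are consumed as precomputed ±1 columns — deriving them from
order tables is out of scope.

## Synthetic cohorts

The generator emulates what the pipeline needs from real data, nothing
more: patients with a latent delirium flag (default prevalence 0.35),
1 note per day over a 3–8-day stay, a contiguous 1–4-day delirium
episode for delirious patients, and slot-filled template sentences.
Delirium-day notes emit keyword sentences at rate 0.8; other notes at
0.8 × 0.015 — keyword density concentrating in delirious patients'
notes is what makes a high global positive share attainable, as in real
corpora.  The global class mixture (default 0.88/0.08/0.04, the
imbalance seen in labeled clinical data) is honored exactly in
expectation by solving the per-delirium-slot positive rate against the
realized share of keyword slots on delirium days; an unreachable
mixture raises instead of silently drifting.  POSITIVE sentences occur
only in delirious patients' delirium-day notes.

Indicators are Bernoulli draws from the latent flag at configured
sensitivity/specificity — ICD defaults to sensitivity 0.2 /
specificity 0.98, reflecting the poor recall of delirium billing codes;
medication 0.65/0.85, restraints 0.55/0.90, CAM 0.80/0.90 are
plausible mid-range values for correlates of delirium, chosen once.
Mortality is logistic in true delirium days (base log-odds −2.5,
+0.35/day).  `expected_phi` gives the closed-form φ of a *perfect*
detector against each noisy indicator from the cell probabilities
(πs, π(1−s), (1−π)(1−t), (1−π)t); the pipeline recovers it because
any-positive-sentence detection is essentially exact on the separable
regime.

The "noisy" regime adds hedged sentences ("Possibly confused…",
"Rule out delirium.") on delirium days whose true label is drawn at
random between POSITIVE and NEGATIVE, creating irreducible ambiguity to
exercise classifier differences; the mixture calibration is only
approximate there.

**What passing tests show — and don't.**  Template grammars make class
membership recoverable from short lexical contexts, so ceiling
accuracies on the separable regime validate the pipeline's mechanics
(lossless offsets, anchoring, label plumbing, calibration), not
clinical performance.  Real notes have misspellings, section headers,
copy-forward text, and negation scopes spanning clauses; none are
modeled.  Association magnitudes depend entirely on the configured
sensitivities/specificities and are meaningful only relative to the
analytic oracle and to each other (e.g. NLP φ exceeding ICD φ when ICD
sensitivity is low).

## Numerical conventions and degenerate inputs

Simplex tolerance 1e−6; argmax ties in fixed class order; entropy with
0·ln 0 = 0; zero rows/columns in confusion normalization stay zero;
coverage of an empty sentence set is an error (undefined fraction);
training on a single class is refused with a diagnostic; a non-finite
training loss aborts with a diagnostic rather than returning a broken
model.  All stochastic components (generator, splits, training
shuffles, bootstrap, queries, projections) take explicit seeds, and
single-threaded float64 NumPy keeps runs reproducible on one machine.

## Known limitations

* Sentence segmentation can under-split around mid-text abbreviations
  ("saw pt. Then…") — a deliberate trade for determinism.
* The always-pattern bank bundled with the generator is illustrative,
  matched to the template grammar; it is not a clinically validated
  rule set.
* The linear kind's probability calibration (softmax over margins) is
  ordinal, not calibrated in the reliability sense.
* UMAP maps are reproducible per environment but not guaranteed
  bit-identical across library versions; the PCA fallback is.
* The active-learning non-inferiority experiments use the linear model;
  neural loop rounds are supported but slower.
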