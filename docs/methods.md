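# Methods

This note records the model, the parameter choices that matter, what the
synthetic corpus does and does not emulate, and the numerical conventions the
implementation commits to. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Scoring model

A narrative's internal (episodic) and external (non-episodic) content is
estimated in two steps.

**Sentence classification.** Narratives are split into sentences and each
sentence is assigned one of four proportion classes, `P0`, `P50`, `P75`,
`P100`, with representative internal fractions 0, 0.5, 0.75 and 1. The label
set reflects the empirical clustering of sentence-level internal fractions in
manually scored interview data: sentences are mostly purely internal or
purely external, with mixed sentences clustering near one-half and
three-quarters internal. There is deliberately no 25% class; external-heavy
mixed sentences map to `P0` or `P50` by nearness. Binning is
nearest-center, with ties resolved toward the more internal class
(0.25 → `P50`, 0.625 → `P75`, 0.875 → `P100`); any tie rule is admissible,
this one is fixed and tested.

**Aggregation.** A sentence of class `c` with `w` words contributes
`f(c)·w` internal and `(1−f(c))·w` external words; per-narrative totals are
the sums over sentences. Word counts proxy manual detail counts; the proxy
quality (Pearson r between detail and word counts within a dataset) is the
premise the validation design checks first. An optional probability-weighted
("expected-fraction") aggregation exists but is off by default; all
validation uses the argmax mode. Conservation — predicted internal plus
external words equal the narrative's total words — holds exactly by
construction and is enforced by the `NarrativeScore` type.

## Preprocessing

- Whitespace is normalized (runs collapsed to single spaces) on every read.
- A *word* is a whitespace-delimited token; punctuation stays attached, and
  hyphens/em-dashes do not split tokens. This is the only convention
  reproducible across implementations, since no finer definition is imposed.
- Sentence boundaries: a token ending in `.`, `!`, `?` or `…` closes a
  sentence unless it is a known abbreviation ("Dr.", "e.g.", …), a single
  capital initial, or a bare number. Text without terminal punctuation is one
  sentence — the failure mode unpunctuated transcripts produce, and the
  reason the punctuation-degradation checks exist. The splitter is pluggable;
  the tests pin the built-in rule-based backend.
- Researcher prompts are removed only when the user supplies them (literal
  strings or regexes); there is no heuristic prompt detection.
- Training/validation corpora drop sentences carrying more than eight manual
  details (`max_details = 8`, strict inequality): such sentences are almost
  always run-ons from transcripts missing punctuation. Per-narrative detail
  totals are decremented by the details removed. The scoring path never
  applies this filter — end users' narratives are scored as given.
- A sentence's detail count is the sum over annotation spans it overlaps,
  with a span crossing a sentence boundary prorated by word overlap and
  rounded half-up per (span, sentence) pair. The annotation unit is the span
  and the filter unit is the sentence, so some join rule is required; this
  one is simple and order-independent, at the cost of not conserving details
  exactly when spans straddle boundaries.

## Training data preparation

Sentences are labeled with the fraction of their words lying in internal
spans, binned as above, and the four classes are balanced by upsampling every
minority class with replacement to the majority count (e.g.,
10,000/8,000/8,000/8,000 becomes 10,000 each via 2,000 sampled additions per
minority class). Balancing prevents the classifier from learning base rates,
which would otherwise let it score well by calling everything internal.
Draws come from a single seeded RNG stream in fixed label order, so the
result is reproducible. Balancing happens after the run-on filter and after
labeling.

## Classifier

The classifier is a scikit-learn-style estimator with pluggable backends
behind one interface; the pipeline's contribution is the label scheme and
aggregation, not a particular encoder.

- `count-logistic` (default): token counts, L1-normalized per sentence into
  term frequencies, feeding a multinomial logistic regression (cross-entropy
  loss). Normalization matters because the label is a *proportion*: relative
  frequencies carry the signal and sentence length would otherwise confound
  the mixed classes. The ridge strength maps from the configured weight
  decay with a correction for the 1/length feature scale
  (`C = mean_len² / weight_decay`), since the weight-decay convention
  presumes O(1) features. The backend is bit-deterministic given the data
  and seed.
- `transformer:<model-name>`: a pretrained transformer encoder with a single
  linear classification head fine-tuned with cross-entropy via the
  huggingface trainer; it consumes the batch/warmup/decay settings and
  truncates at 128 tokens (inputs are single sentences; truncation is
  logged). It requires the optional `transformers`/`torch` dependencies and
  is excluded from the default test suite so CI stays CPU-only.

Training configuration defaults: 3 epochs, train batch 16, eval batch 64,
500 warmup steps, weight decay 0.01, learning rate 5e-5 with linear decay,
accuracy as the (fixed) training evaluation criterion. A stratified 10%
holdout of the training pool provides the per-epoch accuracy log. Prediction
ties resolve toward the more internal class, mirroring the binning rule.

Finite-sample behaviour on the synthetic corpus: with ~400 balanced training
sentences the lightweight backend recovers pure classes at ≥ 0.9 recall and
mixed classes at ≥ 0.6 (the hard boundaries are 50% vs 75%); out-of-sample
accuracy is typically 0.89–0.95 and approaches 1.0 from roughly 1,200
training sentences, where per-word weight estimates stabilize. The test
suite asserts the ≥ 0.95 accuracy property at 1,200 sentences and the recall
floors at 400.

## Validation design

- **Proxy report:** Pearson r between manual detail counts and annotated
  word counts, per category and dataset, with range and mean across
  datasets.
- **Quadrant report:** the 2×2 of correlations between {manual internal,
  manual external} detail counts and {predicted internal, predicted
  external} words. A valid scorer shows a high diagonal and near-zero
  off-diagonal (misclassification) terms. p-values are two-sided via the t
  transform with n−2 degrees of freedom (sidedness is a convention; two-sided
  is assumed and documented). Undefined correlations (constant columns,
  n < 3) are reported as explicit `None` markers, never silently zero.
- **Leave-one-dataset-out:** entire datasets are held out in turn; the
  remaining non-protected datasets are labeled, filtered, balanced, and used
  to train a fresh model; the held-out narratives are scored as an end user
  would score them (no run-on filter, full manual counts as truth; a
  `filter_heldout`-style protocol that updates validation counts after
  filtering can be layered on by callers who preprocess the held-out side
  themselves). Datasets scored with incompatible guidelines can be marked
  *protected*: they are never trained on and are evaluated against a model
  trained on all non-protected data (default) or against each fold's model —
  both modes are provided because either protocol is defensible; the choice
  is recorded in each result. Fold training manifests (dataset and narrative
  ids) are emitted so fold isolation is assertable, and task subgroups of a
  held-out dataset are reported separately.

## Synthetic corpus

The generator emulates the *structure* of scored interview datasets so the
pipeline is testable without private data; textual realism is a non-goal.

- Sentences are composed from two disjoint lexicons — past-tense/perceptual
  ("internal") and habitual/semantic ("external") — so each sentence's true
  internal fraction sits exactly on the class grid. Disjoint vocabularies
  make separability controllable: classifier-recovery tests then measure the
  pipeline, not the encoder.
- Per narrative, pure-class sentence counts (`P0`, `P100`) are drawn
  independently with expectation `weight × mean sentences`, while
  mixed-class counts are held at their rounded expectation and mixed
  segments have fixed sizes (the `words_per_segment` midpoint: 8+8 for
  `P50`, 12+4 for `P75` at defaults). This makes per-narrative internal and
  external totals nearly independent across narratives — the property real
  validation sets show (near-zero misclassification correlations) — where a
  naive multinomial class draw would couple both totals through narrative
  length and force spuriously high cross-quadrant correlations even for a
  perfect scorer.
- Detail counts are generated as `max(0, round(rate·words + N(0, σ)))` per
  segment, deliberately encoding the detail/word proxy as the generative
  assumption, since the scorer's validity argument rests on it. Defaults
  `rate = 0.3` details per word and `σ = 0.45` place the per-dataset
  detail/word correlation mid-band (~0.92–0.95 at 100–200 narratives).
- `punctuation_dropout` deletes each sentence terminator with the given
  probability, merging sentences at split time and mixing classes within
  "sentences" — the unpunctuated-transcript failure mode. The evaluation
  suite asserts only the *direction* of the resulting degradation (diagonal
  correlations decrease), not a magnitude.
- What the generator does **not** emulate: natural vocabulary overlap
  between episodic and semantic speech, disfluencies and uninformative
  speech, multi-event narratives, age-group or clinical effects, and rater
  noise beyond the detail-count jitter. Passing tests therefore demonstrate
  that the pipeline's machinery is correct and well calibrated under its own
  assumptions, not that any particular accuracy will transfer to real
  transcripts.

## Numerical conventions and degenerate inputs

- Rounding is half-up (`floor(x + 0.5)`) wherever a rule calls for rounding.
- Empty narratives score (0, 0, 0) with a warning flag rather than raising;
  empty sentences must be filtered before classification and raise if not.
- `NarrativeScore` tolerates floating error up to `1e-9 × total_words`.
- All stochastic steps (balancing, generation, shuffling, holdout splits)
  take explicit seeds; derived seeds stay below 2³¹.
- Problem sizes in the test and acceptance runs (e.g., 3 synthetic datasets
  × 100 narratives for cross-validation, 1,000 narratives for conservation,
  200 per dataset for the proxy band) are chosen as the smallest scales at
  which the asserted statistics are stable.

## Known limitations

- The rule-based splitter covers common abbreviations and initials only;
  exotic punctuation (dialogue, ellipsis-heavy prose) may over- or
  under-split. The splitter is pluggable for that reason.
- Detail proration rounds per (span, sentence) pair and can create or lose a
  detail when spans straddle boundaries; the run-on filter's adjustments are
  defined in terms of the prorated counts, so its bookkeeping is internally
  consistent.
- The lightweight backend assumes lexical separability of internal and
  external content; on real language, where vocabularies overlap heavily, a
  contextual encoder (the transformer backend) is the appropriate choice.
- Scores quantify content in *words*, not details; studies that need detail
  subcategories or central-event discrimination still require manual
  scoring.
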