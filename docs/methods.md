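# Methods

## Data model

A document is one participant's tokenized spoken output for one elicitation
task (`interview` or `recounting`): a word sequence `x = (w_1, …, w_L)` with
an optional binary tag matrix `T ∈ {0,1}^{L×C}` over the fixed schema of
`C = 147` lexicogrammatical tag types.  A tag is binary per word — active at
least once on a word counts once — so every entry of the tag-frequency
vector `t_i = (active-word count of tag i) / L` lies in `[0, 1]`.
Tokenization (for Japanese, morphological segmentation) is upstream of this
package; the corpus format carries tokens directly.

The tag schema ships as a versioned TSV so the column order `0…146` is
stable across runs and serialisations.  The 16 headings carry
(10, 2, 2, 22, 13, 20, 8, 18, 4, 12, 12, 3, 1, 10, 2, 8) tag types; the
first six headings realise the ideational metafunction (69 tags), the rest
the interpersonal one (78).  Two headings (stative/compound auxiliary verbs
and benefactive auxiliaries) are published only as category counts, so
their tag names are numbered placeholders (`auxiliary_verbs.stative_01` …);
all other names are slugified from the published taxonomy.

## Automatic tagging

Tagging is multi-label sequence labelling: learned word embeddings
(dimension `d`) feed a single-layer Bi-LSTM (hidden width `h` per
direction); each token's concatenated forward/backward state passes through
a linear layer to 147 independent sigmoids.  Training minimises per-token,
per-tag binary cross-entropy, excluding padded positions; a tag is
predicted active when its score strictly exceeds the threshold τ = 0.5 (a
score exactly at τ maps to 0).  The vocabulary is built from the training
fold only; unseen words map to a learned UNK row.  Tagging quality is
summarised by micro-averaged precision/recall/F1 pooled over all
(word, tag) cells, with the 0/0 → 0 convention; micro averaging is used
because single aggregate numbers are reported, and pooling over documents
is exactly equivalent to pooling raw counts.

## Classifiers

All four variants output `P(AS)`; AS is the positive class and the decision
threshold is 0.5 throughout (sensitivity = AS recall, specificity = non-AS
recall).

* `tag_linear` — L2-regularised logistic regression on tag-frequency
  vectors.  Order-free by construction.  The regularisation strength is
  configurable and weak by default (λ = 0.01); the reference procedure
  specifies none.
* `tag_dnn` / `text_dnn` / `text_tag_dnn` — a Bi-LSTM over per-timestep
  inputs: the sum of active-tag embedding rows (an empty tag set gives the
  zero vector), word embeddings, or their concatenation (width `2d`).  The
  "last state" is the forward state at the last real token concatenated
  with the backward state at the first token (width `2h`), followed by a
  fully connected layer with a single sigmoid.  One sigmoid rather than a
  two-way softmax: the two parameterise the same model family.

Reference hyperparameters, used as defaults: `d = h = 300`, 50 epochs,
batch 32, Adam with learning rate 0.001, no early stopping, no validation
split, no pretrained embeddings, no hyperparameter search.

## The numeric core

The recurrent networks are implemented in plain numpy (`lexasd.nn`) with
hand-derived gradients and Adam.  The backward pass is verified against
central finite differences in the test suite (worst relative error ~1e-7).
Batches are padded to the batch maximum length; padded positions are never
consumed by the loss or the last-state extraction, so their gradient
contribution is identically zero (also asserted in tests).  Everything is
float64 and seeded through `numpy.random.default_rng`, which makes training
bitwise-reproducible on one device.  Weight initialisation follows the
common uniform `±1/√h` scheme with the forget-gate bias at 1; embeddings
start at N(0, 0.1).

## Evaluation protocol

Nested leave-one-out cross-validation: for each document *n*, both the
tagger and the classifier are trained on the other N−1 documents (the
classifier always on manual tags), the tagger produces `T_n^auto` for the
held-out tokens, and the held-out document is scored under manual and under
automatic tags.  Fold *n* uses seed `base_seed + n` for both models.  The N
pooled held-out probabilities yield the confusion metrics and a pooled
Wilcoxon–Mann–Whitney AUC with midrank ties (per-fold AUC is undefined for
single samples).  Confidence intervals are Wald,
`p ± 1.96·√(p(1−p)/n)` clipped to `[0, 1]`, reported to 2 decimals — this
choice exactly reproduces the published interview intervals for accuracies
0.78 and 0.80 at n = 135.

Paired classifiers are compared with the McNemar test on discordant counts
`b` (only model 1 correct) and `c` (only model 2 correct):
χ² = (b−c)²/(b+c), continuity-corrected χ² = (|b−c|−1)²/(b+c), or the
two-sided exact binomial on (min(b,c), b+c, ½).  The default is the
continuity-corrected χ², falling back to exact when b + c < 25; with no
discordant pairs the statistic is 0 and p = 1.  No multiple-testing
correction is applied across the three standard comparisons.  Demographic
2×2 tables use the Pearson chi-square with optional Yates correction.

An `"oracle"` tagger option routes the manual tags through the
automatic-annotation path unchanged; it is used (a) as a protocol audit —
the two paths must then coincide exactly — and (b) to score the
manual-annotation path alone where the tagger is not under study, since
fully nested tagger retraining multiplies runtime by the fold count while
being orthogonal to classifier behaviour.

## Synthetic corpus generator

The generator emulates the study design — two diagnostic groups, one or two
elicitation tasks, manually tagged token sequences — without claiming
lexical realism:

* Document length ~ negative binomial, parameterised by mean (default 200
  tokens, the order of a task response) and dispersion; lengths are clipped
  below at 1.  Over-dispersion avoids degenerate fixed-length corpora.
* Tag activation: independent Bernoulli per (word, tag) at the group rate.
  Non-AS rates default to ρ = 0.01 per tag; the AS rate is
  `clip(m_c·ρ_c, 0, 1)`.  Tag co-activation structure is deliberately not
  modelled — the pipeline only needs learnable signal.  An `exclusive_tags`
  mode draws at most one tag per word multinomially; with coupling 1 this
  makes the word → tag mapping exactly rule-deterministic and is used for
  the tagger-recovery benchmark (under independent Bernoulli draws,
  co-active tags are not encoded in the surface word, which caps
  achievable recall below 1 by design rather than by tagger quality).
* Word surfaces: with probability `coupling` (default 0.7) a tagged word is
  drawn from the 4-word sub-vocabulary dedicated to its most salient active
  tag (rarest base rate, ties to the lowest column); otherwise uniformly
  from a 200-word background lexicon.  Coupling makes tags recoverable from
  text, giving the text-only classifier and the tagger learnable signal.
* Effect preset: the published direction of group differences — reduced AS
  use of sentence-final particles *ne* and *yo*, the three evidentiality
  tags, and probability modality — at a default multiplier of 0.4 on
  elevated base rates (0.05).  Per-tag clinical effect sizes are not
  published, so the magnitudes are package defaults.  A `paired_tasks` flag
  emits an interview and a recounting document per subject, with the
  recounting effect attenuated toward 1 (default 50%) to mimic the weaker
  task contrast qualitatively.

What passing benchmarks on this generator shows: that the pipeline recovers
injected group structure of a known direction and stays calibrated under
the null.  What it does not show: performance on real clinical speech,
whose lexical statistics, tag co-occurrence structure, and effect sizes the
generator does not attempt to match.

## Benchmark conditions and sizes

* **Strong-effect recovery**: 40+40 documents, ~200 tokens, 10 implicated
  tags at multiplier 0.2 on ρ = 0.05.  Expected outcome: tag-linear LOOCV
  accuracy ≥ 0.9 with ≥ 90% of implicated coefficients negative;
  text+tag-DNN held-out AUC ≥ 0.9 on a stratified 80/20 split; DNN LOOCV at
  N = 30 above the chance band.
* **Null calibration**: 12+12 documents, all multipliers 1, coupling 0.
  Every variant's LOOCV accuracy must lie inside the central 99% binomial
  band around 0.5.  Small-sample LOOCV has a known pessimistic artifact
  here: a model that merely reproduces the training-fold class prior is
  anti-correlated with the held-out label (holding out an AS document
  leaves the training set majority non-AS).  Under-trained DNNs behave
  exactly like prior-followers, so the null benchmark trains them to
  convergence (20 epochs at learning rate 0.02), where held-out predictions
  are dominated by input noise rather than the prior.  The artifact cannot
  be removed entirely: across many seeds the null LOOCV accuracy of the
  linear model centres near 0.40 rather than 0.50, and an occasional seed
  falls below the nominal band.  This is a property of leave-one-out with
  balanced classes, not of the implementation.
* **Tagger recovery**: exclusive-tags corpus, coupling 1, 10 active tag
  types at rate 0.04, 32 training and 8 held-out documents of ~60 tokens.
  Expected micro-F1 ≥ 0.95.

DNN benchmarks run at reduced width (16–32) and adjusted epochs/learning
rate (Adam step counts on 20–80-document corpora are tiny, so small-corpus
runs use learning rates of 0.01–0.02); the reference widths stay the config
defaults.  All benchmark corpora, splits and model seeds derive from a
single run seed.

## Numerical and design choices

* Strict `>` at the tagging threshold; `≥` at the 0.5 classification
  threshold (so a perfectly uncertain classifier predicts the positive
  class — relevant only on ties).
* Zero-denominator conventions: precision/recall/F1 = 0; AUC is reported as
  missing when the truth is single-class.
* Document batches are shuffled per epoch from the run seed; length
  bucketing is off to keep the shuffle order (and thus training) a pure
  function of the seed.
* Exact McNemar equals full enumeration of the binomial tail (tested for
  all b+c ≤ 12); AUC equals the all-pairs count with ties at ½ (tested up
  to 50 records).
* The generator validates that all rates and clipped products lie in
  [0, 1]; `exclusive_tags` additionally requires Σρ ≤ 1.

## Known limitations

* No Japanese morphology, ASR, or speaker-turn modelling; documents are
  participant responses only, pre-tokenized.
* The tagger has no CRF layer or transformer alternative, and the
  classifiers no attention or pretraining — deliberately outside scope.
* The linear model's coefficients are interpretable only up to the
  collinearity of tag frequencies; no inference on coefficients is
  provided.
* Published performance on the clinical corpus cannot be reproduced without
  that corpus; the package reproduces the self-contained analytic numbers
  and demonstrates the protocol's statistical behaviour on synthetic data.
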