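# Methods

This note documents the models and procedures implemented in `qcla`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer should know about.

## Semantic space

The embedding is classical LSA on n-gram co-occurrence counts.  For a
token stream, every length-N window (N = 5 by default, matching common
n-gram corpora) contributes one count to `C[w, c]` for every ordered pair
of distinct positions `(w, c)` in the window; contexts are the vocabulary
itself, so `C` is symmetric.  Counts are damped with `log(count + 1)` and
factored with a truncated SVD.  Word vectors are the rows of `U_d S_d`
(singular-value weighted — configurable to plain `U_d`, and recorded in
the space's metadata, because unit renormalisation makes the two choices
genuinely different).  Each vector is renormalised to unit length
(tolerance 1e-9).  Determinism: each singular vector's sign is fixed so
its largest-magnitude entry is positive.  All-zero rows cannot be
normalised and are dropped from the vocabulary with a log message.  The
default dimensionality is 512, capped at `min(rows, cols) − 1` for small
corpora; the cap is logged, not silent.

Responses are encoded as the renormalised sum of in-vocabulary word
vectors after minimal token normalisation (lowercase, strip surrounding
punctuation, no stemming — responses are single descriptive words).  A
response with no in-vocabulary words is marked missing rather than
returned as a zero vector, and the participant is excluded from analyses
of that variable.

## Cohort

A cohort row holds age, gender, four scale totals (PHQ-9 0–27, GAD-7
0–21, HILS and SWLS 5–35), a control-item pass flag, and word responses
to 16 questions: three mental-health questions (5 word boxes each), three
reason questions (3 each), two positive-psychology questions (3 each) and
eight symptom questions (2 each) — 46 boxes in total.  Boxes may be left
blank; responses are simply shorter.  Loading validates ranges and
collects violating rows into a rejection report instead of silently
dropping them; duplicate ids are an error.  The control filter removes
participants who failed any control item and logs the count.  The age
split assigns `age < threshold` to the young group and `age >= threshold`
to the old group (ties go old); the threshold can be a number or the
sample median.  Undefined correlations (a constant variable) are reported
as not-available with a warning, never as zero.

## Prediction

The model is ordinary least squares with intercept on the first
`n_dims` embedding dimensions (SVD dimensions are variance-ordered, so a
prefix is the natural nested family).  `n_dims` is selected by maximising
inner-CV correlation over a grid of powers of two {2, 4, …, 512}, capped
at `min(d, n_train/2)` and at the numerical rank of the representation
(single-question encodings built from a few hundred distinct word
combinations are often far from full column rank); ties break toward
fewer dimensions.  Rank-deficient fits fall back to a minimal ridge
penalty (1e-8, trace-scaled) and are logged.  Outer evaluation is 10%
leave-out CV with uniform random, unstratified fold assignment under the
run seed; selection is re-run inside every training fold, so no held-out
information touches any modelling choice.

### The pooled correlation and its p-value

Two subtleties of evaluating pooled out-of-fold predictions with a
Pearson correlation deserve documentation:

1. **Fold-mean artifact.**  The fitted intercept makes each fold's
   predictions ride on the training-fold mean of `y`, which is a linear
   function of the held-out fold's mean *with negative sign*.  Pooling
   across folds therefore injects a spurious negative component into `r`
   under the null.  The reported `r` is computed on the centered slope
   component — prediction minus the training fold's mean of `y` (OLS
   passes through the means, so this removes exactly the per-fold
   offset, including the `x̄·β` term; LSA dimensions are not
   mean-centered, so removing only the fitted intercept would not).
   This is leak-free and shift-invariant; RMSE, Min and Max are computed
   from the full honest predictions.  `debias_fold_means=False` restores
   the raw pooled correlation.
2. **p-value.**  Fold models share training data, so the pooled null
   correlation is overdispersed relative to an ordinary sample
   correlation (measured at roughly twice the nominal variance at
   n = 200 with 10 folds).  The analytic `t = r·sqrt((n−2)/(1−r²))`
   transform therefore understates p for cross-validated predictions,
   and the default p-value is a permutation test that respects the CV
   structure: the target is permuted, the per-fold OLS models are refit
   (via cached training-fold pseudoinverses; fold assignment and
   selected dimensionalities held fixed) and the pooled statistic is
   recomputed.  199 permutations by default (1999 in the question
   battery so Bonferroni thresholds below 1/200 remain reachable).
   Under a Gaussian null this is calibrated to the permutation
   granularity.  The analytic transform remains available
   (`p_method="analytic"`, and `pvalue_for_r` for plain correlations,
   where it is exact).

Bonferroni tiering reports each test as corrected-significant
(`p ≤ α/m`), uncorrected-significant (`p ≤ α`) or ns, with `m` = number
of tests actually run.

## Indicative words

The per-word statistic is a Welch (unequal-variance) two-sample t-test
comparing the target variable between users and non-users of the word;
Welch is the safer default because user/non-user groups are heavily
unbalanced.  Words used by fewer than 5 participants are skipped (a
singleton t-test is meaningless); `m` for Bonferroni is the number of
words actually tested.  Clouds keep the top 100 words per direction,
ordered by p then |t|; an alternative mode that scores single-word
embeddings through a trained regression model is provided
(`model_scored_words`) as a secondary reading of indicativeness.  The
2×2 crossed analysis (age × scale median split) contrasts each cell
against the rest of the cohort on the membership indicator.  The
reference-corpus contrast uses add-one-smoothed log-odds with a
two-proportion z screen; words absent from the reference are smoothed,
not dropped.

## Lexicon scoring

A category score is `100 × matching tokens / total tokens`, with tokens
counted with multiplicity and trailing-asterisk entries matching by
prefix.  An empty text has no defined score and excludes the participant
for that category.  The bundled lexicon is an openly authored substitute
of 63 named categories following the field's standard inventory
(function words, affect, social, cognitive processes, biological
processes, drives, relativity, personal concerns); it is adequate for
testing the machinery and the synthetic cohorts and is *not* a
reconstruction of any proprietary dictionary.  Category percentages are
correlated with age (Pearson), Bonferroni-corrected over the 63
categories, with direction "old" for r > 0 and "young" for r < 0.

## Transfer experiment

For each of the 17 text variables × 4 scales, performance is estimated
in a 2 (train group) × 2 (test group) grid.  Same-group cells use
10-fold CV inside the group — resubstitution would overstate them —
while opposite-group cells train on the full other group and test on the
full target group; dimension selection is re-run per training set.  A
model key that cannot be estimated in some cell is dropped from all four
cells to keep the repeated-measures design balanced.  The 68 per-model
correlations (or MSEs) are analysed as subjects in a two-way
within-subject ANOVA (factors: test-group age, same/opposite condition);
each effect is tested against its own effect-by-subject error term with
df (1, n−1).  Sums of squares are computed explicitly and satisfy
`SS_total = SS_subjects + Σ SS_effects + Σ SS_errors` to 1e-8 by direct
evaluation (the decomposition is asserted in tests, not enforced by
subtraction); SS at round-off scale (below 1e-12 of SS_total) is treated
as zero so an all-equal design yields F = 0, p = 1.  The ANOVA runs on
raw correlations by default; a Fisher-z option exists behind a flag.

## Covariate analysis

A semantic measure of a construct is the out-of-fold CV prediction of
its rating scale from the All-texts representation (one value per
participant, never predicted by a model that saw them).  "Using the
rating scales as covariates" is implemented as first-order partial
correlation — residualise both the measure and age on the corresponding
scale (with intercept) and correlate the residuals, p from the t
transform with n − 3 df — matching the pairing of each measure with its
own scale.  A multi-covariate regression-residualisation variant is
available (`regression_residual_correlation`).  A constant covariate
reduces to the simple correlation with a warning.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated:

- **Sampling frame.**  `n_participants` (default 876) is the retained
  target; `round(n/(1−rate))` participants are drawn and
  `round(raw·rate)` marked as control failures (rate 7/883 by default),
  reproducing an 883 → 876 funnel exactly.  Ages are uniform integers on
  18–70; gender is drawn at the observed cohort proportions.
- **Traits and scales.**  Latent depression and anxiety share a common
  distress factor (loading 0.6) and decline with age (standardised slope
  0.25); two wellbeing variants rise mildly with age.  Scale totals are
  linear transforms of reliability-attenuated traits (reliability 0.8),
  rounded and clipped to instrument ranges.  This yields scale–age
  correlations of about −0.2, a realistic magnitude for cohorts of this
  size.
- **Words.**  Each question has a base mixture over nine shared category
  lexicons (depression, anxiety, stress, positive, work/school, money,
  relationships, body/energy, neutral).  Trait expression modulates the
  mixture (depression trait up-weights depression words, distress
  down-weights positive words) with a strength that grows linearly with
  age from `expressiveness_young` (0.5) to `expressiveness_old` (1.5) —
  older participants describe their state more reliably.  Independently,
  a marker mechanism fills a fraction of word boxes (rate 0.25, scaled
  by age affinity) from group-specific vocabularies inspired by the
  young/old indicative themes (school/work/stress vs
  loneliness/worry/finances and calm confidence), choosing the negative
  or positive sub-pool by a logistic function of expressiveness ×
  distress.  This plants (a) a strong continuous age signal, (b) shared
  trait signal that transfers across groups, and (c) old-specific trait
  signal that does not — producing the age main effect and the
  age-by-condition interaction in the transfer experiment, and the
  incremental language signal that keeps the semantic measures
  age-correlated after partialling out the scales.
- **Word counts.**  Each box is blank with probability 4/46, giving a
  mean of 42 words per participant against the 46-box maximum.
- **Reference corpus.**  Documents of ten 5-grams are sampled one topic
  at a time (topic purity 0.75, neutral glue otherwise), so same-topic
  words co-occur far more than cross-topic ones; 12,000 5-grams by
  default.  Everything is deterministic under the seed.

What the generator does **not** emulate: real English semantics or
vocabulary scale (the vocabulary is ~160 words, so absolute r values run
higher than a real cohort's), free-text noise (typos, multi-word
answers), item-level scale structure, and any demographic covariance
beyond age.  Passing tests therefore demonstrate that the pipeline
recovers known structure under clean conditions with honest
cross-validation — not that real data would yield effects of the same
size.

`oracle_ceiling` regresses a target on the generator's own word-pool
counts (the generative sufficient statistics) with the same CV
machinery, bounding what any embedding pipeline can recover from the
words; recovery tests compare pipeline performance against it.

## Numerical choices and degenerate inputs

- Unit-norm tolerance 1e-9 for stored vectors; numerically-zero SVD rows
  (below 1e-12 of the largest row norm) are treated as zero.
- Degenerate t-tests (both sides constant) report t = 0, p = 1.
- Residuals below 1e-10 of the input scale in partial correlation mean
  the variable is an exact function of the covariate: r = 0, p = 1.
- Empty clouds, suppressed 2×2 cells, degenerate age splits and constant
  correlation inputs warn rather than fail.
- Every stochastic routine takes a seed or Generator; results are
  reproducible bit-for-bit under a fixed seed.

## Problem sizes

Simulation-based checks run at sizes chosen to make their statistical
assertions sharp while keeping the suite quick: calibration at n = 200
with 500 replicates (binomial SE ≈ 1% on the rejection rate), signal
recovery at n = 1000, marker recovery at n = 800, ANOVA power/null at 68
subjects with 60/500 replicates, and the full synthetic study at the
default 876 retained participants.

## Known limitations

- The permutation p holds dimension selection fixed per fold; selection
  noise under the null is not re-drawn per permutation (measured effect
  on calibration is negligible at the tested sizes).
- The question battery treats questions independently; no multivariate
  or hierarchical pooling across questions.
- The substitute lexicon's short word lists make category scores coarse
  compared to a full dictionary.
- Cross-group transfer cells are single train/test evaluations and thus
  noisier than the CV cells; the ANOVA treats both as one observation
  per cell.
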