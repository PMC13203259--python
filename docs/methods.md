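# Methods

This note documents the measurement model, the estimation machinery, the
synthetic data-generating process used for validation, and the design
choices made where the procedure was genuinely open.

## Projection measurement

A construct is represented as one bipolar semantic axis: the unit vector
from the negative-pole anchor centroid to the positive-pole centroid.
Scoring a text means averaging the embedding vectors of all its cleaned
tokens and taking the dot product with the axis. Three conventions
matter:

- **OOV handling.** An out-of-vocabulary token contributes a zero vector
  but stays in the averaging denominator. A text of k in-vocabulary
  tokens among n total is therefore shrunk by k/n toward the neutral
  point. Scores are missing only for empty token lists; a text of pure
  OOV tokens scores exactly 0. Sparse texts are handled downstream by
  the valid-token-length sensitivity filters (≥5 tokens; short (0,20) vs
  long ≥20), not by dropping them at scoring time.
- **Anchor screening is one-shot.** Anchors are screened against the
  vocabulary when the axis is built, and the axis is immutable after
  that, so scores remain comparable across samples and periods. A pole
  with no in-vocabulary word is an error, not a silent degenerate axis.
- **Dictionary baseline.** Hits are counted as word *types* (set
  intersection), not occurrences; a text is "covered" when it has at
  least one hit. For rank-correlation comparisons, uncovered texts can
  either be excluded (coverage semantics) or scored 0 (total-function
  semantics); both modes are available to the caller because published
  practice is ambiguous on this point.

Pole diagnostics compare mean pairwise cosines: a valid bipolar anchor
set has both within-pole means above the between-pole mean. Within-pole
means exclude self-pairs (which would inflate the statistic toward 1);
a single-word pole leaves its within mean undefined (NaN) and the
diagnostic conservatively fails.

## Corpus preparation

Posts are bucketed into 7-day windows anchored at each user's
registration date (week index = floor(days since registration / 7)) —
not ISO calendar weeks — and concatenated chronologically with single
spaces. Cleaning drops URL tokens (containing `://` or starting
`www.`), @-mentions, tokens with no letter in any script (CJK ideographs
count as letters), and one-character tokens. The tokenizer is an
injected callable; tests use whitespace tokenization, and any external
segmenter (for languages without word boundaries) plugs in unchanged.
Panel inclusion removes empty cleaned texts, users without registration
info, and users left with fewer than two valid weeks; the filter is
idempotent and reports removals by reason.

## Cross-temporal stability

Period embedding spaces are aligned to a reference space by orthogonal
Procrustes (rotation and reflection, no scaling or translation), solved
by SVD of the cross-covariance over the shared vocabulary. The default
fitting vocabulary is the intersection of the two vocabularies
restricted to the first N reference tokens (N = 5000), unweighted —
vocabulary order proxies frequency order in embeddings trained by the
usual tooling. Reflections are permitted; a shared vocabulary smaller
than the dimension triggers an ill-conditioning warning. Two indicators
are reported per construct × period: the cosine between the
period-space axis and the reference axis (orientation stability), and
the Spearman correlation of anchor projections between the spaces
(rank-order consistency, average ranks for ties, requiring at least 3
anchors present in both vocabularies; anchors missing from a period are
dropped from that period's test and counted).

## Panel estimation

Raw weekly sums enter as ln(x+1) (exercise minutes, social engagement,
social feedback). The behavioral-inertia control is the first
difference of logged duration between strictly adjacent weeks — a gap
leaves it undefined rather than silently differencing across the gap.
The outcome is led by exactly one week: an estimation row exists only
when the same user is observed in week t+1, so gaps drop rows instead
of changing the estimand. Winsorization (1st/99th percentile, both
tails) and z-standardization of continuous predictors are applied on
the final estimation sample, after filtering, so coefficients read as
per-SD effects in the fitted model.

The within estimator demeans outcome and regressors by user and runs
least squares; this equals dummy-variable OLS exactly (verified to
1e-8 against statsmodels in the tests). Cluster-robust covariance uses
the one-way estimator with correction G/(G−1) × (n−1)/(n−k), where k
counts slopes plus absorbed user effects, and p-values use a t
reference with G−1 degrees of freedom. A regressor constant within
every user is absorbed by the fixed effects and rejected by name; the
constancy check is relative to the column's original scale so
large-magnitude user-level constants are still caught. Within R² is
computed on the demeaned data.

Effect sizes: semi-elasticity 100·(e^β − 1) percent per SD of the
predictor, and minutes-equivalent ref_mean·(e^β − 1); the two satisfy
minutes = ref_mean × semi/100 identically. Collinearity diagnostics
report VIFs from auxiliary regressions (with intercept) and condition
indices from singular values of the z-standardized design. The
between-subgroup coefficient test is the plain normal z-test on two
independent estimates; more elaborate published procedures (e.g.,
interacted models) can give different p-values, so this module's test
should be read as the textbook large-sample check.

Relative-week trajectories z-standardize the raw score with the
full-sample mean and SD, average by week since registration, and smooth
with a 3-week centered moving average whose window shrinks to the
available neighbors at the series edges (endpoints are kept, not
dropped).

## SIMEX

For each λ in {0, 0.5, 1, 1.5, 2}, B = 30 replicates add independent
N(0, λσ²_u) noise to the standardized focal score, the fixed-effects
model is refit, and the focal coefficient is averaged; a quadratic in λ
is fit to the mean path by unweighted least squares and evaluated at
λ = −1. The bias statistic is (|β_naive| − |β_simex|)/|β_simex| × 100.
The error variance σ²_u is deliberately an explicit input — supplied
directly or derived from a reliability ratio r as σ²_x(1−r)/r — because
no principled internal estimate exists for projection scores; silently
assuming one would hide the method's largest free parameter. Noise is
added to the focal construct only; controls are treated as error-free.
All randomness flows from the config seed, so results are bit-identical
across reruns.

## Synthetic data-generating process

The generator plants everything the validation needs to know the truth
of:

- **Space.** Each construct gets a unit direction (mutually orthogonal
  across constructs). Positive/negative anchors are drawn around
  ±(δ/2)·e with isotropic sd σ_a (defaults δ = 3, σ_a = 0.5, 8 anchors
  per pole, d = 50, 500 tokens); fillers are isotropic about the
  origin. Each pole additionally receives 20 "pole neighbor" tokens
  from the same pole distribution that are *not* listed in the anchor
  dictionaries — construct-related community vocabulary beyond the
  curated list. This is what makes the dictionary baseline's coverage
  gap real in the fixtures: projection reads those words, exact
  matching cannot.
- **Panel.** Latent z[i,t] ~ N(0,1) per user-week drives the token
  mixture: with probability 0.6 a token comes from a pole pool
  (positive with probability sigmoid(z)), otherwise a filler; 5% of
  tokens are replaced by OOV strings. Posts are emitted as raw text and
  run through the real cleaning/aggregation path. The outcome is
  α_i + β·z[i,t−1] + ε with α_i ~ N(0,1), ε ~ N(0,1), β = 0.5 — an
  individual fixed effect plus a one-week-ahead construct effect.
- **Benchmark.** Short texts with centered 5-level ordinal labels
  driving the same mixture, for rank-agreement comparisons.
- **Numeric panels.** For estimator-level checks (CI coverage,
  errors-in-variables), panels with an exactly observed or
  noise-contaminated regressor skip the text layer entirely, so the
  estimator is tested in isolation from the scorer.

All randomness derives from one spec seed split into independent child
streams per sub-generator, so adding a generator never perturbs
existing fixtures.

What the fixtures do *not* emulate: natural-language morphology and
segmentation (tokens are synthetic ASCII), topic structure, anisotropic
embedding geometry, frequency-dependent vector quality, user attrition,
and feedback from behavior to language. Passing tests therefore show
that the pipeline is correct and that its statistical properties hold
under the stated model — not that any particular real corpus satisfies
that model.

## Validation problem sizes

End-to-end recovery uses 100 worlds of 300 users × 8 weeks (planted
β = 0.5), requiring a positive coefficient with |t| > 1.96 in ≥ 95% of
worlds. SIMEX improvement uses 50 errors-in-variables replications at
reliability 0.7 (500 users × 8 weeks), requiring the corrected estimate
to beat the naive one in ≥ 90%. Clustered-CI coverage uses 200
replications (300 users × 8 weeks) with a ±4-point band around 95%.
Axis-stability drift uses isotropic noise sd ∈ {0, 0.2, 0.5, 1.0} with
10 replicates per level, requiring monotone decline of the mean cosine.

## Known limitations

- Projection scores are indicators of *expressed* construct salience in
  text, not measurements of latent psychological states; criterion
  associations are predictive, not causal.
- The SIMEX correction is only as good as the supplied error variance;
  the package cannot estimate score reliability internally.
- The plain z-test for subgroup coefficient differences assumes
  independent subsamples.
- The word2vec-text reader enforces a strict dialect (single header,
  space-separated, whitespace-free tokens); files with embedded spaces
  in tokens are rejected rather than guessed at.
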