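# Methods

## Data model

The raw unit is one evaluator's judgment of one participant's
interpretation of one item, on a three-category ordinal scale mapped to
percent scores: *correct* → 100, *minor misdiagnosis* (over- or
under-diagnosis of a minor finding) → 50, *major misdiagnosis* → 0.
Category labels and numeric scores are interchangeable on input; a row
carrying both must be consistent, and any score outside {0, 50, 100} is
rejected rather than coerced.

A participant's submission count is the number of **distinct items** they
answered, not the number of rows: with a k-member panel each answered item
produces k rows. The eligibility filter (default: at least five items,
inclusive) therefore counts items. Aggregation averages each evaluator's
scores over a participant's items, yielding the n × k `ScoreMatrix` on
which every agreement statistic operates. Incomplete panel coverage of an
item is an error, not a silent drop — all downstream estimators assume a
complete matrix, which matches the design where every submitted
interpretation is scored by every evaluator.

## Reliability estimators

All ICCs are ANOVA moment estimators (no REML / mixed models). With
participants as rows and evaluators as columns:

* one-way: SSB between rows (df n−1), SSW within rows (df n(k−1));
* two-way without replication: SSJ between columns (df k−1), residual SSE
  (df (n−1)(k−1)). The decompositions satisfy
  n(k−1)·MSW = (k−1)·MSJ + (n−1)(k−1)·MSE exactly.

Point estimates are the standard forms: ICC(1) and ICC(1k) from
(MSB, MSW); ICC(2) and ICC(2k) — absolute-agreement, two-way random — from
(MSB, MSJ, MSE). Single- and average-measures forms are linked by the
Spearman–Brown relation, which the implementation satisfies identically
(it is an algebraic identity of the estimators, and a property test
enforces it to 1e-10 relative precision).

Confidence intervals use the F-distribution procedures of Shrout & Fleiss
and McGraw & Wong: for the one-way forms, F = MSB/MSW with (n−1, n(k−1))
df transformed through (F/F_U, F·F_L'); for ICC(2), the Satterthwaite
approximation for the denominator df; average-measures intervals are the
Spearman–Brown image of the single-measure bounds. The p-value tests
ICC > 0 via F = MSB/MSW (one-way) or MSB/MSE (two-way). The implementation
is verified in the test suite against `pingouin.intraclass_corr` (an
independent implementation) to 1e-9 on values and p-values.

Edge policies: a constant matrix has no defined ICC and raises a
`DegenerateMatrixError`; MSW = 0 with MSB > 0 (perfect agreement) returns
ICC = 1 with a collapsed CI and p = 0; negative estimates are reported as
computed (truncation at zero is an option, off by default) and always fall
in the "poor" Fleiss band. Fleiss band boundaries are assigned upward:
0.40 is fair-to-good, 0.75 is excellent — consistent with reading 0.74 as
below the excellent threshold.

## Evaluator bias and error

The evaluator-effect ANOVA defaults to the repeated-measures design
(F = MSJ/MSE with (k−1), (n−1)(k−1) df), since scores are paired within
participants; a one-way variant (columns as independent groups) is
provided, along with a reconstruction helper that computes the one-way F
from published per-evaluator means/SDs alone. On the printed four-evaluator
summary (means 78.0/70.7/79.4/78.4, SDs 14.3/16.4/14.5/14.1, n = 107) the
reconstruction gives F = 7.74; a published value computed from unrounded
data or a paired design will differ, so no test pins a specific published
F. Mean absolute error is computed per evaluator against a designated
reference evaluator on participant-level scores; the reference's own
(zero) MAE is omitted. Pairwise Pearson correlations use all matrix rows;
a zero-variance column yields NaN for its pairs rather than a fabricated
value.

## Extended Bland–Altman

For k > 2 raters the classical difference-vs-mean plot is replaced by
(participant mean, intra-subject SD across the k scores). The 95% limit of
agreement defaults to 1.96·s_w with s_w = √MSW — the repeatability-style
bound below which ~95% of intra-subject spreads fall under the Gaussian
within-participant model (a coverage property test checks this on data
generated under that model). The empirical 95th percentile of the observed
intra-subject SDs is available as an alternative and both can be reported
side by side. Because the plot's y-statistic is a spread, the published
literature offers no single canonical LOA formula for it; 1.96·s_w is this
package's default as the Bland–Altman-recommended quantity for multiple
observations per subject.

The bootstrap interval resamples **whole participants** with replacement
(never individual cells, preserving within-participant correlation),
recomputes the LOA per resample, and applies the median-bias-corrected
(BC) percentile interval; BCa (jackknife acceleration) is available behind
a flag. A seed is mandatory — there is no silent entropy — and the
resampling stream depends only on the rows, so reordering evaluator
columns cannot change the interval.

## Ranking and variance decomposition

Participants are ranked by mean accuracy, descending, ties broken by id
(stable and reproducible). The per-participant error bar is the SD across
the k evaluator means — the spread of the panel about that participant —
not the item-level score SD, which lives in the per-item summaries
instead. The variance decomposition reports the between-participant
variance **component** (MSB − MSW)/k (floored at 0) against the within
component MSW, so their ratio estimates σ_b²/σ_w² = ICC/(1 − ICC) for the
single-rater reliability; a simulation test confirms recovery of
0.74/0.26 ≈ 2.85 at study scale.

## The simulator

**Gaussian mode** generates x₍ᵢᵣ₎ = μ + bᵢ + eᵢᵣ with
b ~ N(0, ρV), e ~ N(0, (1−ρ)V): the single-rater ICC is ρ by construction,
making it the calibration harness for the estimators. Defaults mirror a
cohort of 107 participants × 4 raters with ρ = 0.74, grand mean 76.6 and
total variance 13.7².

**Ordinal mode** draws a latent z₍ᵢⱼᵣ₎ = θᵢ − δⱼ + βᵣ + ε₍ᵢⱼᵣ₎ with
participant skill θ ~ N(0, 0.8²), item difficulty δ ~ N(0, 0.5²), fixed
per-rater leniency shifts β, and standard-normal noise; two cutpoints map
z to 0 / 50 / 100. The cutpoints are solved numerically so that the pooled
category frequencies, averaged over the configured rater biases, equal the
target marginal — by default (12.3, 21.5, 66.1)% for (major, minor,
correct), the mix observed in multi-evaluator accuracy scoring of trainee
ECG interpretations; with all biases zero this reduces to scaled normal
quantiles. The default bias vector (0, −0.35, 0, 0) in latent units makes
the second rater roughly 8 accuracy points stricter than the panel,
emulating a severity effect. The latent-normal skill distribution is a
modeling convention, not an inference from data.

The study-shaped cohort default is 192 participants × up to 19 items × 4
raters, with per-participant item counts drawn from binned proportions
(44% in 1–4, 20% in 5–10, 16% in 11–15, 20% in 16–19) so that roughly half
the cohort survives the ≥5-item filter. Missingness is completely at
random by default; an optional selectivity parameter makes response
propensity increase with latent skill, for studying the accuracy
overestimation that confidence-driven self-selection would induce.
One global seed feeds independent substreams for skills, difficulties,
noise and missingness, so changing the item count does not perturb the
skill draws.

What the simulator does **not** emulate: real item content (items are
abstract difficulty parameters), correlated evaluator errors (panel
members err independently given the latent value), learning or drift over
time, and any dependence between a participant's skill and which
particular items they see beyond the optional selectivity mechanism.
Passing calibration tests therefore shows the estimators behave correctly
under this generative model, not that any particular real cohort satisfies
it.

## Numerical choices and problem sizes

Statistics are computed in float64; JSON outputs round to 6 significant
digits for diffability. Bootstrap default is 1000 resamples. Simulation
studies in the test suite use 107 × 4 matrices with 500 replicates for
estimator recovery, 200 outer replicates for bootstrap-coverage checks,
and 5 seeds of the 192-participant cohort for ordinal calibration checks —
sizes at which Monte-Carlo error is comfortably inside the asserted
tolerances while the whole suite stays fast. Figures are drawn strictly
from precomputed result objects; plotting never recomputes statistics.

## Known limitations

* ANOVA-based ICCs assume a complete balanced matrix; there is no support
  for unbalanced or missing cells at the matrix level (missingness is
  handled upstream, at the item level, where it belongs).
* The consistency-type two-way forms ICC(3)/ICC(3k) are not implemented —
  the toolkit targets the one-way and absolute-agreement family.
* Kappa-family chance-corrected statistics are out of scope.
* The ordinal simulator's cutpoint calibration targets the pooled marginal;
  per-evaluator marginals follow from the bias vector and are not
  independently calibratable.
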