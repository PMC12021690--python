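"""Inter-rater reliability statistics from ANOVA mean squares.

All reliability statistics here are moment (ANOVA) estimators computed from a
complete participants x evaluators score matrix:

* one-way mean squares MSB (between participants) and MSW (within
  participants) feed ICC(1) and ICC(1k);
* two-way mean squares MSJ (between evaluators) and MSE (residual) feed the
  absolute-agreement forms ICC(2) and ICC(2k);
* the same decompositions give the evaluator-bias F test, and the matrix
  columns give pairwise Pearson correlations and mean absolute error against
  a designated reference evaluator.

Confidence intervals and p-values use the classical F-distribution procedures
(Shrout & Fleiss 1979; McGraw & Wong 1996).  ICC values are interpreted with
Fleiss' qualitative bands: below 0.40 poor, 0.40 to below 0.75 fair-to-good,
0.75 and above excellent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import ScoreMatrix

ICC_FORMS = ("ICC1", "ICC1k", "ICC2", "ICC2k")


class DegenerateMatrixError(ValueError):
    """The score matrix carries no variance, so the ICC is undefined."""


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Sufficient statistics for every ANOVA-based ICC form.

    ``msb``/``msw`` come from the one-way (participants as groups)
    decomposition; ``msj``/``mse`` from the two-way participant x evaluator
    decomposition without replication.  ``degenerate`` flags a constant
    matrix (all mean squares zero).
    """

    msb: float
    msw: float
    msj: float
    mse: float
    n: int
    k: int

    @property
    def degenerate(self) -> bool:
        return self.msb == 0.0 and self.msw == 0.0

    @property
    def df(self) -> dict[str, int]:
        return {
            "between": self.n - 1,
            "within": self.n * (self.k - 1),
            "evaluators": self.k - 1,
            "residual": (self.n - 1) * (self.k - 1),
        }


@dataclass(frozen=True)
class IccEstimate:
    form: str
    value: float
    ci_low: float
    ci_high: float
    p_value: float
    band: str


@dataclass(frozen=True)
class BiasReport:
    """Per-evaluator means/SDs, the evaluator-effect ANOVA, and MAE profile."""

    evaluator_ids: tuple[str, ...]
    evaluator_means: tuple[float, ...]
    evaluator_sds: tuple[float, ...]
    anova_f: float
    anova_p: float
    design: str
    reference: str | None
    mae_vs_reference: dict[str, float]


def anova_mean_squares(matrix: ScoreMatrix) -> AnovaMeanSquares:
    """One-way and two-way ANOVA mean squares of the score matrix.

    Satisfies the within-sum-of-squares identity
    ``n(k-1) * MSW == (k-1) * MSJ + (n-1)(k-1) * MSE`` exactly (up to
    floating-point error), which ties the one-way and two-way decompositions
    together.
    """
    x = matrix.values
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 participants and k >= 2 evaluators, got {n}x{k}")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssb = k * float(np.sum((row_means - grand) ** 2))
    ssw = float(np.sum((x - row_means[:, None]) ** 2))
    ssj = n * float(np.sum((col_means - grand) ** 2))
    sse = float(
        np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    )
    return AnovaMeanSquares(
        msb=ssb / (n - 1),
        msw=ssw / (n * (k - 1)),
        msj=ssj / (k - 1),
        mse=sse / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def classify_fleiss(value: float) -> str:
    """Fleiss qualitative band for a reliability coefficient (boundaries go up)."""
    if value > 1.0:
        raise ValueError(f"ICC value {value} exceeds 1")
    if value < 0.40:
        return "poor"
    if value < 0.75:
        return "fair-to-good"
    return "excellent"


def _safe_ratio(num: float, den: float) -> float:
    if den == 0.0:
        return math.copysign(math.inf, num) if num != 0.0 else math.nan
    return num / den


def _point_estimate(ms: AnovaMeanSquares, form: str) -> float:
    n, k = ms.n, ms.k
    if form == "ICC1":
        return _safe_ratio(ms.msb - ms.msw, ms.msb + (k - 1) * ms.msw)
    if form == "ICC1k":
        return _safe_ratio(ms.msb - ms.msw, ms.msb)
    if form == "ICC2":
        return _safe_ratio(
            ms.msb - ms.mse,
            ms.msb + (k - 1) * ms.mse + k * (ms.msj - ms.mse) / n)
    return _safe_ratio(ms.msb - ms.mse, ms.msb + (ms.msj - ms.mse) / n)


def spearman_brown(icc_single: float, k: int) -> float:
    """Single-measure -> k-measure (average) reliability: k*r / (1 + (k-1)*r)."""
    return _safe_ratio(k * icc_single, 1.0 + (k - 1) * icc_single)


def _icc1_ci(ms: AnovaMeanSquares, alpha: float) -> tuple[float, float, float]:
    n, k = ms.n, ms.k
    df1, df2 = n - 1, n * (k - 1)
    if ms.msw == 0.0:  # perfect within-participant agreement
        return 1.0, 1.0, 0.0
    f_obs = ms.msb / ms.msw
    p = float(stats.f.sf(f_obs, df1, df2))
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return lo, hi, p


def _icc2_ci(ms: AnovaMeanSquares, icc2: float, alpha: float
             ) -> tuple[float, float, float]:
    # Satterthwaite-approximate CI of Shrout & Fleiss / McGraw & Wong
    n, k = ms.n, ms.k
    if ms.mse == 0.0:  # no residual disagreement
        return icc2, icc2, 0.0
    p = float(stats.f.sf(ms.msb / ms.mse, n - 1, (n - 1) * (k - 1)))
    a = k * icc2 / (n * (1 - icc2)) if icc2 < 1 else math.inf
    b = 1 + k * icc2 * (n - 1) / (n * (1 - icc2)) if icc2 < 1 else math.inf
    if not math.isfinite(a) or not math.isfinite(b):
        return icc2, icc2, p
    num = (a * ms.msj + b * ms.mse) ** 2
    den = (a * ms.msj) ** 2 / (k - 1) + (b * ms.mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f_lo = float(stats.f.ppf(1 - alpha / 2, n - 1, v))
    f_hi = float(stats.f.ppf(1 - alpha / 2, v, n - 1))
    lo = n * (ms.msb - f_lo * ms.mse) / (
        f_lo * (k * ms.msj + (k * n - k - n) * ms.mse) + n * ms.msb
    )
    hi = n * (f_hi * ms.msb - ms.mse) / (
        k * ms.msj + (k * n - k - n) * ms.mse + n * f_hi * ms.msb
    )
    return lo, hi, p


def icc(ms: AnovaMeanSquares, form: str, alpha: float = 0.05,
        truncate_negative: bool = False) -> IccEstimate:
    """One ICC form with its F-based 95% CI, p-value, and Fleiss band.

    Forms (k = number of evaluators, n = number of participants):

    * ``ICC1``  = (MSB - MSW) / (MSB + (k-1) MSW)       one-way, single rater
    * ``ICC1k`` = (MSB - MSW) / MSB                      one-way, mean of k
    * ``ICC2``  = (MSB - MSE) / (MSB + (k-1) MSE + k (MSJ - MSE)/n)
                                                         two-way, single rater
    * ``ICC2k`` = (MSB - MSE) / (MSB + (MSJ - MSE)/n)    two-way, mean of k

    Negative estimates are reported as computed unless ``truncate_negative``;
    the band of a negative value is "poor" either way.
    """
    if form not in ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; expected one of {ICC_FORMS}")
    if ms.degenerate:
        raise DegenerateMatrixError(
            "constant score matrix: between- and within-participant variance "
            "are both zero, ICC undefined"
        )
    value = _point_estimate(ms, form)
    n, k = ms.n, ms.k
    if form in ("ICC1", "ICC1k"):
        lo, hi, p = _icc1_ci(ms, alpha)
        if form == "ICC1k":
            lo, hi = spearman_brown(lo, k), spearman_brown(hi, k)
    else:
        icc2 = _point_estimate(ms, "ICC2")
        lo, hi, p = _icc2_ci(ms, icc2, alpha)
        if form == "ICC2k":
            lo, hi = spearman_brown(lo, k), spearman_brown(hi, k)
    if truncate_negative:
        value, lo, hi = max(value, 0.0), max(lo, 0.0), max(hi, 0.0)
    if math.isnan(lo):
        lo = value
    if math.isnan(hi):
        hi = value
    lo, hi = min(lo, value), max(hi, value)  # guard CI ordering at extremes
    return IccEstimate(form=form, value=value, ci_low=lo, ci_high=hi,
                       p_value=p, band=classify_fleiss(min(value, 1.0)))


def icc_all(matrix: ScoreMatrix, forms: tuple[str, ...] = ICC_FORMS,
            **kwargs) -> list[IccEstimate]:
    ms = anova_mean_squares(matrix)
    return [icc(ms, form, **kwargs) for form in forms]


def pairwise_pearson(matrix: ScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    """k x k Pearson correlation grid between evaluator columns, with p-values.

    Returns ``(r, p)`` arrays; the diagonal is r = 1 with p = 0.  A
    zero-variance column yields NaN for every pair that involves it.
    """
    x = matrix.values
    n, k = x.shape
    if n < 3:
        raise ValueError("pairwise Pearson requires n >= 3 participants")
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.std(x[:, i]) == 0 or np.std(x[:, j]) == 0:
                rij, pij = math.nan, math.nan
            else:
                res = stats.pearsonr(x[:, i], x[:, j])
                rij, pij = float(res.statistic), float(res.pvalue)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return r, p


def evaluator_bias_anova(matrix: ScoreMatrix, design: str = "repeated_measures",
                         reference: str | None = None) -> BiasReport:
    """Test for a systematic evaluator (leniency/severity) effect.

    ``repeated_measures`` (default) respects the pairing of scores within a
    participant: F = MSJ / MSE with (k-1) and (n-1)(k-1) degrees of freedom.
    ``one_way`` treats the evaluator columns as independent groups, which is
    how the test is reconstructed from published per-evaluator summary rows.
    Identical columns give F = 0 with p = 1 by convention.
    """
    x = matrix.values
    n, k = x.shape
    if k < 2:
        raise ValueError("evaluator bias ANOVA requires k >= 2 evaluators")
    means = tuple(float(m) for m in x.mean(axis=0))
    sds = tuple(float(s) for s in x.std(axis=0, ddof=1))
    if design == "repeated_measures":
        ms = anova_mean_squares(matrix)
        if ms.mse == 0.0:
            f, p = (0.0, 1.0) if ms.msj == 0.0 else (math.inf, 0.0)
        else:
            f = ms.msj / ms.mse
            p = float(stats.f.sf(f, k - 1, (n - 1) * (k - 1)))
    elif design == "one_way":
        if np.allclose(x, x[:, [0]]):
            f, p = 0.0, 1.0
        else:
            res = stats.f_oneway(*[x[:, j] for j in range(k)])
            f, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown design {design!r}")
    mae = (mae_vs_reference(matrix, reference) if reference is not None else {})
    return BiasReport(
        evaluator_ids=matrix.evaluator_ids,
        evaluator_means=means,
        evaluator_sds=sds,
        anova_f=f,
        anova_p=p,
        design=design,
        reference=reference,
        mae_vs_reference=mae,
    )


def one_way_f_from_summary(means: np.ndarray, sds: np.ndarray, n_per_group: int
                           ) -> tuple[float, float]:
    """Reconstruct a one-way ANOVA F (and p) from per-group mean/SD summaries.

    Useful for checking a published between-evaluator ANOVA when only the
    per-evaluator means and SDs are printed.  Assumes equal group sizes.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    k = means.size
    msb = n_per_group * float(np.var(means, ddof=1))
    msw = float(np.mean(sds**2))
    f = msb / msw
    p = float(stats.f.sf(f, k - 1, k * (n_per_group - 1)))
    return f, p


def mae_vs_reference(matrix: ScoreMatrix, reference: str) -> dict[str, float]:
    """Mean absolute error of each evaluator's participant scores vs a reference.

    ``MAE_r = mean_i |x[i, r] - x[i, ref]|`` for every evaluator except the
    reference itself (whose MAE is identically zero and is omitted).
    """
    ref_idx = matrix.evaluator_index(reference)
    x = matrix.values
    out: dict[str, float] = {}
    for j, eid in enumerate(matrix.evaluator_ids):
        if j == ref_idx:
            continue
        out[eid] = float(np.mean(np.abs(x[:, j] - x[:, ref_idx])))
    return out
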