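"""Extended Bland-Altman agreement analysis for more than two raters.

With k raters per subject the classical difference-vs-mean plot does not
apply directly; following Bland & Altman's recommendation for multiple
observations, each subject is plotted as (mean across raters, intra-subject
standard deviation across raters).  The 95% limit of agreement is the bound
below which the intra-subject spread of 95% of subjects is expected to fall:

* parametric (default): ``LOA = 1.96 * s_w`` where ``s_w = sqrt(MSW)`` is the
  pooled within-subject SD from the one-way ANOVA;
* empirical: the 95th percentile of the observed intra-subject SDs.

A bias-corrected (BC) bootstrap interval for the LOA is obtained by
resampling whole subjects (rows) with replacement, preserving the
within-subject correlation structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import ScoreMatrix
from .agreement import anova_mean_squares

LOA_METHODS = ("parametric", "empirical")


@dataclass(frozen=True)
class BlandAltmanResult:
    participant_ids: tuple[str, ...]
    means: np.ndarray  # per-participant mean across evaluators
    intra_subject_sds: np.ndarray  # per-participant SD across evaluators
    loa: float
    loa_method: str
    bootstrap_ci: tuple[float, float] | None
    n_boot: int
    seed: int | None
    outliers: tuple[str, ...]  # participants with intra-subject SD above LOA
    evaluator_means: tuple[float, ...]


def ba_points(matrix: ScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant (mean across evaluators, intra-subject SD) coordinates.

    The SD is the sample SD over the k evaluator scores (divisor k-1); for
    k = 2 it equals |difference| / sqrt(2), which links this plot back to the
    classical two-rater construction.
    """
    if matrix.k < 2:
        raise ValueError("Bland-Altman points require k >= 2 evaluators")
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    return means, sds


def _loa_from_row_vars(row_vars: np.ndarray, method: str) -> float:
    if method == "parametric":
        return 1.96 * math.sqrt(float(np.mean(row_vars)))
    return float(np.percentile(np.sqrt(row_vars), 95))


def loa(matrix: ScoreMatrix, method: str = "parametric") -> float:
    """95% limit of agreement for the intra-subject SD.

    For a complete matrix the one-way MSW equals the mean of the per-row
    sample variances, so the parametric LOA is ``1.96 * sqrt(mean row var)``.
    """
    if method not in LOA_METHODS:
        raise ValueError(f"unknown LOA method {method!r}; expected {LOA_METHODS}")
    ms = anova_mean_squares(matrix)
    row_vars = matrix.values.var(axis=1, ddof=1)
    if method == "parametric":
        return 1.96 * math.sqrt(ms.msw)
    return _loa_from_row_vars(row_vars, method)


def bootstrap_loa(matrix: ScoreMatrix, n_boot: int = 1000, seed: int | None = None,
                  method: str = "parametric", alpha: float = 0.05,
                  bca: bool = False) -> tuple[float, float]:
    """Bias-corrected bootstrap percentile interval for the LOA.

    Whole participants (rows) are resampled with replacement; the LOA is
    recomputed on each resample.  The default interval applies the
    median-bias correction (BC); ``bca`` adds the jackknife acceleration
    term (BCa).  A seed is required: the resampling stream must be
    reproducible, and it depends only on the rows, not the column order.
    """
    if seed is None:
        raise ValueError("bootstrap_loa requires an explicit seed")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be unstable",
                      stacklevel=2)
    n = matrix.n
    if n < 10:
        warnings.warn(f"bootstrapping only {n} participants; interval is crude",
                      stacklevel=2)
    row_vars = matrix.values.var(axis=1, ddof=1)
    theta_hat = _loa_from_row_vars(row_vars, method)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.array([_loa_from_row_vars(row_vars[ix], method) for ix in idx])

    # median-bias correction
    prop = np.mean(boots < theta_hat) + 0.5 * np.mean(boots == theta_hat)
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = stats.norm.ppf(prop)
    z = stats.norm.ppf(1 - alpha / 2)
    if bca:
        jack = np.array([
            _loa_from_row_vars(np.delete(row_vars, i), method) for i in range(n)
        ])
        d = jack.mean() - jack
        denom = 6.0 * (np.sum(d**2) ** 1.5)
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    else:
        a = 0.0
    lo_q = stats.norm.cdf(z0 + (z0 - z) / (1 - a * (z0 - z)))
    hi_q = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    low, high = np.percentile(boots, [100 * lo_q, 100 * hi_q])
    return float(low), float(high)


def analyze(matrix: ScoreMatrix, method: str = "parametric", n_boot: int = 1000,
            seed: int | None = None, bca: bool = False) -> BlandAltmanResult:
    """Full extended Bland-Altman analysis of a score matrix."""
    means, sds = ba_points(matrix)
    bound = loa(matrix, method=method)
    ci = (bootstrap_loa(matrix, n_boot=n_boot, seed=seed, method=method, bca=bca)
          if n_boot > 0 else None)
    outliers = tuple(
        pid for pid, s in zip(matrix.participant_ids, sds) if s > bound
    )
    return BlandAltmanResult(
        participant_ids=matrix.participant_ids,
        means=means,
        intra_subject_sds=sds,
        loa=bound,
        loa_method=method,
        bootstrap_ci=ci,
        n_boot=n_boot if ci is not None else 0,
        seed=seed,
        outliers=outliers,
        evaluator_means=tuple(float(m) for m in matrix.values.mean(axis=0)),
    )


def classical_two_rater(matrix: ScoreMatrix) -> dict[str, float | np.ndarray]:
    """Classical difference-vs-mean Bland-Altman for exactly two raters.

    Provided as a convenience; the extended intra-subject-SD representation
    is the default for any k.
    """
    if matrix.k != 2:
        raise ValueError("classical Bland-Altman applies to exactly 2 raters")
    diffs = matrix.values[:, 0] - matrix.values[:, 1]
    means = matrix.values.mean(axis=1)
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return {
        "means": means,
        "differences": diffs,
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }
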