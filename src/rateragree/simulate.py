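"""Synthetic assessment-data generators.

Two modes with different purposes:

* **gaussian** — a pure variance-components model for exact reliability
  calibration: ``x[i, r] = mu + b_i + e_ir`` with
  ``b ~ N(0, rho * V)`` and ``e ~ N(0, (1 - rho) * V)``, so the true
  single-rater intraclass correlation is ``rho`` by construction.  Used to
  verify that the ANOVA estimators recover known truth.

* **ordinal** — a latent-trait emulation of a 3-category accuracy-scoring
  study: participant skill ``theta_i``, item difficulty ``delta_j`` and
  rater leniency ``beta_r`` combine on a latent scale,
  ``z_ijr = theta_i - delta_j + beta_r + eps_ijr`` with standard-normal
  noise, and two cutpoints map ``z`` to scores 0 / 50 / 100.  The default
  calibration reproduces a cohort whose pooled category frequencies are
  about 66 / 22 / 12 percent (correct / minor / major), with one rater about
  8 points stricter than the panel.

One global seed feeds independent substreams (skills, difficulties, noise,
missingness), so e.g. changing the number of items does not perturb the
participant skills.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .records import InterpretationRecord, ScoreMatrix

#: pooled target frequencies for (major=0, minor=50, correct=100); the
#: printed study marginals 12.3 / 21.5 / 66.1 normalized to sum to one
DEFAULT_MARGINAL = (0.123 / 0.999, 0.215 / 0.999, 0.661 / 0.999)

#: default per-rater leniency shifts (latent units); the second rater is the
#: systematically stricter one
DEFAULT_RATER_BIAS = (0.0, -0.35, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Gaussian mode uses ``icc_target``, ``grand_mean`` and ``total_var``
    (percent^2).  Ordinal mode uses the latent-trait parameters:
    ``skill_sd`` and ``item_difficulty_sd`` are SDs in latent (probit)
    units, ``rater_bias`` per-rater latent shifts, and ``cutpoints`` the two
    thresholds mapping latent values to the 0/50/100 scale (``None`` means
    "calibrate so the pooled marginal matches ``target_marginal``").
    """

    mode: str = "ordinal"
    n_participants: int = 192
    n_items: int = 19
    n_raters: int = 4
    # gaussian mode
    icc_target: float = 0.74
    grand_mean: float = 76.6
    total_var: float = 13.7**2
    # ordinal mode
    skill_sd: float = 0.8
    item_difficulty_sd: float = 0.5
    rater_bias: tuple[float, ...] = DEFAULT_RATER_BIAS
    cutpoints: tuple[float, float] | None = None
    target_marginal: tuple[float, float, float] = DEFAULT_MARGINAL
    response_rate_model: dict | None = None
    selectivity: float = 0.0  # >0: higher-skill participants answer more items
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("gaussian", "ordinal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "gaussian" and not (0.0 <= self.icc_target < 1.0):
            raise ValueError(f"icc_target must be in [0, 1), got {self.icc_target}")
        if len(self.rater_bias) != self.n_raters:
            raise ValueError("rater_bias length must equal n_raters")
        if self.cutpoints is not None and not self.cutpoints[0] < self.cutpoints[1]:
            raise ValueError("cutpoints must be strictly increasing")
        tm = self.target_marginal
        if abs(sum(tm) - 1.0) > 1e-6 or any(p <= 0 for p in tm):
            raise ValueError(f"target marginal {tm} is not a valid simplex")


def _streams(seed: int, n: int = 4) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def calibrate_cutpoints(config: SimulationConfig) -> tuple[float, float]:
    """Solve the two latent thresholds matching the target pooled marginal.

    The pooled latent score for rater r is N(beta_r, s^2) with
    ``s^2 = skill_sd^2 + item_difficulty_sd^2 + 1``; the cutpoints are
    chosen numerically so that the frequency of each category, averaged over
    the configured rater biases, equals the target marginal.  With all
    biases zero this reduces to scaled normal quantiles.
    """
    s = math.sqrt(config.skill_sd**2 + config.item_difficulty_sd**2 + 1.0)
    betas = np.asarray(config.rater_bias, dtype=float)
    p0, p50, _ = config.target_marginal

    def pooled_cdf(c: float) -> float:
        return float(np.mean(stats.norm.cdf((c - betas) / s)))

    lo, hi = -10.0 * s, 10.0 * s
    c1 = optimize.brentq(lambda c: pooled_cdf(c) - p0, lo, hi, xtol=1e-12)
    c2 = optimize.brentq(lambda c: pooled_cdf(c) - (p0 + p50), lo, hi, xtol=1e-12)
    if not c1 < c2:
        raise ValueError("calibrated cutpoints are not increasing; "
                         "target marginal too extreme for the latent scale")
    return c1, c2


def simulate_gaussian(config: SimulationConfig) -> ScoreMatrix:
    """One score matrix from the Gaussian variance-components model."""
    if config.mode != "gaussian":
        raise ValueError("config.mode must be 'gaussian'")
    n, k = config.n_participants, config.n_raters
    rho, v = config.icc_target, config.total_var
    rng_b, rng_e = _streams(config.seed, 2)
    b = rng_b.normal(0.0, math.sqrt(rho * v), size=n)
    e = rng_e.normal(0.0, math.sqrt((1.0 - rho) * v), size=(n, k))
    values = config.grand_mean + b[:, None] + e
    return ScoreMatrix(
        participant_ids=tuple(f"P{i+1:03d}" for i in range(n)),
        evaluator_ids=tuple(f"E{r+1}" for r in range(k)),
        values=values,
        n_items_per_participant=tuple([1] * n),
    )


def _draw_item_counts(config: SimulationConfig, theta: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-participant number of answered items under the response-rate model.

    ``None`` means every participant answers every item.  A
    ``{"kind": "bins", "bins": [[lo, hi, prob], ...]}`` model draws the
    count from binned ranges (uniform within a bin, capped at n_items); a
    ``{"kind": "binomial", "p": p}`` model answers each item independently.
    With ``selectivity > 0`` the response propensity increases with the
    participant's latent skill, emulating confidence-driven self-selection.
    """
    n, m = config.n_participants, config.n_items
    model = config.response_rate_model
    if model is None:
        return np.full(n, m, dtype=int)
    kind = model.get("kind")
    if kind == "bins":
        bins = model["bins"]
        probs = np.array([b[2] for b in bins], dtype=float)
        probs = probs / probs.sum()
        if config.selectivity > 0:
            # shift each participant's bin draw toward higher bins with skill
            u = stats.norm.cdf(
                stats.norm.ppf(rng.random(n)) + config.selectivity * theta
            )
            cum = np.cumsum(probs)
            which = np.searchsorted(cum, u, side="right").clip(0, len(bins) - 1)
        else:
            which = rng.choice(len(bins), size=n, p=probs)
        lows = np.array([b[0] for b in bins], dtype=int)
        highs = np.minimum(np.array([b[1] for b in bins], dtype=int), m)
        counts = rng.integers(lows[which], highs[which] + 1)
        return counts.clip(1, m)
    if kind == "binomial":
        p = float(model["p"])
        if config.selectivity > 0:
            logit = math.log(p / (1 - p)) + config.selectivity * theta
            p_i = 1.0 / (1.0 + np.exp(-logit))
        else:
            p_i = np.full(n, p)
        counts = rng.binomial(m, p_i)
        return counts.clip(1, m)
    raise ValueError(f"unknown response_rate_model kind {kind!r}")


def simulate_ordinal(config: SimulationConfig) -> list[InterpretationRecord]:
    """Latent-trait ordinal records: every answered item scored by all raters."""
    if config.mode != "ordinal":
        raise ValueError("config.mode must be 'ordinal'")
    n, m, k = config.n_participants, config.n_items, config.n_raters
    c1, c2 = (config.cutpoints if config.cutpoints is not None
              else calibrate_cutpoints(config))
    rng_skill, rng_item, rng_noise, rng_miss = _streams(config.seed, 4)
    theta = rng_skill.normal(0.0, config.skill_sd, size=n)
    delta = rng_item.normal(0.0, config.item_difficulty_sd, size=m)
    beta = np.asarray(config.rater_bias, dtype=float)
    counts = _draw_item_counts(config, theta, rng_miss)
    records: list[InterpretationRecord] = []
    for i in range(n):
        answered = np.sort(rng_miss.choice(m, size=counts[i], replace=False))
        eps = rng_noise.standard_normal((counts[i], k))
        z = theta[i] - delta[answered][:, None] + beta[None, :] + eps
        score = np.where(z > c2, 100, np.where(z > c1, 50, 0))
        for jj, j in enumerate(answered):
            for r in range(k):
                records.append(InterpretationRecord(
                    participant_id=f"P{i+1:03d}",
                    item_id=f"ECG{j+1:02d}",
                    evaluator_id=f"E{r+1}",
                    category={100: "correct", 50: "minor_misdiagnosis",
                              0: "major_misdiagnosis"}[int(score[jj, r])],
                ))
    return records


#: response-count distribution of the emulated cohort: about 44% of
#: participants answer fewer than five items, and counts span 1..19
STUDY_RESPONSE_BINS = [
    [1, 4, 0.4375],
    [5, 10, 0.1979],
    [11, 15, 0.1615],
    [16, 19, 0.2031],
]


def study_shaped_config(seed: int = 0) -> SimulationConfig:
    """The default study-shaped cohort: 192 participants, 19 items, 4 raters."""
    return SimulationConfig(
        mode="ordinal",
        n_participants=192,
        n_items=19,
        n_raters=4,
        response_rate_model={"kind": "bins", "bins": STUDY_RESPONSE_BINS},
        seed=seed,
    )


def study_shaped_dataset(seed: int = 0) -> list[InterpretationRecord]:
    """Generate the default study-shaped cohort of ordinal records."""
    return simulate_ordinal(study_shaped_config(seed))


def replicate_gaussian_icc(config: SimulationConfig, n_reps: int,
                           seed: int) -> np.ndarray:
    """ICC(1) and ICC(1k) estimates over repeated Gaussian simulations.

    Returns an array of shape (n_reps, 2) with columns (ICC1, ICC1k); used
    for estimator-recovery studies.  Each replicate gets an independent
    substream spawned from ``seed``.
    """
    from .agreement import anova_mean_squares, icc

    out = np.empty((n_reps, 2))
    for rep, child in enumerate(np.random.SeedSequence(seed).spawn(n_reps)):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        mat = simulate_gaussian(replace(config, seed=child_seed))
        ms = anova_mean_squares(mat)
        out[rep, 0] = icc(ms, "ICC1").value
        out[rep, 1] = icc(ms, "ICC1k").value
    return out
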