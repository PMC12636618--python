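"""Summary statistics and fits for comparing conditions and observers.

Accuracy (absolute error summaries), precision (mean absolute deviation),
sensitivity (d-prime with rate clipping), psychometric-function fits on
log f0-difference with 2AFC floor, bootstrap confidence intervals,
split-half reliability with Spearman–Brown and attenuation corrections,
and the pooled z-scored human–model similarity machinery with a paired
bootstrap test on correlation differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

__all__ = [
    "PsychometricFit", "absolute_error_summary", "mad_precision", "dprime",
    "fit_psychometric", "bootstrap_ci", "spearman_brown",
    "split_half_reliability", "reliability_corrected_correlation",
    "aggregate_similarity", "paired_delta_r_test",
]


def absolute_error_summary(table, estimator: str = "median_then_mean",
                           condition_col: str = "condition",
                           unit_col: str = "unit",
                           error_col: str = "abs_error"):
    """Per-condition absolute-error summary.

    ``median_then_mean``: median absolute error within each unit
    (participant/model), then averaged across units — the human analysis.
    ``mean_then_mean``: mean within unit, then averaged — the model
    analysis. Returns a pandas Series indexed by condition.
    """
    if estimator not in ("median_then_mean", "mean_then_mean"):
        raise ValueError(f"unknown estimator {estimator!r}")
    inner = "median" if estimator == "median_then_mean" else "mean"
    per_unit = table.groupby([condition_col, unit_col])[error_col].agg(inner)
    return per_unit.groupby(level=0).mean()


def mad_precision(responses, pooling: str = "pooled") -> float:
    """Mean absolute deviation of responses around their mean (degrees).

    ``responses``: 1-D array (already pooled across subjects) or list of
    per-unit arrays with ``pooling="per_unit"`` (MAD per unit, then mean).
    """
    if pooling == "pooled":
        x = np.asarray(responses, dtype=float)
        return float(np.mean(np.abs(x - x.mean())))
    if pooling == "per_unit":
        return float(np.mean([mad_precision(r, "pooled") for r in responses]))
    raise ValueError(f"unknown pooling {pooling!r}")


def dprime(hits: int, misses: int, false_alarms: int,
           correct_rejections: int) -> float:
    """Sensitivity d' = z(H) − z(FA), with per-class rate clipping.

    Rates are clipped to [1/(2n), 1 − 1/(2n)] for class size n, so
    perfect or null performance yields finite values.
    """
    n_signal = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_signal < 1 or n_noise < 1:
        raise ValueError("need at least one signal and one noise trial")

    def rate(k, n):
        return float(np.clip(k / n, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))
    return float(norm.ppf(rate(hits, n_signal))
                 - norm.ppf(rate(false_alarms, n_noise)))


@dataclass(frozen=True)
class PsychometricFit:
    location: float              # m, in log %-difference units
    scale: float                 # s > 0
    threshold_pct: float         # in (0, 100]
    ci_low: float | None = None
    ci_high: float | None = None
    degenerate: bool = False

    def __post_init__(self):
        if not 0.0 < self.threshold_pct <= 100.0:
            raise ValueError("threshold_pct must be in (0, 100]")

    def predict(self, diff_pct):
        d = np.asarray(diff_pct, dtype=float)
        return 0.5 + 0.5 * norm.cdf((np.log(d) - self.location) / self.scale)


_CRITERION = 0.707


def fit_psychometric(diff_pct, prop_correct, criterion: float = _CRITERION,
                     cap_pct: float = 100.0) -> PsychometricFit:
    """Least-squares normal-CDF fit to a 2AFC psychometric function.

    Model: p(Δ) = 0.5 + 0.5·Φ((log Δ − m)/s) on the percent-difference
    axis; threshold = exp(m + s·Φ⁻¹(2·criterion − 1)), capped at
    ``cap_pct``. Degenerate data (at-floor, at-ceiling, or decreasing)
    are flagged; at-floor data get the capped threshold.
    """
    d = np.asarray(diff_pct, dtype=float)
    p = np.asarray(prop_correct, dtype=float)
    if d.size < 3 or d.size != p.size:
        raise ValueError("need >= 3 (diff, proportion) points")
    if np.any(d <= 0):
        raise ValueError("differences must be positive")
    logd = np.log(d)

    def resid(theta):
        m, log_s = theta
        return 0.5 + 0.5 * norm.cdf((logd - m) / np.exp(log_s)) - p

    at_floor = np.all(p <= 0.52)
    at_ceiling = np.all(p >= 0.98)
    slope = np.polyfit(logd, p, 1)[0]
    degenerate = bool(at_floor or at_ceiling or slope <= 0)
    if at_floor:
        return PsychometricFit(location=float(np.log(cap_pct)), scale=1.0,
                               threshold_pct=cap_pct, degenerate=True)
    # initialize from the empirical crossing of the criterion
    m0 = float(np.interp(criterion, np.clip(p, 0.5, 1.0), logd,
                         left=logd[0], right=logd[-1]))
    sol = least_squares(resid, x0=np.array([m0, 0.0]), method="lm",
                        max_nfev=2000)
    m, s = float(sol.x[0]), float(np.exp(sol.x[1]))
    thr = float(np.exp(m + s * norm.ppf(2 * criterion - 1)))
    thr = min(thr, cap_pct)
    thr = max(thr, np.finfo(float).tiny)
    return PsychometricFit(location=m, scale=s, threshold_pct=thr,
                           degenerate=degenerate)


def bootstrap_ci(statistic, units, n_boot: int = 1024, seed: int = 0,
                 alpha: float = 0.05):
    """Percentile bootstrap over resampled units.

    ``statistic(list_of_units) -> float``; ``units``: sequence of
    resampling units (participants, conditions...). Returns
    (low, high, sd) of the bootstrap distribution.
    """
    units = list(units)
    if not units:
        raise ValueError("no units to resample")
    rng = np.random.default_rng(seed)
    n = len(units)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = statistic([units[i] for i in idx])
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi), float(vals.std(ddof=1))


def spearman_brown(r_half: float) -> float:
    """Spearman–Brown step-up of a split-half correlation: 2r/(1+r)."""
    return 2.0 * r_half / (1.0 + r_half)


def _pearson(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def split_half_reliability(trial_values: np.ndarray,
                           condition_ids: np.ndarray) -> float:
    """Split-half reliability of per-condition means, Spearman–Brown
    corrected. Halves are formed by alternating trial parity within each
    condition (deterministic and balanced)."""
    v = np.asarray(trial_values, dtype=float)
    cid = np.asarray(condition_ids)
    conds = np.unique(cid)
    even, odd = [], []
    for c in conds:
        x = v[cid == c]
        if x.size < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 trials")
        even.append(x[0::2].mean())
        odd.append(x[1::2].mean())
    return spearman_brown(_pearson(even, odd))


def reliability_corrected_correlation(x, y, r_xx: float, r_yy: float) -> float:
    """Attenuation-corrected correlation r_xy / sqrt(r_xx · r_yy), clipped
    to [−1, 1]. Reliabilities should already be Spearman–Brown corrected."""
    if r_xx <= 0 or r_yy <= 0:
        raise ValueError("reliabilities must be positive")
    r = _pearson(x, y) / np.sqrt(r_xx * r_yy)
    return float(np.clip(r, -1.0, 1.0))


def _zscore_blocks(values: np.ndarray, experiment_ids: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float).copy()
    eid = np.asarray(experiment_ids)
    for e in np.unique(eid):
        m = eid == e
        sd = v[m].std()
        v[m] = (v[m] - v[m].mean()) / (sd if sd > 0 else 1.0)
    return v


def aggregate_similarity(human, model, experiment_ids, n_boot: int = 1024,
                         seed: int = 0):
    """Pooled human–model similarity across experiments.

    Each per-condition value is z-scored within its experiment block, the
    blocks are pooled, and the Pearson correlation computed; the CI is a
    bootstrap over conditions. Returns (r, ci_low, ci_high).
    """
    h = _zscore_blocks(human, experiment_ids)
    m = _zscore_blocks(model, experiment_ids)
    r = _pearson(h, m)
    rows = list(zip(h, m))

    def stat(rs):
        a = np.array([t[0] for t in rs])
        b = np.array([t[1] for t in rs])
        return _pearson(a, b)
    lo, hi, _ = bootstrap_ci(stat, rows, n_boot=n_boot, seed=seed)
    return float(r), lo, hi


def paired_delta_r_test(human, model_a, model_b, experiment_ids,
                        n_boot: int = 1024, seed: int = 0):
    """One-tailed paired bootstrap test of Δr = r(human, A) − r(human, B).

    Conditions are resampled identically for both models (paired); the
    p-value is the fraction of bootstrap Δr values ≤ 0. Returns
    (delta_r, p_value).
    """
    h = _zscore_blocks(human, experiment_ids)
    a = _zscore_blocks(model_a, experiment_ids)
    b = _zscore_blocks(model_b, experiment_ids)
    n = h.size
    if not (a.size == b.size == n):
        raise ValueError("inputs must share length")
    delta = _pearson(h, a) - _pearson(h, b)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        deltas[i] = _pearson(h[idx], a[idx]) - _pearson(h[idx], b[idx])
    p = float(np.mean(deltas <= 0.0))
    return float(delta), p
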