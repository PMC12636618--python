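import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from percept import psychometrics as ps


# ---------------------------------------------------------------------------
# absolute error, MAD
# ---------------------------------------------------------------------------

def test_absolute_error_hand_built():
    t = pd.DataFrame({"condition": ["a"] * 3, "unit": [1] * 3,
                      "abs_error": [1.0, 2.0, 9.0]})
    assert ps.absolute_error_summary(t, "median_then_mean")["a"] == 2.0
    assert ps.absolute_error_summary(t, "mean_then_mean")["a"] == 4.0


def test_absolute_error_all_correct():
    t = pd.DataFrame({"condition": list("ab") * 4, "unit": [1, 2] * 4,
                      "abs_error": [0.0] * 8})
    assert (ps.absolute_error_summary(t, "median_then_mean") == 0).all()


def test_absolute_error_matches_bruteforce(rng):
    t = pd.DataFrame({
        "condition": rng.choice(list("abc"), 300),
        "unit": rng.integers(0, 5, 300),
        "abs_error": rng.exponential(size=300)})
    ours = ps.absolute_error_summary(t, "median_then_mean")
    for cond in "abc":
        sub = t[t.condition == cond]
        medians = [np.median(sub[sub.unit == u].abs_error)
                   for u in sorted(sub.unit.unique())]
        assert ours[cond] == pytest.approx(np.mean(medians), abs=1e-12)


def test_mad_oracle(rng):
    assert ps.mad_precision([5.0, 5.0, 5.0]) == 0.0
    assert ps.mad_precision([-1.0, 1.0]) == 1.0
    x = rng.normal(size=1000)
    assert ps.mad_precision(x) == pytest.approx(
        np.abs(x - x.mean()).mean(), abs=1e-12)
    groups = [rng.normal(size=50) for _ in range(4)]
    assert ps.mad_precision(groups, "per_unit") == pytest.approx(
        np.mean([np.abs(g - g.mean()).mean() for g in groups]), abs=1e-12)


# ---------------------------------------------------------------------------
# d-prime
# ---------------------------------------------------------------------------

def test_dprime_oracles():
    assert ps.dprime(84, 16, 16, 84) == pytest.approx(
        norm.ppf(0.84) - norm.ppf(0.16), abs=1e-10)
    assert ps.dprime(84, 16, 16, 84) == pytest.approx(1.9889, abs=1e-3)
    assert ps.dprime(50, 50, 50, 50) == 0.0
    # perfect with n=10 -> rates clipped to 0.95 / 0.05
    assert ps.dprime(10, 0, 0, 10) == pytest.approx(
        norm.ppf(0.95) - norm.ppf(0.05), abs=1e-10)
    assert ps.dprime(10, 0, 0, 10) == pytest.approx(3.29, abs=0.01)


def test_dprime_antisymmetry(rng):
    for _ in range(20):
        h, m = rng.integers(1, 50, 2)
        fa, cr = rng.integers(1, 50, 2)
        assert ps.dprime(h, m, fa, cr) == pytest.approx(
            -ps.dprime(fa, cr, h, m), abs=1e-10)


def test_dprime_requires_trials():
    with pytest.raises(ValueError):
        ps.dprime(0, 0, 1, 1)


# ---------------------------------------------------------------------------
# psychometric fits
# ---------------------------------------------------------------------------

def test_fit_recovery_within_10pct():
    m_true, s_true = np.log(1.5), 0.6
    diffs = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
    rng = np.random.default_rng(6)
    p_true = 0.5 + 0.5 * norm.cdf((np.log(diffs) - m_true) / s_true)
    p_obs = rng.binomial(500, p_true) / 500
    fit = ps.fit_psychometric(diffs, p_obs)
    thr_true = np.exp(m_true + s_true * norm.ppf(2 * 0.707 - 1))
    assert fit.threshold_pct == pytest.approx(thr_true, rel=0.10)
    assert not fit.degenerate


def test_fit_floor_capped():
    diffs = np.array([0.5, 1.0, 2.0, 4.0])
    fit = ps.fit_psychometric(diffs, np.full(4, 0.5))
    assert fit.threshold_pct == 100.0 and fit.degenerate


def test_fit_ceiling_flagged():
    diffs = np.array([0.5, 1.0, 2.0, 4.0])
    fit = ps.fit_psychometric(diffs, np.ones(4))
    assert fit.degenerate and fit.threshold_pct <= 0.5


def test_fit_unit_invariance():
    # percent vs proportion scaling of the difference axis shifts the
    # location but scales the threshold identically
    diffs = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
    p = np.array([0.55, 0.65, 0.8, 0.93, 0.99])
    thr_pct = ps.fit_psychometric(diffs, p).threshold_pct
    thr_prop = ps.fit_psychometric(diffs / 100.0, p,
                                   cap_pct=1.0).threshold_pct
    assert thr_pct == pytest.approx(thr_prop * 100.0, rel=1e-6)


def test_fit_requires_three_points():
    with pytest.raises(ValueError):
        ps.fit_psychometric([1.0, 2.0], [0.6, 0.9])


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_constant_zero_width():
    lo, hi, sd = ps.bootstrap_ci(lambda u: float(np.mean(u)), [3.0] * 10,
                                 seed=0)
    assert lo == hi == 3.0 and sd == 0.0


def test_bootstrap_seed_reproducible(rng):
    units = list(rng.normal(size=20))
    a = ps.bootstrap_ci(lambda u: float(np.mean(u)), units, seed=4)
    b = ps.bootstrap_ci(lambda u: float(np.mean(u)), units, seed=4)
    assert a == b


def test_bootstrap_matches_bruteforce_replication(rng):
    # identical resampling with the same generator sequence
    units = list(rng.normal(size=12))
    lo, hi, sd = ps.bootstrap_ci(lambda u: float(np.mean(u)), units,
                                 n_boot=256, seed=9)
    r = np.random.default_rng(9)
    vals = np.array([np.mean([units[i] for i in r.integers(0, 12, 12)])
                     for _ in range(256)])
    elo, ehi = np.percentile(vals, [2.5, 97.5])
    assert lo == pytest.approx(elo, abs=1e-12)
    assert hi == pytest.approx(ehi, abs=1e-12)
    assert sd == pytest.approx(vals.std(ddof=1), abs=1e-12)


def test_bootstrap_coverage():
    # 95% CI for a normal mean: coverage approximately 0.95
    rng = np.random.default_rng(123)
    hits = 0
    n_rep = 300
    for i in range(n_rep):
        x = list(rng.normal(size=25))
        lo, hi, _ = ps.bootstrap_ci(lambda u: float(np.mean(u)), x,
                                    n_boot=256, seed=i)
        hits += lo <= 0.0 <= hi
    assert hits / n_rep == pytest.approx(0.95, abs=0.04)


# ---------------------------------------------------------------------------
# reliability and aggregation
# ---------------------------------------------------------------------------

def test_spearman_brown_closed_form():
    assert ps.spearman_brown(1 / 3) == pytest.approx(0.5, abs=1e-12)
    assert ps.spearman_brown(1.0) == 1.0


def test_perfectly_reliable_corrected_equals_raw(rng):
    x = rng.normal(size=50)
    y = x + rng.normal(size=50) * 0.5
    raw = np.corrcoef(x, y)[0, 1]
    assert ps.reliability_corrected_correlation(x, y, 1.0, 1.0) == \
        pytest.approx(raw, abs=1e-12)


def test_corrected_r_recovers_truth():
    # true scores correlate 0.8; noisy measures attenuate it
    rng = np.random.default_rng(11)
    n, n_cond = 200, 60
    rho = 0.8
    recovered = []
    for _ in range(8):
        t1 = rng.normal(size=n_cond)
        t2 = rho * t1 + np.sqrt(1 - rho ** 2) * rng.normal(size=n_cond)
        # per-condition trial noise
        x_trials = t1[None, :] + rng.normal(size=(20, n_cond)) * 1.0
        y_trials = t2[None, :] + rng.normal(size=(20, n_cond)) * 1.0
        x, y = x_trials.mean(0), y_trials.mean(0)
        rxx = ps.split_half_reliability(x_trials.T.ravel(),
                                        np.repeat(np.arange(n_cond), 20))
        ryy = ps.split_half_reliability(y_trials.T.ravel(),
                                        np.repeat(np.arange(n_cond), 20))
        recovered.append(
            ps.reliability_corrected_correlation(x, y, rxx, ryy))
    assert np.mean(recovered) == pytest.approx(rho, abs=0.05)


def test_split_half_requires_two_trials():
    with pytest.raises(ValueError):
        ps.split_half_reliability(np.array([1.0, 2.0]), np.array([0, 1]))


def test_aggregate_identical_tables(rng):
    h = rng.normal(size=30)
    eid = np.repeat([0, 1, 2], 10)
    r, lo, hi = ps.aggregate_similarity(h, h.copy(), eid, n_boot=64, seed=0)
    assert r == pytest.approx(1.0, abs=1e-12)


def test_aggregate_zscore_shift_invariance(rng):
    h = rng.normal(size=30)
    m = h + rng.normal(size=30) * 0.4
    eid = np.repeat([0, 1, 2], 10)
    r1, *_ = ps.aggregate_similarity(h, m, eid, n_boot=8, seed=0)
    h2 = h.copy()
    h2[:10] += 7.5
    r2, *_ = ps.aggregate_similarity(h2, m, eid, n_boot=8, seed=0)
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_paired_delta_r_detects_better_model():
    rng = np.random.default_rng(17)
    wins = 0
    for i in range(20):
        h = rng.normal(size=40)
        eid = np.repeat([0, 1], 20)
        a = h + rng.normal(size=40) * 0.2
        b = rng.permutation(h)
        d, p = ps.paired_delta_r_test(h, a, b, eid, n_boot=256, seed=i)
        wins += (d > 0) and (p < 0.05)
    assert wins >= 19
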