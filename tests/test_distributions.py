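import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

from percept import distributions as d


# ---------------------------------------------------------------------------
# log I0: converged power-series oracle
# ---------------------------------------------------------------------------

def _log_i0_series(kappa: float) -> float:
    """Converged power series for log I0 (oracle)."""
    from math import lgamma, log, exp
    x2 = (kappa / 2.0) ** 2
    terms = []
    log_term = 0.0
    for m in range(0, 600):
        log_term = m * np.log(x2) - 2 * lgamma(m + 1) if x2 > 0 else (
            0.0 if m == 0 else -np.inf)
        terms.append(log_term)
        if m > 4 and log_term < max(terms) - 60:
            break
    mx = max(terms)
    return mx + log(sum(exp(t - mx) for t in terms))


def test_log_i0_matches_series_oracle():
    kappas = np.concatenate([np.linspace(0, 3.75, 60),
                             np.linspace(3.75, 512.0, 150)])
    ours = d.log_i0(kappas)
    oracle = np.array([_log_i0_series(k) for k in kappas])
    assert np.max(np.abs(ours - oracle)) < 1e-4


def test_log_i0_continuous_at_switch():
    eps = 1e-9
    below = float(d.log_i0(np.array([3.75 - eps]))[0])
    above = float(d.log_i0(np.array([3.75 + eps]))[0])
    assert abs(below - above) < 1e-5


def test_log_i0_zero():
    assert float(d.log_i0(np.array([0.0]))[0]) == pytest.approx(0.0, abs=1e-7)


# ---------------------------------------------------------------------------
# densities integrate to one
# ---------------------------------------------------------------------------

def _vm_mixture(seed=0, K=3):
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(K))
    means = rng.uniform(-np.pi, np.pi, size=(K, 2))
    conc = rng.uniform(0.5, 60.0, size=(K, 2))
    return d.VonMisesMixture(weights=w, means=means, concentrations=conc)


def test_vm_mixture_integrates_to_one():
    m = _vm_mixture(3)
    n = 360
    az = np.linspace(-np.pi, np.pi, n, endpoint=False)
    el = np.linspace(-np.pi, np.pi, n, endpoint=False)
    A, E = np.meshgrid(az, el, indexing="ij")
    pts = np.stack([A.ravel(), E.ravel()], axis=1)          # (n*n, 2)
    # vectorized density over the torus grid
    logi0 = np.asarray(d.log_i0(m.concentrations))
    comp = (np.log(m.weights)[None, :]
            + np.sum(m.concentrations[None] * np.cos(
                pts[:, None, :] - m.means[None]) - d.LOG_2PI - logi0[None],
                axis=2))
    mx = comp.max(axis=1, keepdims=True)
    p = np.exp(mx[:, 0]) * np.exp(comp - mx).sum(axis=1)
    # spot-check the vectorization against the scalar implementation
    assert np.log(p[1234]) == pytest.approx(
        d.vm_mixture_logpdf(pts[1234], m), abs=1e-10)
    integral = p.sum() * (2 * np.pi / n) ** 2
    assert integral == pytest.approx(1.0, abs=1e-3)


def test_gm_mixture_integrates_to_one():
    rng = np.random.default_rng(7)
    m = d.GaussianMixture1D(weights=rng.dirichlet(np.ones(4)),
                            means=rng.uniform(4, 9, 4),
                            variances=rng.uniform(0.01, 0.5, 4))
    s = np.linspace(-5, 20, 100001)
    comp = (np.log(m.weights)[None] - 0.5 * np.log(2 * np.pi * m.variances)
            - (s[:, None] - m.means[None]) ** 2 / (2 * m.variances[None]))
    p = np.exp(comp).sum(axis=1)
    assert np.log(p[50000]) == pytest.approx(
        d.gm_mixture_logpdf(s[50000], m), abs=1e-10)
    assert np.trapezoid(p, s) == pytest.approx(1.0, abs=1e-3)


def test_von_mises_kappa0_is_uniform():
    lp = d.von_mises_logpdf(np.array(1.2), 0.3, 0.0)
    assert float(lp) == pytest.approx(-np.log(2 * np.pi), abs=1e-12)


def test_vm_logpdf_rotation_invariance():
    m = _vm_mixture(11)
    x = np.array([0.4, -1.1])
    shift = 0.73
    m2 = d.VonMisesMixture(weights=m.weights,
                           means=d.wrap_angle(m.means + shift),
                           concentrations=m.concentrations)
    assert d.vm_mixture_logpdf(d.wrap_angle(x + shift), m2) == pytest.approx(
        d.vm_mixture_logpdf(x, m), abs=1e-10)


def test_kappa_512_normal_variance_limit():
    # large-kappa von Mises ~ wrapped normal, variance 1/kappa
    s = d.sample_von_mises_mixture(
        d.VonMisesMixture(weights=np.array([1.0]),
                          means=np.array([[0.0, 0.0]]),
                          concentrations=np.array([[512.0, 512.0]])),
        100000, seed=5)
    assert np.var(s[:, 0]) == pytest.approx(1.0 / 512.0, rel=0.05)


# ---------------------------------------------------------------------------
# constraint transforms
# ---------------------------------------------------------------------------

def test_constrain_weights_simplex(rng):
    u = rng.normal(size=7)
    w = d.constrain_weights(u)
    w = np.asarray(w if not hasattr(w, "data") else w.data)
    assert np.all(w > 0) and w.sum() == pytest.approx(1.0, abs=1e-12)


def test_relux_bounds():
    x = np.linspace(-100, 1000, 5001)
    y = np.asarray(d.relux(x, 1.0, 512.0))
    assert y.min() >= 1.0 and y.max() <= 512.0
    inside = (x > 1.0) & (x < 512.0)
    assert np.allclose(y[inside], x[inside])


def test_constrain_variance_positive(rng):
    v = np.asarray(d.constrain_variance(rng.normal(size=100) * 10))
    assert np.all(v >= 1e-9)


def test_constrain_circular_mean_range(rng):
    u, v = rng.normal(size=50), rng.normal(size=50)
    mu = np.asarray(d.constrain_circular_mean(u, v))
    assert np.all(mu >= -np.pi) and np.all(mu <= np.pi)


def test_wrap_angle_interval():
    x = np.array([-np.pi, np.pi, 3 * np.pi, -7.5, 7.5, 0.0])
    w = d.wrap_angle(x)
    assert np.all(w > -np.pi - 1e-12) and np.all(w <= np.pi + 1e-12)
    assert d.wrap_angle(np.pi + 0.1) == pytest.approx(-np.pi + 0.1)


# ---------------------------------------------------------------------------
# sampling and serialization
# ---------------------------------------------------------------------------

def test_sampling_deterministic_and_moments():
    m = _vm_mixture(2)
    a = d.sample_von_mises_mixture(m, 1000, seed=9)
    b = d.sample_von_mises_mixture(m, 1000, seed=9)
    assert np.array_equal(a, b)

    gm = d.GaussianMixture1D(weights=np.array([0.3, 0.7]),
                             means=np.array([4.0, 6.0]),
                             variances=np.array([0.04, 0.09]))
    s = d.sample_gaussian_mixture(gm, 200000, seed=3)
    assert s.mean() == pytest.approx(0.3 * 4 + 0.7 * 6, abs=0.01)


def test_mixture_json_roundtrip():
    m = _vm_mixture(4)
    m2 = d.VonMisesMixture.from_json(json.loads(json.dumps(m.to_json())))
    assert np.allclose(m2.weights, m.weights)
    assert np.allclose(m2.means, m.means)
    assert np.allclose(m2.concentrations, m.concentrations)


def test_invalid_weights_rejected():
    with pytest.raises(ValueError):
        d.VonMisesMixture(weights=np.array([0.5, 0.6]),
                          means=np.zeros((2, 2)),
                          concentrations=np.ones((2, 2)))


def test_univariate_gaussian_nll_closed_form():
    x, mu, var = 1.3, 0.5, 0.7
    expect = 0.5 * np.log(2 * np.pi * var) + (x - mu) ** 2 / (2 * var)
    assert float(d.univariate_gaussian_nll(x, mu, var)) == pytest.approx(
        expect, abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(hs.floats(min_value=-50, max_value=50),
       hs.floats(min_value=0.01, max_value=500.0))
def test_von_mises_logpdf_finite(mu, kappa):
    lp = d.von_mises_logpdf(np.array(0.7), mu, kappa)
    assert np.isfinite(float(lp))
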