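"""Mixture distributions, constrained parameter transforms, and likelihoods.

This module houses the probabilistic readout machinery of the uncertainty
models: finite von Mises mixtures over (azimuth, elevation) for sound
localization, finite Gaussian mixtures over s = log f0 for pitch, the
constraint transforms that map unconstrained network activations onto valid
parameters, and the maximum-likelihood objectives. All density code is
written against :mod:`percept._autodiff`, so the same functions evaluate
plain NumPy arrays (analysis) and autodiff tensors (training).

Angles are radians in (−π, π]; pitch lives on the natural-log frequency
axis (e³ ≈ 20 Hz to e¹⁰ ≈ 22 kHz, the approximate range of human hearing).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad

LOG_2PI = float(np.log(2.0 * np.pi))

# Abramowitz & Stegun 9.8.1 / 9.8.2: polynomial approximations of I0.
# Small-argument branch is a polynomial in (kappa/3.75)^2; large-argument
# branch multiplies exp(kappa)/sqrt(kappa) by a polynomial in 3.75/kappa.
_I0_SMALL = (1.0, 3.5156229, 3.0899424, 1.2067492,
             0.2659732, 0.0360768, 0.0045813)
_I0_LARGE = (0.39894228, 0.01328592, 0.00225319, -0.00157565,
             0.00916281, -0.02057706, 0.02635537, -0.01647633,
             0.00392377)
_I0_SWITCH = 3.75


@dataclass(frozen=True)
class ReadoutBounds:
    """Constraint constants for the readout heads."""

    conc_lb: float = 1.0
    conc_ub: float = 512.0
    mean_lb_logf0: float = 3.0
    mean_ub_logf0: float = 10.0
    var_epsilon: float = 1e-9

    def __post_init__(self):
        if not self.conc_lb < self.conc_ub:
            raise ValueError("concentration lower bound must be < upper bound")
        if not self.mean_lb_logf0 < self.mean_ub_logf0:
            raise ValueError("log-f0 mean lower bound must be < upper bound")
        if self.var_epsilon <= 0:
            raise ValueError("variance epsilon must be positive")


DEFAULT_BOUNDS = ReadoutBounds()


def wrap_angle(theta):
    """Wrap angles (radians) into (−π, π]."""
    theta = np.asarray(theta, dtype=np.float64)
    out = np.remainder(-theta + np.pi, 2.0 * np.pi)
    return np.pi - out


@dataclass(frozen=True)
class SphericalLocation:
    """A direction on the sphere: azimuth and elevation, radians in (−π, π]."""

    azimuth: float
    elevation: float

    def __post_init__(self):
        object.__setattr__(self, "azimuth", float(wrap_angle(self.azimuth)))
        object.__setattr__(self, "elevation", float(wrap_angle(self.elevation)))

    @classmethod
    def from_degrees(cls, azimuth_deg: float, elevation_deg: float):
        return cls(np.deg2rad(azimuth_deg), np.deg2rad(elevation_deg))

    @property
    def azimuth_deg(self) -> float:
        return float(np.rad2deg(self.azimuth))

    @property
    def elevation_deg(self) -> float:
        return float(np.rad2deg(self.elevation))


def _check_simplex(weights: np.ndarray, tol: float = 1e-9):
    if np.any(weights < 0):
        raise ValueError("mixture weights must be nonnegative")
    if abs(weights.sum() - 1.0) > tol:
        raise ValueError(f"mixture weights must sum to 1 (got {weights.sum()!r})")


@dataclass
class VonMisesMixture:
    """Mixture of K factorized bivariate von Mises components.

    ``weights``: (K,) simplex; ``means``: (K, 2) radians (azimuth, elevation);
    ``concentrations``: (K, 2) in [bounds.conc_lb, bounds.conc_ub].
    """

    weights: np.ndarray
    means: np.ndarray
    concentrations: np.ndarray
    bounds: ReadoutBounds = field(default_factory=ReadoutBounds)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        k = self.weights.shape[0]
        self.means = wrap_angle(np.asarray(self.means, dtype=np.float64)).reshape(k, 2)
        self.concentrations = np.asarray(
            self.concentrations, dtype=np.float64).reshape(k, 2)
        _check_simplex(self.weights)
        lb, ub = self.bounds.conc_lb, self.bounds.conc_ub
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any((self.concentrations > ub)):
            raise ValueError(f"concentrations exceed upper bound {ub}")

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    def to_json(self) -> str:
        return json.dumps({
            "family": "von_mises_mixture",
            "K": self.n_components,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "concentrations": self.concentrations.tolist(),
            "bounds": {"conc_lb": self.bounds.conc_lb,
                       "conc_ub": self.bounds.conc_ub},
        })

    @classmethod
    def from_json(cls, s: str) -> "VonMisesMixture":
        d = json.loads(s)
        b = d.get("bounds", {})
        bounds = ReadoutBounds(conc_lb=b.get("conc_lb", 1.0),
                               conc_ub=b.get("conc_ub", 512.0))
        return cls(weights=np.array(d["weights"]), means=np.array(d["means"]),
                   concentrations=np.array(d["concentrations"]), bounds=bounds)


@dataclass
class GaussianMixture1D:
    """Mixture of K univariate Gaussians over s = log f0 (natural log Hz)."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    bounds: ReadoutBounds = field(default_factory=ReadoutBounds)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        self.means = np.asarray(self.means, dtype=np.float64).reshape(-1)
        self.variances = np.asarray(self.variances, dtype=np.float64).reshape(-1)
        _check_simplex(self.weights)
        if np.any(self.variances < self.bounds.var_epsilon):
            raise ValueError("variances must be >= epsilon")
        lb, ub = self.bounds.mean_lb_logf0, self.bounds.mean_ub_logf0
        if np.any(self.means < lb) or np.any(self.means > ub):
            raise ValueError(f"means must lie within [{lb}, {ub}]")

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    def to_json(self) -> str:
        return json.dumps({
            "family": "gaussian_mixture_1d",
            "K": self.n_components,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "bounds": {"mean_lb_logf0": self.bounds.mean_lb_logf0,
                       "mean_ub_logf0": self.bounds.mean_ub_logf0,
                       "var_epsilon": self.bounds.var_epsilon},
        })

    @classmethod
    def from_json(cls, s: str) -> "GaussianMixture1D":
        d = json.loads(s)
        b = d.get("bounds", {})
        bounds = ReadoutBounds(
            mean_lb_logf0=b.get("mean_lb_logf0", 3.0),
            mean_ub_logf0=b.get("mean_ub_logf0", 10.0),
            var_epsilon=b.get("var_epsilon", 1e-9))
        return cls(weights=np.array(d["weights"]), means=np.array(d["means"]),
                   variances=np.array(d["variances"]), bounds=bounds)


# ---------------------------------------------------------------------------
# Scalar densities and objectives
# ---------------------------------------------------------------------------

def univariate_gaussian_nll(y, mu, sigma2):
    """Negative log-likelihood of y under N(mu, sigma2).

    With a constant sigma2 this is an affine function of the squared error,
    which is why maximum likelihood with input-dependent variance strictly
    generalizes least-squares regression.
    """
    if np.any(ad.value(sigma2) <= 0):
        raise ValueError("sigma2 must be strictly positive")
    return 0.5 * LOG_2PI + 0.5 * ad.log(sigma2) + (y - mu) ** 2 / (2.0 * sigma2)


def _polyval(coeffs, x):
    """Horner evaluation of sum_i coeffs[i] * x**i (autodiff-safe)."""
    out = coeffs[-1]
    for c in reversed(coeffs[:-1]):
        out = out * x + c
    return out


def log_i0(kappa):
    """log of the modified Bessel function I0, piecewise-polynomial.

    Small arguments (kappa < 3.75) use the series polynomial in
    (kappa/3.75)^2; large arguments use the asymptotic form
    kappa − ½·log(2π·kappa) + log P(3.75/kappa). Both branches are smooth
    and the switch at 3.75 is continuous to ~1e−7, so the function is
    usable inside a differentiable loss over the full concentration range.
    """
    kv = ad.value(kappa)
    if np.any(kv < 0):
        raise ValueError("kappa must be nonnegative")
    small = kv < _I0_SWITCH
    t2 = (kappa / _I0_SWITCH) ** 2
    small_val = ad.log(_polyval(_I0_SMALL, t2))
    # clamp the argument fed to the large branch so masked-out lanes stay finite
    kappa_safe = ad.where(small, np.maximum(kv, _I0_SWITCH), kappa)
    inv = _I0_SWITCH / kappa_safe
    large_val = kappa_safe - 0.5 * ad.log(kappa_safe) + ad.log(_polyval(_I0_LARGE, inv))
    out = ad.where(small, small_val, large_val)
    if np.ndim(ad.value(out)) == 0 and not ad.is_tensor(out):
        return float(out)
    return out


def von_mises_logpdf(theta, mu, kappa):
    """log density of the von Mises distribution on the circle."""
    return kappa * ad.cos(theta - mu) - LOG_2PI - log_i0(kappa)


def vm_mixture_logpdf(y: SphericalLocation, m: VonMisesMixture) -> float:
    """Log density of a location under a factorized von Mises mixture.

    Uses log-sum-exp over components; stable up to the concentration
    upper bound (512 contributes ~exp(512) only through shifted exponents).
    """
    if hasattr(y, "azimuth"):
        theta = np.array([y.azimuth, y.elevation])
    else:
        theta = np.asarray(y, dtype=float)        # (azimuth, elevation) radians
    comp = (np.log(np.maximum(m.weights, 1e-300))
            + np.sum(m.concentrations * np.cos(theta[None, :] - m.means)
                     - LOG_2PI - log_i0(m.concentrations), axis=1))
    return float(ad.logsumexp(comp, axis=0))


def gm_mixture_logpdf(s: float, m: GaussianMixture1D) -> float:
    """Log density of s = log f0 under a univariate Gaussian mixture."""
    comp = (np.log(np.maximum(m.weights, 1e-300))
            - 0.5 * LOG_2PI - 0.5 * np.log(m.variances)
            - (s - m.means) ** 2 / (2.0 * m.variances))
    return float(ad.logsumexp(comp, axis=0))


# ---------------------------------------------------------------------------
# Constraint transforms (network activations -> valid parameters)
# ---------------------------------------------------------------------------

def constrain_weights(logits):
    """Softmax map onto the probability simplex (shift-invariant)."""
    shifted = logits - ad.value(logits).max(axis=-1, keepdims=True)
    e = ad.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def constrain_circular_mean(u, v):
    """Map an unconstrained (u, v) pair to an angle in (−π, π].

    tanh squashes the raw activations into legitimate sine/cosine
    components before atan2. The degenerate input (0, 0) maps to 0 by
    convention (with a warning): the direction is undefined there.
    """
    tu, tv = ad.tanh(u), ad.tanh(v)
    if np.any((ad.value(tu) == 0) & (ad.value(tv) == 0)):
        warnings.warn("constrain_circular_mean received (0, 0); returning 0 "
                      "by convention", RuntimeWarning, stacklevel=2)
    return ad.atan2(tu, tv)


def relux(x, lb: float, ub: float):
    """Rectifier bounded below and above: min(max(x, lb), ub)."""
    if lb >= ub:
        raise ValueError("relux requires lb < ub")
    return ad.clip(x, lb, ub)


def constrain_variance(v, epsilon: float = 1e-9):
    """softplus(v) + epsilon: smooth, strictly positive variance."""
    return ad.softplus(v) + epsilon


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _choose_components(weights: np.ndarray, n: int, rng: np.random.Generator):
    return rng.choice(weights.shape[0], size=n, p=weights)


def sample_von_mises_mixture(m: VonMisesMixture, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. (azimuth, elevation) samples; returns an (n, 2) array.

    Components are chosen by the mixture weights; each coordinate is drawn
    from its von Mises marginal (Best–Fisher rejection sampling, as
    provided by NumPy's generator). Reproducible per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ks = _choose_components(m.weights, n, rng)
    out = np.empty((n, 2))
    for dim in range(2):
        mu = m.means[ks, dim]
        kappa = m.concentrations[ks, dim]
        out[:, dim] = rng.vonmises(mu, kappa)
    return wrap_angle(out)


def sample_gaussian_mixture(m: GaussianMixture1D, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. samples of s = log f0; returns an (n,) array."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ks = _choose_components(m.weights, n, rng)
    return rng.normal(m.means[ks], np.sqrt(m.variances[ks]))
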