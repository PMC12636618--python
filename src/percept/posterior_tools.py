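"""Decision and uncertainty extraction from predicted posteriors.

MAP location estimates are obtained the way a sampling-based observer
would: draw Monte Carlo samples from the mixture, histogram them at 1°
resolution, and take the modal bin. Uncertainty summaries: 50% highest-
posterior-density (HPD) interval width over azimuth (absolute localization
confidence), binary front/back entropy (front–back judgments), and the
posterior variance within a one-octave window around the mode (pitch
discrimination confidence).

Azimuth convention here: degrees in [−180°, 180°), 0° straight ahead,
positive to the listener's right; the front hemifield is |az| <= 90°
(the boundary itself counted as front — the experimental designs omit it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import (
    GaussianMixture1D, SphericalLocation, VonMisesMixture,
    gm_mixture_logpdf, sample_gaussian_mixture, sample_von_mises_mixture,
)

__all__ = [
    "EmpiricalPosterior", "log_f0_bin_edges", "circular_histogram",
    "histogram_mode",
    "map_estimate", "hpd_width", "hpd_interval_from_samples",
    "front_back_entropy", "fold_to_frontal", "constrained_map_f0",
    "mode_local_variance",
]

SEMITONE = np.log(2.0) / 12.0


def log_f0_bin_edges(fmin: float = 80.0, fmax: float = 1000.0,
                     bins_per_semitone: int = 16) -> np.ndarray:
    """Edges of log-spaced f0 bins of width 1/``bins_per_semitone`` semitone.

    The default 80–1000 Hz range at 1/16-semitone width (≈0.36% per bin)
    yields 700 bins — the f0 discretization used to balance pitch
    training data. Returns n_bins + 1 edges in Hz.
    """
    step = SEMITONE / bins_per_semitone
    n = int(round(np.log(fmax / fmin) / step))
    return fmin * np.exp(step * np.arange(n + 1))


@dataclass
class EmpiricalPosterior:
    """Monte Carlo posterior: raw samples plus a normalized 1°-bin histogram."""

    samples: np.ndarray          # (n,) or (n, dims)
    histogram: np.ndarray        # normalized mass per bin
    bin_centers: np.ndarray
    n: int
    seed: int | None = None

    def save_h5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=self.samples)
            f.create_dataset("histogram", data=self.histogram)
            f.create_dataset("bin_centers", data=self.bin_centers)
            f["samples"].attrs["n"] = self.n
            if self.seed is not None:
                f["samples"].attrs["seed"] = self.seed


def circular_histogram(angles_deg: np.ndarray, bin_deg: float = 1.0):
    """Normalized histogram of angles over [−180°, 180°), returns
    (mass, bin_centers)."""
    angles = np.mod(np.asarray(angles_deg, dtype=float) + 180.0, 360.0) - 180.0
    n_bins = int(round(360.0 / bin_deg))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts / counts.sum(), centers


def histogram_mode(mass: np.ndarray, centers: np.ndarray) -> float:
    """Modal bin center; ties broken toward the midline (smallest
    |center|), then by lowest index."""
    m = mass.max()
    tied = np.flatnonzero(mass == m)
    best = tied[np.lexsort((tied, np.abs(centers[tied])))[0]]
    return float(centers[best])


def map_estimate(m: VonMisesMixture, n: int = 5000, bin_deg: float = 1.0,
                 seed: int = 0) -> SphericalLocation:
    """Monte Carlo MAP: 1°-bin marginal histogram modes per dimension.

    Marginal (per-dimension) histograms are used rather than a joint 2-D
    histogram: 5000 samples cannot populate a 360×360 grid, and the
    experimental decisions are azimuthal or hemifield-based.
    """
    samples = sample_von_mises_mixture(m, n, seed)          # (n, 2) radians
    deg = np.rad2deg(samples)
    az_mass, az_centers = circular_histogram(deg[:, 0], bin_deg)
    el_mass, el_centers = circular_histogram(deg[:, 1], bin_deg)
    return SphericalLocation.from_degrees(histogram_mode(az_mass, az_centers),
                                          histogram_mode(el_mass, el_centers))


def hpd_width(mass: np.ndarray, target_mass: float = 0.5,
              bin_deg: float = 1.0) -> float:
    """Width (degrees) of the narrowest contiguous circular arc holding
    at least ``target_mass`` of the histogram.

    Scans all window sizes on the circular (wrapped) histogram; returns
    the smallest window length whose best placement reaches the target.
    """
    mass = np.asarray(mass, dtype=float)
    mass = mass / mass.sum()
    n = mass.size
    doubled = np.concatenate([mass, mass])
    prefix = np.concatenate([[0.0], np.cumsum(doubled)])
    for w in range(1, n + 1):
        window_sums = prefix[w:w + n] - prefix[:n]
        if window_sums.max() >= target_mass - 1e-12:
            return w * bin_deg
    return n * bin_deg


def hpd_interval_from_samples(samples: np.ndarray, target_mass: float = 0.5):
    """Shortest interval containing ``target_mass`` of 1-D samples
    (linear topology); returns (low, high)."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    m = max(1, int(np.ceil(target_mass * n)))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1:] - s[:n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def front_back_entropy(azimuth_deg_samples: np.ndarray):
    """Binary front/back uncertainty of an azimuthal posterior.

    Integrates the posterior over the front (|az| <= 90°) and back
    hemifields; returns (entropy_bits, p_front). The entropy of the
    resulting binomial distribution is the model's (inverse) confidence
    for front–back judgments. 0·log 0 := 0.
    """
    az = np.mod(np.asarray(azimuth_deg_samples, dtype=float) + 180.0, 360.0) - 180.0
    p_front = float(np.mean(np.abs(az) <= 90.0))
    return binary_entropy_bits(p_front), p_front


def fold_to_frontal(azimuth_deg: np.ndarray) -> np.ndarray:
    """Map each azimuth to its frontal cone-of-confusion partner.

    Rear-hemifield angles (|az| > 90°) are reflected across the interaural
    axis (az → sign(az)·(180° − |az|)); frontal angles are unchanged. Used
    when the response protocol restricts answers to the frontal arc, so
    that front/back posterior bimodality does not enter the azimuthal
    uncertainty summary.
    """
    az = np.mod(np.asarray(azimuth_deg, dtype=float) + 180.0, 360.0) - 180.0
    rear = np.abs(az) > 90.0
    return np.where(rear, np.sign(az) * (180.0 - np.abs(az)), az)


def binary_entropy_bits(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def constrained_map_f0(m: GaussianMixture1D, nominal_f0: float,
                       n: int = 5000, seed: int = 0,
                       bin_semitones: float = 1.0 / 16.0) -> float:
    """MAP f0 (Hz) restricted to ±1 octave around the nominal f0.

    Posterior samples of s = log f0 falling within
    [log(nominal/2), log(2·nominal)) — upper edge excluded — are
    histogrammed at ``bin_semitones`` resolution; returns exp of the modal
    bin center. If no sample lands in the window, falls back to a dense
    density-grid argmax over the window.
    """
    if nominal_f0 <= 0:
        raise ValueError("nominal_f0 must be positive")
    lo, hi = np.log(nominal_f0 / 2.0), np.log(2.0 * nominal_f0)
    samples = sample_gaussian_mixture(m, n, seed)
    inside = samples[(samples >= lo) & (samples < hi)]
    if inside.size == 0:
        grid = np.linspace(lo, hi, 4097, endpoint=False)
        dens = np.array([gm_mixture_logpdf(s, m) for s in grid])
        return float(np.exp(grid[np.argmax(dens)]))
    bw = bin_semitones * SEMITONE
    n_bins = int(np.ceil((hi - lo) / bw))
    edges = lo + bw * np.arange(n_bins + 1)
    counts, _ = np.histogram(inside, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = histogram_mode(counts / counts.sum(), centers - np.log(nominal_f0))
    return float(np.exp(mode + np.log(nominal_f0)))


def _density_grid(m: GaussianMixture1D, lo: float, hi: float, n: int):
    grid = np.linspace(lo, hi, n)
    var = m.variances[None, :]
    logcomp = (np.log(np.maximum(m.weights, 1e-300))[None, :]
               - 0.5 * np.log(2 * np.pi * var)
               - (grid[:, None] - m.means[None, :]) ** 2 / (2 * var))
    mx = logcomp.max(axis=1, keepdims=True)
    dens = np.exp(mx[:, 0] + np.log(np.exp(logcomp - mx).sum(axis=1)))
    return grid, dens


def mode_local_variance(m: GaussianMixture1D, window: float = np.log(2.0),
                        grid_points: int = 4001) -> float:
    """Posterior variance within a one-octave window centered on the mode.

    The mode is located on a dense global grid; the density restricted to
    [mode − window/2, mode + window/2] is renormalized and its variance
    computed by trapezoidal quadrature, in (log f0)² units. This is the
    "width of the dominant mode" confidence summary for pitch: faraway
    mixture components (e.g. octave errors) do not inflate it.
    """
    span = 3.0 * float(np.sqrt(m.variances.max()))
    glo = float(m.means.min()) - span
    ghi = float(m.means.max()) + span
    grid, dens = _density_grid(m, glo, ghi, 8192)
    mode = grid[np.argmax(dens)]
    g, d = _density_grid(m, mode - window / 2.0, mode + window / 2.0,
                         grid_points)
    z = np.trapezoid(d, g)
    mean = np.trapezoid(g * d, g) / z
    return float(np.trapezoid((g - mean) ** 2 * d, g) / z)
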