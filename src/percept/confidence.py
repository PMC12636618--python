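"""Mapping per-trial uncertainty onto discrete 1–5 confidence bets.

Human observers in post-decision wagering place integer bets (1–5).
Model uncertainty values (HPD widths, entropies, mode-local variances)
are converted to bets by an inverse-CDF transform: the uncertainties of
an experiment are pooled and sorted in descending order, each trial's
rank quantile is pushed through the CDF of a discrete Gaussian prior over
the betting scale (centered at 3, unit variance), and the resulting bet
is the smallest level whose cumulative prior mass covers the quantile.
Most-uncertain trials therefore receive the lowest bets, and the bet
proportions converge to the prior probabilities as the pool grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BetPrior", "discrete_gaussian_bet_prior", "assign_bets"]


@dataclass(frozen=True)
class BetPrior:
    support: tuple
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("prior must be a probability vector")
        object.__setattr__(self, "probabilities", p)

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.probabilities)

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))


def discrete_gaussian_bet_prior() -> BetPrior:
    """Discrete normal over the integers 1–5, centered at 3, unit variance,
    normalized to sum to one: p(k) ∝ exp(−(k−3)²/2)."""
    k = np.arange(1, 6)
    p = np.exp(-((k - 3.0) ** 2) / 2.0)
    return BetPrior(support=tuple(k.tolist()), probabilities=p / p.sum())


def assign_bets(uncertainties, prior: BetPrior | None = None) -> np.ndarray:
    """Map pooled uncertainty values to integer bets via the prior's CDF.

    Trials are ranked by uncertainty, descending (ties broken by original
    index — a stable sort); trial at descending rank i (of N) has quantile
    i/(N−1), and receives the smallest bet level whose cumulative prior
    probability reaches that quantile. Monotone: higher uncertainty never
    yields a higher bet. A single trial (N=1) gets the central bet.
    """
    u = np.asarray(uncertainties, dtype=float)
    if u.ndim != 1 or u.size < 1:
        raise ValueError("uncertainties must be a nonempty 1-D array")
    if prior is None:
        prior = discrete_gaussian_bet_prior()
    n = u.size
    order = np.argsort(-u, kind="stable")
    bets = np.empty(n, dtype=int)
    if n == 1:
        bets[0] = prior.support[len(prior.support) // 2]
        return bets
    quantiles = np.arange(n) / (n - 1)
    cdf = prior.cdf
    levels = np.searchsorted(cdf, quantiles, side="left")
    levels = np.minimum(levels, len(prior.support) - 1)
    bets[order] = np.asarray(prior.support)[levels]
    return bets
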