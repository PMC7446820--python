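"""Closed-form neutral-theory baselines.

Under neutral drift a high-diversity community's species abundance
distribution converges to Fisher's log-series,
``P_k = alpha p^k / k`` with ``alpha = -1/log(1 - p)``, whose single
parameter ``p`` is fixed by the mean abundance through
``alpha p / (1 - p) = n``.

Dynamical baselines come from the matched subcritical linear birth-death
process: per-capita death rate 1 (time measured in generations), per-capita
birth rate ``p``, absorbing at zero.  This yields the expected extinction
time ``T_k`` of a species of abundance ``k``,

.. math::

    T_k = \\frac{1}{1-p}\\Big(p^{-k} B(p; 1+k, 0) + H_k + \\log(1-p)\\Big),

(with ``H_k`` the harmonic number and ``B(z; a, 0)`` the incomplete beta
function with vanishing second argument), and the across-history variance of
the relative abundance change ``D(t) = (n(t) - n0)/n0``, used as the
short-timescale neutrality diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "LogSeriesModel",
    "logseries_pmf",
    "fit_logseries_p",
    "neutral_extinction_time",
    "extinction_curve",
    "bd_extinction_prob",
    "bd_transition_pmf",
    "bd_moments",
    "predicted_var_D",
]


@dataclass(frozen=True)
class LogSeriesModel:
    """Fisher log-series with parameter ``p`` in (0, 1)."""

    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError("log-series parameter p must lie in (0, 1)")

    @property
    def alpha(self) -> float:
        return -1.0 / np.log1p(-self.p)

    @property
    def mean_abundance(self) -> float:
        return self.alpha * self.p / (1.0 - self.p)

    def pmf(self, k) -> np.ndarray:
        return logseries_pmf(k, self.p)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Sample abundances; scipy's logser sampler under our rng."""
        return stats.logser.rvs(self.p, size=size, random_state=rng)

    @classmethod
    def from_mean(cls, mean_abundance: float) -> "LogSeriesModel":
        return cls(fit_logseries_p(mean_abundance))


def logseries_pmf(k, p: float):
    """Log-series probability ``alpha p^k / k`` for integer abundance k >= 1."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    k_arr = np.asarray(k)
    if np.any(k_arr < 1):
        raise ValueError("log-series support is k >= 1")
    alpha = -1.0 / np.log1p(-p)
    out = alpha * np.power(p, k_arr) / k_arr
    return out if out.shape else float(out)


def fit_logseries_p(mean_abundance: float) -> float:
    """Solve ``alpha p / (1 - p) = mean`` for ``p`` in (0, 1).

    The mean is strictly increasing in ``p`` with infimum 1 as ``p -> 0``, so a
    unique root exists for any mean > 1.
    """
    m = float(mean_abundance)
    if not np.isfinite(m) or m <= 1.0:
        raise ValueError(f"log-series mean abundance must exceed 1, got {m}")

    def f(p: float) -> float:
        return -p / (np.log1p(-p) * (1.0 - p)) - m

    lo, hi = 1e-12, 1.0 - 1e-15
    # f(lo) < 0 always; expand precision near 1 is handled by brentq
    p = optimize.brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    return float(p)


def _incbeta_tail_over_pk(k: np.ndarray, p: float) -> np.ndarray:
    """Compute ``p^{-k} B(p; 1+k, 0)`` stably as ``sum_{j>=1} p^j / (k + j)``.

    Expanding ``1/(1-t)`` inside ``B(p;1+k,0) = int_0^p t^k/(1-t) dt`` gives
    ``sum_{m>k} p^m/m``; multiplying by ``p^{-k}`` leaves a geometrically
    convergent series free of overflow for any ``k``.
    """
    # number of terms so the geometric tail bound p^J/(1-p) is negligible
    J = int(np.ceil(np.log(1e-17 * (1.0 - p)) / np.log(p))) + 1 if p > 1e-8 else 60
    J = max(J, 10)
    j = np.arange(1, J + 1, dtype=float)
    pj = np.power(p, j)
    return (pj[None, :] / (np.asarray(k, float)[:, None] + j[None, :])).sum(axis=1)


def neutral_extinction_time(k, p: float):
    """Expected time to extinction ``T_k`` (generations) under neutral drift.

    Evaluates the closed form for the matched subcritical birth-death process
    (per-capita death 1, birth ``p``) started from abundance ``k``.  The
    ``p^{-k} B(p; 1+k, 0)`` product is computed in combined series form, so the
    result is stable for ``k`` well beyond 1e4.  At ``k = 1`` the expression
    reduces to ``-log(1-p)/p``.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    k_arr = np.atleast_1d(np.asarray(k))
    if np.any(k_arr < 1) or np.any(k_arr != np.floor(k_arr)):
        raise ValueError("abundance k must be a positive integer")
    kf = k_arr.astype(float)
    tail = _incbeta_tail_over_pk(kf, p)
    harmonic = special.digamma(kf + 1.0) + np.euler_gamma
    T = (tail + harmonic + np.log1p(-p)) / (1.0 - p)
    if np.any(~np.isfinite(T)):
        raise FloatingPointError("extinction-time evaluation lost precision")
    return T if np.asarray(k).shape else float(T[0])


def extinction_curve(k_max: int, p: float) -> np.ndarray:
    """``T_k`` for k = 1..k_max as an array (generations)."""
    return np.asarray(neutral_extinction_time(np.arange(1, k_max + 1), p))


# --- matched subcritical linear birth-death process (death 1, birth p) ------


def _bd_alpha_beta(t: float, p: float) -> tuple[float, float]:
    """Kendall's auxiliary quantities for the linear birth-death transition law.

    For birth rate ``p`` and death rate 1 per capita (``p < 1`` subcritical),
    ``alpha(t)`` is the single-ancestor extinction probability and ``beta(t)``
    the geometric decay of the surviving lineage's offspring number.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if t == 0.0:
        return 0.0, 0.0
    w = np.exp(-(1.0 - p) * t)  # e^{(lambda - mu) t}, in (0, 1)
    alpha = (1.0 - w) / (1.0 - p * w)
    beta = p * alpha
    return float(alpha), float(beta)


def bd_extinction_prob(n0: int, t, p: float):
    """Probability the process is absorbed at 0 by time t, starting from n0."""
    t_arr = np.atleast_1d(np.asarray(t, float))
    out = np.array([_bd_alpha_beta(ti, p)[0] ** n0 for ti in t_arr])
    return out if np.asarray(t).shape else float(out[0])


def bd_transition_pmf(n0: int, t: float, p: float, n_max: int) -> np.ndarray:
    """Transition probabilities ``P(n(t) = n | n0)`` for n = 0..n_max.

    Kendall's closed form: each of the ``n0`` initial individuals leaves, by
    time ``t``, zero descendants with probability ``alpha`` or a geometric
    number (success ``1 - beta``) given survival; ``n(t)`` is their sum::

        P(0) = alpha^n0
        P(n) = sum_j C(n0, j) C(n-1, j-1) alpha^(n0-j)
               ((1-alpha)(1-beta))^j beta^(n-j),   n >= 1

    computed in log space for stability at large ``n0``.
    """
    if n0 < 1:
        raise ValueError("n0 must be a positive integer")
    alpha, beta = _bd_alpha_beta(t, p)
    if t == 0.0:
        out = np.zeros(n_max + 1)
        if n0 <= n_max:
            out[n0] = 1.0
        return out
    out = np.zeros(n_max + 1)
    out[0] = alpha**n0
    log_a = np.log(alpha) if alpha > 0 else -np.inf
    log_b = np.log(beta) if beta > 0 else -np.inf
    log_c = np.log1p(-alpha) + np.log1p(-beta)
    for nn in range(1, n_max + 1):
        j = np.arange(1, min(n0, nn) + 1)
        terms = (
            special.gammaln(n0 + 1)
            - special.gammaln(j + 1)
            - special.gammaln(n0 - j + 1)
            + special.gammaln(nn)
            - special.gammaln(nn - j + 1)
            - special.gammaln(j)
            + (n0 - j) * log_a
            + (nn - j) * log_b
            + j * log_c
        )
        out[nn] = np.exp(terms).sum()
    return out


def bd_moments(n0: int, t, p: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of n(t) given n0 (absorbing state included).

    Standard linear birth-death moments with ``c = lambda - mu = -(1-p)``:
    ``E = n0 e^{ct}`` and ``Var = n0 (1+p)/(1-p) e^{ct} (1 - e^{ct})``.
    """
    t_arr = np.asarray(t, float)
    w = np.exp(-(1.0 - p) * t_arr)
    mean = n0 * w
    var = n0 * (1.0 + p) / (1.0 - p) * w * (1.0 - w)
    return mean, var


def predicted_var_D(n0: int, t_grid, p: float):
    """Across-history variance of ``D(t) = (n(t) - n0)/n0`` under neutral drift.

    Uses the exact first two moments of the matched subcritical birth-death
    process (extinct histories contribute ``n(t) = 0``):
    ``var D = Var[n(t)] / n0^2``.  Zero at t = 0 by construction.
    """
    if n0 < 1:
        raise ValueError("n0 must be a positive integer")
    _, var = bd_moments(n0, t_grid, p)
    out = var / float(n0) ** 2
    return out if np.asarray(t_grid).shape else float(out)
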