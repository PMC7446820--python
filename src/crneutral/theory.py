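"""Mean-field dynamics, Jacobian spectra and the niche/neutral thresholds.

The mean-field counterpart of the stochastic consumer-resource process is

.. math::

    \\dot R_k = \\rho_k - R_k \\sum_j C_{kj} N_j, \\qquad
    \\dot N_i = \\epsilon N_i \\sum_j C_{ji} R_j - \\eta_i N_i.

Near the calibrated fixed point the Jacobian eigenvalues split into a fast
*resource bulk* (K large-magnitude eigenvalues) and a slow *consumer bulk*
(S small-magnitude eigenvalues).  The most negative real part in the consumer
bulk, ``lambda_+``, sets the fastest deterministic stabilisation timescale of
consumers; comparing ``1/|lambda_+|`` against the neutral drift-to-extinction
timescale ``T_n / eta_bar`` predicts whether demographic drift or niche
stabilisation dominates, and yields threshold scalings (up to a multiplicative
constant) for the generalist coefficient of variation and the specialist
``Cd/Co`` ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .community import CommunityParams, ConsumptionMatrix
from .neutral import neutral_extinction_time

__all__ = [
    "SpectrumResult",
    "ThresholdPrediction",
    "ode_rhs",
    "equilibrium_residual",
    "jacobian_at",
    "spectrum_split",
    "gamma_coefficient",
    "predict_generalist_threshold",
    "predict_thresholds",
    "predict_specialist_threshold",
    "drift_timescale",
]


def _entries(C: ConsumptionMatrix | np.ndarray) -> np.ndarray:
    return C.entries if isinstance(C, ConsumptionMatrix) else np.asarray(C, float)


def ode_rhs(
    R: np.ndarray, N: np.ndarray, params: CommunityParams, C: ConsumptionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side of the mean-field equations at state ``(R, N)``."""
    entries = _entries(C)
    R = np.asarray(R, float)
    N = np.asarray(N, float)
    if R.shape != (params.K,) or N.shape != (params.S,):
        raise ValueError("state dimensions do not match (K, S)")
    dR = params.rho - R * (entries @ N)
    dN = params.eps * N * (entries.T @ R) - params.eta * N
    return dR, dN


def equilibrium_residual(
    params: CommunityParams,
    C: ConsumptionMatrix,
    R_star: np.ndarray,
    N_star: np.ndarray,
) -> float:
    """Max-norm of the mean-field right-hand side at a candidate equilibrium."""
    dR, dN = ode_rhs(R_star, N_star, params, C)
    return float(max(np.max(np.abs(dR)), np.max(np.abs(dN))))


def jacobian_at(
    params: CommunityParams,
    C: ConsumptionMatrix,
    R_star: np.ndarray | None = None,
    N_star: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic ``(K+S) x (K+S)`` Jacobian of the mean-field system.

    Ordering is resources first, consumers second.  Blocks::

        dRdot/dR = diag(-sum_j C_kj N_j)      dRdot/dN = -R_k C_kj
        dNdot/dR = eps N_i C_ji (transposed)  dNdot/dN = diag(eps (C^T R)_i - eta_i)

    At the calibrated uniform fixed point the consumer-consumer block vanishes.
    Defaults to the calibrated fixed point ``(r*1, n*1)`` when no state is given.
    """
    entries = _entries(C)
    K, S = entries.shape
    if R_star is None:
        R_star = np.full(K, params.r)
    if N_star is None:
        N_star = np.full(S, params.n)
    R_star = np.asarray(R_star, float)
    N_star = np.asarray(N_star, float)
    J = np.zeros((K + S, K + S))
    J[:K, :K] = np.diag(-(entries @ N_star))
    J[:K, K:] = -R_star[:, None] * entries
    J[K:, :K] = params.eps * N_star[:, None] * entries.T
    J[K:, K:] = np.diag(params.eps * (entries.T @ R_star) - params.eta)
    return J


@dataclass(frozen=True)
class ThresholdPrediction:
    """Analytic niche/neutral threshold scalings for one parameter set.

    Both thresholds are defined up to a multiplicative constant; the package
    reports scalings and fits the constant empirically when comparing against
    simulation ensembles.
    """

    gamma: float
    cv_threshold: float
    cd_co_threshold: float
    drift_timescale: float  # T_n / eta_bar, model time units


def predict_thresholds(
    S: int, n: float, r: float, eps: float, eta_bar: float, p: float
) -> ThresholdPrediction:
    """Bundle both threshold scalings with the drift timescale."""
    return ThresholdPrediction(
        gamma=gamma_coefficient(n, r, eps),
        cv_threshold=predict_generalist_threshold(S, n, r, eps),
        cd_co_threshold=predict_specialist_threshold(S, n, r, eps),
        drift_timescale=drift_timescale(n, p, eta_bar),
    )


@dataclass(frozen=True)
class SpectrumResult:
    """Jacobian eigenvalues split into resource and consumer bulks."""

    eigenvalues: np.ndarray
    resource_bulk: np.ndarray  # indices into eigenvalues
    consumer_bulk: np.ndarray
    lambda_plus: float
    stabilization_timescale: float
    separation_ratio: float


def spectrum_split(J: np.ndarray, K: int, S: int, split: str = "gap") -> SpectrumResult:
    """Partition the Jacobian spectrum into resource and consumer bulks.

    The slow *consumer* modes are the drift directions of the consumer
    subsystem; besides the ``K - 1`` pure resource relaxations, two fast
    *global* modes couple total resource and total consumer biomass and
    belong with the fast bulk.  The default ``split="gap"`` therefore places
    the boundary at the largest multiplicative gap in the sorted eigenvalue
    magnitudes among cut positions near ``S`` (cuts ``S-2 .. S`` from the
    slow end), which selects the ``S - 1`` slow modes when the global pair is
    fast.  ``split="count"`` forces the literal count partition (largest
    ``K`` magnitudes = resource bulk).

    ``lambda_+`` is the most negative real part within the consumer bulk and
    ``1/|lambda_+|`` the consumer stabilisation timescale.  A warning (not an
    error) is raised when the bulks are separated by less than a factor of 2,
    so that parameter scans crossing pathological regions stay alive.
    """
    eig = np.linalg.eigvals(np.asarray(J, float))
    if not np.all(np.isfinite(eig)):
        raise ValueError("non-finite eigenvalues")
    if eig.shape != (K + S,):
        raise ValueError("Jacobian size does not match K + S")
    mags = np.abs(eig)
    asc = np.argsort(mags)  # slow -> fast
    if split == "count":
        cut = S
    elif split == "gap":
        candidates = [c for c in (max(S - 2, 1), S - 1, S) if 0 < c < K + S]
        best, best_gap = S, -np.inf
        for c in candidates:
            lo = mags[asc[c - 1]]
            hi = mags[asc[c]]
            gap = np.inf if lo == 0 else hi / lo
            if gap > best_gap:
                best, best_gap = c, gap
        cut = best
    else:
        raise ValueError(f"unknown split {split!r}")
    consumer_bulk = asc[:cut]
    resource_bulk = asc[cut:]
    cons = eig[consumer_bulk]
    lambda_plus = float(np.min(cons.real))
    res_min = float(np.min(np.abs(eig[resource_bulk]))) if resource_bulk.size else np.inf
    con_max = float(np.max(np.abs(cons))) if consumer_bulk.size else 0.0
    separation = res_min / con_max if con_max > 0 else np.inf
    if separation < 2.0:
        warnings.warn(
            f"resource and consumer eigenvalue bulks poorly separated "
            f"(ratio {separation:.3g} < 2); bulk assignment may be unreliable",
            stacklevel=2,
        )
    timescale = np.inf if lambda_plus == 0.0 else 1.0 / abs(lambda_plus)
    return SpectrumResult(
        eigenvalues=eig,
        resource_bulk=resource_bulk,
        consumer_bulk=consumer_bulk,
        lambda_plus=lambda_plus,
        stabilization_timescale=timescale,
        separation_ratio=separation,
    )


def gamma_coefficient(n: float, r: float, eps: float) -> float:
    """Dimensionless drift coefficient ``gamma = (1/n) (1 - eps r / (2 n))``."""
    return (1.0 / n) * (1.0 - eps * r / (2.0 * n))


def predict_generalist_threshold(
    S: int, n: float, r: float, eps: float = 1.0, correction: bool = True
) -> float:
    """Predicted CV threshold for neutral-like behaviour, generalist scenario.

    ``CV_threshold ~ sqrt( S/(4n) * (1 - eps r/(2n)) )``, defined up to a
    multiplicative constant.  With ``correction=False`` the small parenthetical
    term is dropped, leaving the pure power law ``sqrt(S/(4n))`` whose square
    is inversely proportional to the mean consumer abundance ``n``.
    """
    if n <= 0 or r <= 0:
        raise ValueError("abundances must be positive")
    radicand = S / (4.0 * n)
    if correction:
        factor = 1.0 - eps * r / (2.0 * n)
        if factor <= 0:
            raise ValueError(
                f"correction term 1 - eps*r/(2n) = {factor:.4g} <= 0 at "
                f"n={n}, r={r}, eps={eps}: threshold formula not applicable"
            )
        radicand *= factor
    return float(np.sqrt(radicand))


def predict_specialist_threshold(S: int, n: float, r: float, eps: float = 1.0) -> float:
    """Predicted ``Cd/Co`` threshold, specialist scenario.

    ``Cd/Co ~ (1 + gamma (S - 1)) / (1 - gamma)`` with
    ``gamma = (1/n)(1 - eps r/(2n))``: linear in the number of consumers and
    equal to 1 in the neutral limit ``gamma = 0``.  Defined up to a
    multiplicative constant.
    """
    g = gamma_coefficient(n, r, eps)
    if g >= 1.0:
        raise ValueError(f"gamma = {g:.4g} >= 1: specialist threshold diverges")
    return (1.0 + g * (S - 1.0)) / (1.0 - g)


def drift_timescale(n: float, p: float, eta_bar: float) -> float:
    """Drift-to-extinction timescale ``T_n / eta_bar`` in model time units.

    ``T_n`` is the neutral expected extinction time (in generations) of a
    species starting from the mean abundance ``round(n)``; dividing by the
    mean mortality rate converts generations to model time.
    """
    k = max(1, int(round(n)))
    return float(neutral_extinction_time(k, p)) / eta_bar
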