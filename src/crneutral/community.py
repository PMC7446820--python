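"""Consumption matrices, rate calibration, and the non-neutrality index.

A community of ``S`` consumers competing for ``K`` substitutable abiotic
resources is characterised by a non-negative ``K x S`` consumption matrix
``C`` (rows = resources, columns = consumers), per-resource inflow rates
``rho`` and per-capita consumer mortality rates ``eta``.  Two departures
from the neutral limit (all entries of ``C`` equal) are supported:

* **generalist** — i.i.d. random entries with mean ``mu`` and coefficient
  of variation ``cv = sigma/mu``;
* **specialist** — one preferred resource per consumer: diagonal entries
  ``C_d``, off-diagonal ``C_o <= C_d`` (requires ``K == S``).

Given any strictly positive matrix, inflow and mortality vectors can be
chosen so that the uniform state (all resources at ``r``, all consumers at
``n``) is a fixed point of the mean-field dynamics; :func:`calibrate_rates`
returns the unique such rates.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "ConsumptionMatrix",
    "CommunityParams",
    "build_generalist_matrix",
    "build_specialist_matrix",
    "calibrate_rates",
    "calibrate_community",
    "non_neutrality_index",
    "specialist_nni",
    "specialist_ratio_for_nni",
]


@dataclass(frozen=True)
class ConsumptionMatrix:
    """A K x S matrix of per-capita consumption rates with scenario metadata.

    ``entries[k, i]`` is the rate at which one individual of consumer ``i``
    depletes one unit of resource ``k`` (per resource-unit per consumer per
    unit time).
    """

    entries: np.ndarray
    scenario: Literal["generalist", "specialist", "custom"] = "custom"
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2:
            raise ValueError("consumption matrix must be 2-dimensional")
        if np.any(entries < 0):
            raise ValueError("consumption rates must be non-negative")
        object.__setattr__(self, "entries", entries)

    @property
    def K(self) -> int:
        return self.entries.shape[0]

    @property
    def S(self) -> int:
        return self.entries.shape[1]

    def to_text(self, path: str | Path) -> None:
        """Write entries as delimited text plus a JSON metadata sidecar."""
        path = Path(path)
        np.savetxt(path, self.entries, delimiter="\t")
        meta = {"scenario": self.scenario, "params": self.params, "seed": self.seed}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_text(cls, path: str | Path) -> "ConsumptionMatrix":
        path = Path(path)
        entries = np.loadtxt(path, delimiter="\t", ndmin=2)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            entries,
            scenario=meta.get("scenario", "custom"),
            params=meta.get("params", {}),
            seed=meta.get("seed"),
        )


@dataclass(frozen=True)
class CommunityParams:
    """Community-level parameters with rates calibrated to a uniform fixed point.

    ``rho`` (length K, units/time) and ``eta`` (length S, 1/time) are chosen so
    that all resources equilibrate at ``r`` and all consumers at ``n`` under the
    mean-field dynamics.  One generation is the expected individual lifespan
    ``1 / mean(eta)``.
    """

    S: int
    K: int
    eps: float
    n: float
    r: float
    rho: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        eta = np.asarray(self.eta, dtype=float)
        if rho.shape != (self.K,) or eta.shape != (self.S,):
            raise ValueError("rho must have length K and eta length S")
        if np.any(rho <= 0) or np.any(eta <= 0):
            raise ValueError("inflow and mortality rates must be strictly positive")
        if not (0.0 < self.eps <= 1.0):
            raise ValueError("conversion efficiency eps must lie in (0, 1]")
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "eta", eta)

    @property
    def eta_bar(self) -> float:
        """Mean per-capita mortality rate (1/time)."""
        return float(np.mean(self.eta))

    @property
    def generation_time(self) -> float:
        """Expected individual lifespan ``1/eta_bar`` in model time units."""
        return 1.0 / self.eta_bar


def build_generalist_matrix(
    S: int,
    K: int,
    mean: float,
    cv: float,
    seed: int | None = None,
    distribution: Literal["uniform", "normal"] = "uniform",
    rng: np.random.Generator | None = None,
) -> ConsumptionMatrix:
    """Sample a generalist consumption matrix with i.i.d. entries.

    Entries are drawn independently with mean ``mean`` and standard deviation
    ``mean * cv``.  The uniform option uses the symmetric support
    ``[mean - sqrt(3) sigma, mean + sqrt(3) sigma]`` (the unique uniform with
    that mean and variance); ``cv`` must then not exceed ``1/sqrt(3)`` or the
    lower endpoint turns negative.  Normal draws that land below zero are
    resampled; the resample count is recorded in ``params``.
    """
    if mean <= 0:
        raise ValueError("mean consumption rate must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    sigma = mean * cv
    if rng is None:
        rng = np.random.default_rng(seed)
    if distribution == "uniform":
        half = np.sqrt(3.0) * sigma
        if mean - half < 0:
            raise ValueError(
                f"uniform generalist matrix requires cv <= 1/sqrt(3) ~ 0.5774, got {cv}"
            )
        entries = rng.uniform(mean - half, mean + half, size=(K, S))
        resamples = 0
    elif distribution == "normal":
        entries = rng.normal(mean, sigma, size=(K, S))
        resamples = 0
        bad = entries < 0
        while np.any(bad):
            resamples += int(bad.sum())
            entries[bad] = rng.normal(mean, sigma, size=int(bad.sum()))
            bad = entries < 0
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    params = {"mean": mean, "cv": cv, "sigma": sigma, "distribution": distribution}
    if resamples:
        params["negative_resamples"] = resamples
    return ConsumptionMatrix(entries, scenario="generalist", params=params, seed=seed)


def build_specialist_matrix(S: int, Cd: float, Co: float) -> ConsumptionMatrix:
    """Specialist consumption matrix: diagonal ``Cd``, off-diagonal ``Co``.

    Each consumer depletes its own preferred resource at rate ``Cd`` and every
    other resource at ``Co``.  ``Cd >= Co >= 0`` with ``Cd > 0``; ``Cd == Co``
    is the neutral limit, ``Co == 0`` full specialisation (NNI = 1).
    """
    if Cd <= 0:
        raise ValueError("Cd must be positive")
    if Co < 0:
        raise ValueError("Co must be non-negative")
    if Cd < Co:
        raise ValueError("specialist scenario requires Cd >= Co")
    entries = np.full((S, S), float(Co))
    np.fill_diagonal(entries, float(Cd))
    return ConsumptionMatrix(
        entries, scenario="specialist", params={"Cd": float(Cd), "Co": float(Co)}
    )


def calibrate_rates(
    C: ConsumptionMatrix | np.ndarray, n: float, r: float, eps: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Inflow and mortality rates making ``(r*1, n*1)`` a mean-field fixed point.

    Setting the resource equation to zero at the uniform state gives
    ``rho_k = r n sum_j C_kj``; the consumer equation gives
    ``eta_i = eps r sum_j C_ji``.  These are the unique such rates.
    """
    entries = C.entries if isinstance(C, ConsumptionMatrix) else np.asarray(C, float)
    if n <= 0 or r <= 0:
        raise ValueError("target abundances must be positive")
    row_sums = entries.sum(axis=1)
    col_sums = entries.sum(axis=0)
    if np.any(row_sums <= 0) or np.any(col_sums <= 0):
        raise ValueError(
            "calibration requires every resource to be consumed and every "
            "consumer to consume something (strictly positive row/column sums)"
        )
    rho = r * n * row_sums
    eta = eps * r * col_sums
    return rho, eta


def calibrate_community(
    C: ConsumptionMatrix, n: float, r: float, eps: float = 1.0
) -> CommunityParams:
    """Bundle :func:`calibrate_rates` output into a :class:`CommunityParams`."""
    rho, eta = calibrate_rates(C, n, r, eps)
    return CommunityParams(S=C.S, K=C.K, eps=eps, n=n, r=r, rho=rho, eta=eta)


def non_neutrality_index(C: ConsumptionMatrix | np.ndarray) -> float:
    """NNI = 1 - mean pairwise cosine between consumers' preference columns.

    0 for identical resource preferences (complete neutrality); 1 for
    pairwise-orthogonal preferences (complete niche differentiation).
    """
    entries = C.entries if isinstance(C, ConsumptionMatrix) else np.asarray(C, float)
    S = entries.shape[1]
    if S < 2:
        raise ValueError("NNI needs at least two consumers")
    norms = np.linalg.norm(entries, axis=0)
    if np.any(norms == 0):
        raise ValueError("NNI undefined with an all-zero preference column")
    unit = entries / norms
    gram = unit.T @ unit
    iu = np.triu_indices(S, k=1)
    return float(1.0 - gram[iu].mean())


def specialist_nni(S: int, ratio: float) -> float:
    """Closed-form NNI of the specialist matrix as a function of ``Cd/Co``.

    Any two distinct columns share ``S - 2`` entries at ``Co`` and swap
    ``Cd``/``Co`` on the two preferred rows, so with ``x = Cd/Co``::

        cos = (2 x + S - 2) / (x^2 + S - 1)

    independent of the overall scale.  ``ratio = inf`` (``Co = 0``) gives 1.
    """
    if S < 2:
        raise ValueError("NNI needs at least two consumers")
    if not np.isfinite(ratio):
        return 1.0
    if ratio < 1:
        raise ValueError("specialist scenario requires Cd/Co >= 1")
    x = float(ratio)
    return 1.0 - (2.0 * x + S - 2.0) / (x * x + S - 1.0)


def specialist_ratio_for_nni(S: int, nni: float) -> float:
    """Invert :func:`specialist_nni`: the ``Cd/Co`` giving a target NNI.

    Solves the quadratic ``(1 - nni) x^2 - 2 x + (1 - nni)(S - 1) - (S - 2) = 0``
    for the root ``x >= 1``.  ``nni = 1`` maps to infinity (``Co = 0``).
    """
    if not (0.0 <= nni <= 1.0):
        raise ValueError("NNI must lie in [0, 1]")
    if nni == 0.0:
        return 1.0
    if nni == 1.0:
        return np.inf
    c1 = 1.0 - nni
    # c1 * x^2 - 2x + (c1 * (S - 1) - (S - 2)) = 0
    c0 = c1 * (S - 1.0) - (S - 2.0)
    disc = 1.0 - c1 * c0
    if disc < 0:
        raise ValueError(f"NNI {nni} not attainable in the specialist scenario at S={S}")
    x = (1.0 + np.sqrt(disc)) / c1
    return float(x)
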