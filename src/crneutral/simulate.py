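"""Exact event-driven simulation of the stochastic consumer-resource process.

:func:`run_simulation` drives the compiled kernel in :mod:`crneutral._ssa`
and reports everything in *generations* (1 generation = the expected
individual lifespan ``1/eta_bar``).  The module also exposes a transparent
single-step interface (:func:`event_rates`, :func:`draw_next_event`,
:func:`apply_event`) used for exactness checks against brute-force Markov
chains and for didactic stepping of tiny systems.

Species selected for a death event at abundance 1 stay at abundance 1 — a
minimal stand-in for point speciation / rare immigration — and each such
event is logged as an extinction (turnover) with its time, so that a species
can "go extinct" repeatedly over a long run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _ssa
from .community import CommunityParams, ConsumptionMatrix

__all__ = [
    "SimState",
    "RateSet",
    "Schedule",
    "Trajectory",
    "event_rates",
    "draw_next_event",
    "apply_event",
    "run_simulation",
    "run_reference",
    "link_extinctions",
]


@dataclass
class SimState:
    """Integer abundances of all consumers and resources at model time ``t``."""

    N: np.ndarray
    R: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=np.int64)
        self.R = np.asarray(self.R, dtype=np.int64)
        if np.any(self.N < 1):
            raise ValueError("consumer abundances must be >= 1 (speciation floor)")
        if np.any(self.R < 0):
            raise ValueError("resource abundances must be non-negative")

    def copy(self) -> "SimState":
        return SimState(self.N.copy(), self.R.copy(), self.t)


class RateSet(NamedTuple):
    """Event rates at a state: inflow per resource, death per consumer, and
    the consumption matrix split into birth and non-birth parts."""

    inflow: np.ndarray  # (K,)
    death: np.ndarray  # (S,)
    consumption_birth: np.ndarray  # (K, S): eps * R_k C_ki N_i
    consumption_no_birth: np.ndarray  # (K, S): (1 - eps) * R_k C_ki N_i

    @property
    def consumption_total(self) -> float:
        return float(self.consumption_birth.sum() + self.consumption_no_birth.sum())

    @property
    def total(self) -> float:
        return float(self.inflow.sum() + self.death.sum()) + self.consumption_total


def event_rates(
    state: SimState, params: CommunityParams, C: ConsumptionMatrix
) -> RateSet:
    """All transition rates out of ``state``."""
    if np.any(state.N < 1) or np.any(state.R < 0):
        raise ValueError("invalid state")
    entries = C.entries if isinstance(C, ConsumptionMatrix) else np.asarray(C, float)
    cons = state.R[:, None] * entries * state.N[None, :]
    return RateSet(
        inflow=params.rho.copy(),
        death=params.eta * state.N,
        consumption_birth=params.eps * cons,
        consumption_no_birth=(1.0 - params.eps) * cons,
    )


def draw_next_event(rates: RateSet, rng: np.random.Generator):
    """Sample the waiting time and the next event from a :class:`RateSet`.

    Returns ``(event, dt)`` where ``event`` is one of ``("inflow", k)``,
    ``("death", i)``, ``("consume", k, i)`` or ``("birth", k, i)``.
    """
    total = rates.total
    if total <= 0:
        raise RuntimeError("total event rate is zero: absorbing state")
    dt = rng.exponential(1.0 / total)
    w = np.concatenate(
        [
            rates.inflow,
            rates.death,
            rates.consumption_no_birth.ravel(),
            rates.consumption_birth.ravel(),
        ]
    )
    idx = rng.choice(w.size, p=w / w.sum())
    K = rates.inflow.size
    S = rates.death.size
    if idx < K:
        return ("inflow", int(idx)), dt
    idx -= K
    if idx < S:
        return ("death", int(idx)), dt
    idx -= S
    kind = "consume" if idx < K * S else "birth"
    idx %= K * S
    return (kind, int(idx // S), int(idx % S)), dt


def apply_event(state: SimState, event, extinction_log: list | None = None) -> SimState:
    """Apply one event in place and return the state.

    A death drawn for a species at abundance 1 leaves abundances unchanged
    and appends ``(species, t)`` to ``extinction_log``.
    """
    kind = event[0]
    if kind == "inflow":
        state.R[event[1]] += 1
    elif kind == "death":
        i = event[1]
        if state.N[i] > 1:
            state.N[i] -= 1
        elif extinction_log is not None:
            extinction_log.append((i, state.t))
    elif kind in ("consume", "birth"):
        k, i = event[1], event[2]
        if state.R[k] <= 0:
            raise RuntimeError("consumption drawn for a depleted resource")
        state.R[k] -= 1
        if kind == "birth":
            state.N[i] += 1
    else:
        raise ValueError(f"unknown event {event!r}")
    return state


@dataclass(frozen=True)
class Schedule:
    """Timing of a run, all in generations.

    ``burn_in`` generations are simulated before recording starts; snapshots
    are then taken every ``cadence`` generations for ``runtime`` generations.
    """

    burn_in: float = 500.0
    runtime: float = 2000.0
    cadence: float = 50.0
    record_events: bool = False

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.runtime <= 0 or self.cadence <= 0:
            raise ValueError("schedule entries must be positive")


@dataclass
class Trajectory:
    """Recorded output of one simulation run.

    Snapshot times are in generations measured from the start of recording
    (i.e. after burn-in).  ``extinctions`` has columns ``species`` and
    ``t_gen`` on the same clock; burn-in extinctions are discarded.
    """

    times: np.ndarray  # (n_snap,) generations
    N: np.ndarray  # (n_snap, S)
    R: np.ndarray  # (n_snap, K)
    extinctions: pd.DataFrame
    event_counts: np.ndarray | None = None
    params: CommunityParams | None = None
    seed: int | None = None
    n_births: int = 0
    n_consumptions: int = 0
    initial_state: SimState | None = None
    final_state: SimState | None = None
    meta: dict = field(default_factory=dict)

    def snapshots_frame(self) -> pd.DataFrame:
        """Tidy (time_generations, species_id, abundance) table."""
        n_snap, S = self.N.shape
        return pd.DataFrame(
            {
                "time_generations": np.repeat(self.times, S),
                "species_id": np.tile(np.arange(S), n_snap),
                "abundance": self.N.ravel(),
            }
        )

    def to_text(self, directory: str | Path, prefix: str = "run") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.snapshots_frame().to_csv(directory / f"{prefix}_snapshots.tsv", sep="\t", index=False)
        self.extinctions.to_csv(directory / f"{prefix}_extinctions.tsv", sep="\t", index=False)
        if self.event_counts is not None:
            np.savetxt(directory / f"{prefix}_event_counts.tsv", self.event_counts, fmt="%d", delimiter="\t")


def _derive_seed(seed_or_seq) -> tuple[int, int]:
    """Two independent 31-bit kernel seeds (burn-in phase, recording phase)."""
    ss = seed_or_seq if isinstance(seed_or_seq, np.random.SeedSequence) else np.random.SeedSequence(seed_or_seq)
    s = ss.generate_state(2, dtype=np.uint32)
    return int(s[0] >> 1), int(s[1] >> 1)


def run_simulation(
    C: ConsumptionMatrix,
    params: CommunityParams,
    schedule: Schedule,
    seed: int | np.random.SeedSequence = 0,
    initial_state: SimState | None = None,
) -> Trajectory:
    """Simulate the exact stochastic process and collect scheduled output.

    The initial condition defaults to the deterministic equilibrium rounded to
    integers (``N = round(n)``, ``R = round(r)``).  Burn-in runs first with a
    derived seed; the recording phase continues from the burn-in endpoint with
    a second derived seed, taking abundance snapshots every
    ``schedule.cadence`` generations (the first at time 0 on the recording
    clock) and, when ``schedule.record_events`` is set, accumulating
    per-(resource, consumer) consumption-event counts over the recording
    window only.  Bit-for-bit reproducible from ``(C, params, schedule, seed)``.
    """
    entries = np.ascontiguousarray(C.entries, dtype=np.float64)
    Ct = np.ascontiguousarray(entries.T)
    gen = params.generation_time
    if initial_state is None:
        initial_state = SimState(
            np.full(params.S, max(1, round(params.n)), dtype=np.int64),
            np.full(params.K, max(0, round(params.r)), dtype=np.int64),
        )
    seed_burn, seed_rec = _derive_seed(seed)

    N0, R0 = initial_state.N.copy(), initial_state.R.copy()
    if schedule.burn_in > 0:
        out = _ssa.run_core(
            entries, Ct, params.rho, params.eta, params.eps,
            N0, R0, schedule.burn_in * gen,
            np.empty(0, dtype=np.float64), False, seed_burn,
        )
        N0, R0 = out[5], out[6]

    snap_times = np.arange(0.0, schedule.runtime + 1e-9, schedule.cadence) * gen
    (snapN, snapR, ext_sp, ext_t, events, N_fin, R_fin, n_birth, n_cons, _steps) = _ssa.run_core(
        entries, Ct, params.rho, params.eta, params.eps,
        N0, R0, schedule.runtime * gen,
        snap_times, schedule.record_events, seed_rec,
    )
    extinctions = pd.DataFrame({"species": ext_sp, "t_gen": ext_t / gen})
    return Trajectory(
        times=snap_times / gen,
        N=snapN,
        R=snapR,
        extinctions=extinctions,
        event_counts=events if schedule.record_events else None,
        params=params,
        seed=seed if isinstance(seed, int) else None,
        n_births=int(n_birth),
        n_consumptions=int(n_cons),
        initial_state=SimState(N0, R0),
        final_state=SimState(N_fin, R_fin),
        meta={"schedule": schedule},
    )


def run_reference(
    C: ConsumptionMatrix,
    params: CommunityParams,
    t_end: float,
    seed: int = 0,
    initial_state: SimState | None = None,
    sample_every: float | None = None,
):
    """Pure-Python event loop over the single-step interface.

    Slow but transparent; used to validate the compiled kernel against
    brute-force stationary distributions on tiny systems.  Returns the final
    state, the extinction log, and (if ``sample_every`` is given) the states
    sampled on that model-time grid as an ``(n_samples, S + K)`` array.
    """
    rng = np.random.default_rng(seed)
    if initial_state is None:
        initial_state = SimState(
            np.full(params.S, max(1, round(params.n)), dtype=np.int64),
            np.full(params.K, max(0, round(params.r)), dtype=np.int64),
        )
    state = initial_state.copy()
    ext: list = []
    samples = []
    next_sample = 0.0
    while state.t < t_end:
        rates = event_rates(state, params, C)
        event, dt = draw_next_event(rates, rng)
        t_new = state.t + dt
        if sample_every is not None:
            while next_sample <= min(t_new, t_end):
                samples.append(np.concatenate([state.N, state.R]))
                next_sample += sample_every
        state.t = t_new
        if state.t >= t_end:
            break
        apply_event(state, event, ext)
    return state, ext, (np.array(samples) if sample_every is not None else None)


def link_extinctions(traj: Trajectory) -> pd.DataFrame:
    """Pair every snapshot observation with that species' next extinction.

    Each recorded abundance of a species joins the species' pending list; when
    the species next logs an extinction all pending observations are flushed
    into records ``(species, observed_abundance, wait_generations)`` where the
    wait is from observation to extinction.  Observations with no later
    extinction within the run are dropped (right-censoring ignored).
    """
    records = []
    ext = traj.extinctions
    for i in range(traj.N.shape[1]):
        times_ext = ext.loc[ext["species"] == i, "t_gen"].to_numpy()
        if times_ext.size == 0:
            continue
        idx = np.searchsorted(times_ext, traj.times, side="left")
        ok = idx < times_ext.size
        for t_obs, n_obs, j in zip(traj.times[ok], traj.N[ok, i], idx[ok]):
            records.append((i, int(n_obs), float(times_ext[j] - t_obs)))
    return pd.DataFrame(records, columns=["species", "observed_abundance", "wait_generations"])
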