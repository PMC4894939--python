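"""Exact event-driven Monte-Carlo simulation of age-structured populations.

State is the vector of times of birth (TOB) of the living individuals;
ages are ``t - tob``.  Two statistically exact samplers are provided:

* **inversion** (size-independent hazards only): every individual carries
  its own event clock, drawn by exact inversion of the total-event
  survival ``exp(-int gamma)``; at an event a competing-risks coin
  ``beta/gamma`` decides birth versus death.  Clocks stay valid across
  events because no hazard depends on the population size.

* **thinning** (any bounded hazards): candidate events are proposed from
  a homogeneous bound and accepted with probability ``gamma_n(a)/bound``.
  Every accepted event discards all pending proposals (the bound and the
  hazards may depend on ``n``), so the scheme is exact for interacting
  models such as a carrying capacity.

A fixed-timestep scheme with O(dt) bias is available behind
``method="fixed-step"`` for fidelity experiments.

Randomness: each trajectory derives one stream from
``SeedSequence((master_seed, trajectory_index))``; spatial runs split it
into an event stream and a motion stream so that switching diffusion off
reproduces the non-spatial event sequence draw for draw.  Draw order is
fixed (founder ages, then per-event draws in event order) so event logs
are bitwise reproducible.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .rates import InvalidModelError, RateSpec

__all__ = [
    "PopulationState",
    "EventRecord",
    "Trajectory",
    "EnsembleSummary",
    "BoundViolationError",
    "simulate_budding",
    "simulate_fission_death",
    "simulate_spatial",
    "run_ensemble",
    "estimate_number_density",
    "estimate_marginal_age_density",
    "estimate_window_count_moments",
    "estimate_tob_density",
    "AgeDensityEstimate",
]


class BoundViolationError(RuntimeError):
    """A proposed hazard exceeded the declared thinning bound."""


@dataclass
class PopulationState:
    """Times of birth of the living individuals at clock time ``t``.

    ``doublet_tobs`` lists one TOB per living twin *pair* (fission models
    only).  ``positions`` (spatial models) aligns with ``singlet_tobs``.
    """

    t: float = 0.0
    singlet_tobs: np.ndarray = field(default_factory=lambda: np.empty(0))
    doublet_tobs: np.ndarray = field(default_factory=lambda: np.empty(0))
    positions: Optional[np.ndarray] = None

    def __post_init__(self):
        self.singlet_tobs = np.asarray(self.singlet_tobs, dtype=float)
        self.doublet_tobs = np.asarray(self.doublet_tobs, dtype=float)
        if np.any(self.singlet_tobs > self.t + 1e-12) or (
                self.doublet_tobs.size and np.any(self.doublet_tobs > self.t + 1e-12)):
            raise ValueError("every time of birth must be <= current time")

    @classmethod
    def from_ages(cls, ages, t: float = 0.0, positions=None) -> "PopulationState":
        ages = np.asarray(ages, dtype=float)
        return cls(t=t, singlet_tobs=t - ages, positions=None if positions is None
                   else np.asarray(positions, dtype=float))

    @property
    def size(self) -> int:
        """Number of living individuals (pairs count twice)."""
        return len(self.singlet_tobs) + 2 * len(self.doublet_tobs)

    def ages(self) -> np.ndarray:
        """Ages of all individuals (pair members appear twice)."""
        return np.concatenate([
            self.t - self.singlet_tobs,
            np.repeat(self.t - self.doublet_tobs, 2),
        ])


@dataclass
class EventRecord:
    time: float
    kind: str                    # {"birth", "fission", "death"}
    parent_tob: float
    child_tobs: Tuple[float, ...]
    n_before: int


@dataclass
class Trajectory:
    events: List[EventRecord]
    snapshots: dict              # time -> PopulationState
    seed_entropy: tuple


@dataclass
class EnsembleSummary:
    """Snapshot states of ``R`` independent trajectories.

    ``states[k][r]`` is the (singlet_tobs, doublet_tobs) pair of
    trajectory ``r`` at ``snapshot_times[k]``.
    """

    snapshot_times: np.ndarray
    states: list
    R: int
    master_seed: int
    meta: dict = field(default_factory=dict)

    def snapshot_index(self, t: float) -> int:
        idx = np.nonzero(np.isclose(self.snapshot_times, t))[0]
        if len(idx) == 0:
            raise KeyError(f"no snapshot at t = {t}; have {self.snapshot_times}")
        return int(idx[0])


# ---------------------------------------------------------------------------
# core samplers
# ---------------------------------------------------------------------------

def _resolve_rng(seed) -> Tuple[np.random.Generator, np.random.Generator, tuple]:
    """Event and motion streams from one seed (int, tuple or SeedSequence)."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    ev, mv = ss.spawn(2)
    return np.random.default_rng(ev), np.random.default_rng(mv), tuple(
        np.atleast_1d(ss.entropy).tolist())


def _snapshot_checkpoints(snapshot_times, t_final) -> List[float]:
    snaps = sorted(float(s) for s in snapshot_times)
    if any(s < 0 or s > t_final + 1e-12 for s in snaps):
        raise ValueError("snapshot times must lie in [0, t_final]")
    return snaps


def simulate_budding(rates: RateSpec, init: PopulationState, t_final: float,
                     seed, snapshot_times: Sequence[float] = (),
                     method: str = "auto", dt: Optional[float] = None,
                     record_events: bool = True) -> Trajectory:
    """Simulate the budding birth-death process exactly.

    Each of the ``n`` living individuals of age ``a`` gives birth at rate
    ``beta_n(a)`` (adding an age-0 individual, parent unaffected) and dies
    at rate ``mu_n(a)``.
    """
    if len(init.doublet_tobs):
        raise InvalidModelError("budding dynamics has no twin pairs")
    rng, _, entropy = _resolve_rng(seed)
    if method == "auto":
        method = "inversion" if rates.size_independent else "thinning"
    if method == "inversion":
        return _budding_inversion(rates, init, t_final, rng, snapshot_times,
                                  entropy, record_events)
    if method == "thinning":
        return _thinning_run(rates, init, t_final, rng, snapshot_times,
                             entropy, record_events, fission=False)
    if method == "fixed-step":
        if dt is None:
            raise ValueError("fixed-step method requires dt")
        return _fixed_step_run(rates, init, t_final, rng, snapshot_times,
                               entropy, record_events, dt, fission=False)
    raise ValueError(f"unknown method {method!r}")


def _budding_inversion(rates, init, t_final, rng, snapshot_times, entropy,
                       record_events):
    tobs: List[float] = list(init.singlet_tobs)
    alive: List[bool] = [True] * len(tobs)
    heap: List[Tuple[float, int]] = []
    t0 = init.t
    for i, b in enumerate(tobs):  # founder clocks in index order
        ev_age = rates.sample_event_age(rng, t0 - b)
        if math.isfinite(ev_age):
            heapq.heappush(heap, (b + ev_age, i))

    events: List[EventRecord] = []
    snapshots = {}
    checkpoints = _snapshot_checkpoints(snapshot_times, t_final)
    ci = 0
    t = t0

    def record_through(up_to):
        nonlocal ci
        while ci < len(checkpoints) and checkpoints[ci] <= up_to + 1e-15:
            s = checkpoints[ci]
            live = np.array([b for b, a in zip(tobs, alive) if a])
            snapshots[s] = PopulationState(t=s, singlet_tobs=live)
            ci += 1

    while heap:
        t_ev, idx = heapq.heappop(heap)
        if not alive[idx]:
            continue
        if t_ev > t_final:
            break
        record_through(t_ev - 1e-15)  # snapshots strictly before the event
        t = t_ev
        a = t - tobs[idx]
        beta = float(rates.beta(1, a))
        gam = beta + float(rates.mu(1, a))
        n_before = sum(alive)
        if gam <= 0:
            continue
        if rng.uniform() * gam < beta:
            child = t
            tobs.append(child)
            alive.append(True)
            ev_age = rates.sample_event_age(rng, 0.0)
            if math.isfinite(ev_age):
                heapq.heappush(heap, (child + ev_age, len(tobs) - 1))
            ev_age_p = rates.sample_event_age(rng, a)
            if math.isfinite(ev_age_p):
                heapq.heappush(heap, (tobs[idx] + ev_age_p, idx))
            if record_events:
                events.append(EventRecord(t, "birth", tobs[idx], (child,),
                                          n_before))
        else:
            alive[idx] = False
            if record_events:
                events.append(EventRecord(t, "death", tobs[idx], (), n_before))
    record_through(t_final)
    return Trajectory(events=events, snapshots=snapshots, seed_entropy=entropy)


def _individual_list(init: PopulationState, fission: bool):
    """Flat individual arrays (tobs, alive, twin index) from a state."""
    tobs: List[float] = list(init.singlet_tobs)
    twin: List[int] = [-1] * len(tobs)
    if fission:
        for b in init.doublet_tobs:
            i = len(tobs)
            tobs.extend([b, b])
            twin.extend([i + 1, i])
    elif len(init.doublet_tobs):
        raise InvalidModelError("twin pairs require a fission model")
    return tobs, [True] * len(tobs), twin


def _state_from_individuals(t, tobs, alive, twin) -> PopulationState:
    singles, pairs = [], []
    seen = set()
    for i, (b, al) in enumerate(zip(tobs, alive)):
        if not al or i in seen:
            continue
        j = twin[i]
        if j >= 0 and alive[j]:
            pairs.append(b)
            seen.add(j)
        else:
            singles.append(b)
    return PopulationState(t=t, singlet_tobs=np.array(singles),
                           doublet_tobs=np.array(pairs))


def simulate_fission_death(rates: RateSpec, init: PopulationState,
                           t_final: float, seed,
                           snapshot_times: Sequence[float] = (),
                           method: str = "auto",
                           record_events: bool = True) -> Trajectory:
    """Simulate the binary fission-death process exactly.

    Each individual (twin pairs are two individuals sharing a TOB, hence
    a pair carries twice the hazard) experiences events at rate
    ``gamma(a)``; with probability ``h2`` the individual is replaced by a
    newborn twin pair, with ``h0`` it dies.  A surviving twin becomes a
    singlet but keeps its TOB.
    """
    if rates.progeny_split is None:
        raise InvalidModelError("fission dynamics needs a progeny split (h0, h2)")
    rng, _, entropy = _resolve_rng(seed)
    if method == "auto":
        method = "inversion" if rates.size_independent else "thinning"
    if method == "thinning":
        return _thinning_run(rates, init, t_final, rng, snapshot_times,
                             entropy, record_events, fission=True)
    if method != "inversion":
        raise ValueError(f"unknown method {method!r}")

    tobs, alive, twin = _individual_list(init, fission=True)
    heap: List[Tuple[float, int]] = []
    t0 = init.t
    for i, b in enumerate(tobs):
        ev_age = rates.sample_event_age(rng, t0 - b)
        if math.isfinite(ev_age):
            heapq.heappush(heap, (b + ev_age, i))

    events: List[EventRecord] = []
    snapshots = {}
    checkpoints = _snapshot_checkpoints(snapshot_times, t_final)
    ci = 0

    def record_through(up_to):
        nonlocal ci
        while ci < len(checkpoints) and checkpoints[ci] <= up_to + 1e-15:
            s = checkpoints[ci]
            snapshots[s] = _state_from_individuals(s, tobs, alive, twin)
            ci += 1

    while heap:
        t_ev, idx = heapq.heappop(heap)
        if not alive[idx]:
            continue
        if t_ev > t_final:
            break
        record_through(t_ev - 1e-15)
        t = t_ev
        a = t - tobs[idx]
        beta = float(rates.beta(1, a))
        gam = beta + float(rates.mu(1, a))
        n_before = sum(alive)
        p_fission = rates.progeny_split[1] if gam <= 0 else beta / gam
        if rng.uniform() < p_fission:
            alive[idx] = False
            j = twin[idx]
            if j >= 0:
                twin[j] = -1  # surviving twin becomes a singlet
            i1, i2 = len(tobs), len(tobs) + 1
            tobs.extend([t, t])
            alive.extend([True, True])
            twin.extend([i2, i1])
            for child in (i1, i2):
                ev_age = rates.sample_event_age(rng, 0.0)
                if math.isfinite(ev_age):
                    heapq.heappush(heap, (t + ev_age, child))
            if record_events:
                events.append(EventRecord(t, "fission", tobs[idx], (t, t),
                                          n_before))
        else:
            alive[idx] = False
            j = twin[idx]
            if j >= 0:
                twin[j] = -1
            if record_events:
                events.append(EventRecord(t, "death", tobs[idx], (), n_before))
    record_through(t_final)
    return Trajectory(events=events, snapshots=snapshots, seed_entropy=entropy)


def _thinning_run(rates, init, t_final, rng, snapshot_times, entropy,
                  record_events, fission, positions=None, D=0.0,
                  rng_motion=None):
    """Ogata thinning: exact for bounded (possibly n-dependent) hazards."""
    if rates.hazard_bound is None:
        raise InvalidModelError(
            "thinning requires a finite hazard_bound(n) on beta + mu")
    tobs, alive, twin = _individual_list(init, fission)
    spatial = positions is not None
    pos = list(positions) if spatial else None

    events: List[EventRecord] = []
    snapshots = {}
    checkpoints = _snapshot_checkpoints(snapshot_times, t_final)
    ci = 0
    t = init.t

    def move_to(t_new):
        nonlocal t
        dt_ = t_new - t
        if spatial and dt_ > 0:
            sd = math.sqrt(2.0 * D * dt_)
            for i in range(len(pos)):
                z = rng_motion.normal()
                if alive[i]:
                    pos[i] += sd * z
        t = t_new

    def record_through(up_to):
        nonlocal ci
        while ci < len(checkpoints) and checkpoints[ci] <= up_to + 1e-15:
            s = checkpoints[ci]
            move_to(s)
            st = _state_from_individuals(s, tobs, alive, twin)
            if spatial:
                live_pos = [p for p, al in zip(pos, alive) if al]
                st.positions = np.array(live_pos)
            snapshots[s] = st
            ci += 1

    live_idx = [i for i, al in enumerate(alive) if al]
    while True:
        n = len(live_idx)
        if n == 0:
            break
        bound = float(rates.hazard_bound(n))
        if bound <= 0:
            break
        total = n * bound
        t_prop = t + rng.exponential(1.0 / total)
        if t_prop > t_final:
            break
        record_through(t_prop - 1e-15)
        move_to(t_prop)
        idx = live_idx[rng.integers(n)]
        a = t - tobs[idx]
        if spatial:
            beta = float(rates.birth_hazard(n, a, pos[idx]))
            mu = float(rates.death_hazard(n, a, pos[idx]))
        else:
            beta = float(rates.beta(n, a))
            mu = float(rates.mu(n, a))
        gam = beta + mu
        if gam > bound * (1.0 + 1e-9):
            raise BoundViolationError(
                f"hazard {gam} exceeds bound {bound} at age {a}, n={n}")
        u = rng.uniform() * bound
        if u >= gam:
            continue  # thinned proposal
        n_before = n
        if rng.uniform() * gam < beta:
            if fission:
                h2 = rates.progeny_split[1]
                # beta already carries h2 through the hazards; the event
                # splits the individual into a twin pair
                alive[idx] = False
                j = twin[idx]
                if j >= 0:
                    twin[j] = -1
                i1, i2 = len(tobs), len(tobs) + 1
                tobs.extend([t, t])
                alive.extend([True, True])
                twin.extend([i2, i1])
                if spatial:
                    pos.extend([pos[idx], pos[idx]])
                if record_events:
                    events.append(EventRecord(t, "fission", tobs[idx], (t, t),
                                              n_before))
            else:
                tobs.append(t)
                alive.append(True)
                twin.append(-1)
                if spatial:
                    pos.append(pos[idx])
                if record_events:
                    events.append(EventRecord(t, "birth", tobs[idx], (t,),
                                              n_before))
        else:
            alive[idx] = False
            if fission:
                j = twin[idx]
                if j >= 0:
                    twin[j] = -1
            if record_events:
                events.append(EventRecord(t, "death", tobs[idx], (), n_before))
        live_idx = [i for i, al in enumerate(alive) if al]
    record_through(t_final)
    return Trajectory(events=events, snapshots=snapshots, seed_entropy=entropy)


def _fixed_step_run(rates, init, t_final, rng, snapshot_times, entropy,
                    record_events, dt, fission):
    """First-order fixed-timestep scheme (O(dt) bias; diagnostics only)."""
    tobs, alive, twin = _individual_list(init, fission)
    events: List[EventRecord] = []
    snapshots = {}
    checkpoints = _snapshot_checkpoints(snapshot_times, t_final)
    ci = 0
    t = init.t
    while t < t_final - 1e-12:
        step = min(dt, t_final - t)
        t_new = t + step
        n = sum(alive)
        for idx in [i for i, al in enumerate(alive) if al]:
            a = t - tobs[idx]
            beta = float(rates.beta(n, a))
            mu = float(rates.mu(n, a))
            u = rng.uniform()
            if u < (beta + mu) * step:
                n_before = sum(alive)
                if u < beta * step:
                    if fission:
                        alive[idx] = False
                        j = twin[idx]
                        if j >= 0:
                            twin[j] = -1
                        i1, i2 = len(tobs), len(tobs) + 1
                        tobs.extend([t_new, t_new])
                        alive.extend([True, True])
                        twin.extend([i2, i1])
                        kind = "fission"
                        childs = (t_new, t_new)
                    else:
                        tobs.append(t_new)
                        alive.append(True)
                        twin.append(-1)
                        kind = "birth"
                        childs = (t_new,)
                else:
                    alive[idx] = False
                    if fission:
                        j = twin[idx]
                        if j >= 0:
                            twin[j] = -1
                    kind = "death"
                    childs = ()
                if record_events:
                    events.append(EventRecord(t_new, kind, tobs[idx], childs,
                                              n_before))
        t = t_new
        while ci < len(checkpoints) and checkpoints[ci] <= t + 1e-12:
            snapshots[checkpoints[ci]] = _state_from_individuals(
                checkpoints[ci], tobs, alive, twin)
            ci += 1
    while ci < len(checkpoints):
        snapshots[checkpoints[ci]] = _state_from_individuals(
            checkpoints[ci], tobs, alive, twin)
        ci += 1
    return Trajectory(events=events, snapshots=snapshots, seed_entropy=entropy)


def simulate_spatial(rates: RateSpec, D: float, init: PopulationState,
                     t_final: float, seed,
                     snapshot_times: Sequence[float] = (),
                     record_events: bool = True) -> Trajectory:
    """Budding birth-death with independent 1-d Brownian motion.

    Hazards are called as ``f(n, a, q)``; a newborn starts at its parent's
    current position.  Motion uses a dedicated random stream, so with
    ``D = 0`` the event sequence is draw-for-draw identical to
    :func:`simulate_budding` under the same seed.
    """
    if D < 0:
        raise InvalidModelError(f"diffusivity must be nonnegative, got {D}")
    if init.positions is None or len(init.positions) != len(init.singlet_tobs):
        raise ValueError("spatial simulation needs one position per individual")
    rng, rng_motion, entropy = _resolve_rng(seed)
    return _thinning_run(rates, init, t_final, rng, snapshot_times, entropy,
                         record_events, fission=False,
                         positions=np.asarray(init.positions, dtype=float),
                         D=D, rng_motion=rng_motion)


# ---------------------------------------------------------------------------
# ensembles and estimators
# ---------------------------------------------------------------------------

def run_ensemble(kind: str, rates: RateSpec, init, R: int, t_final: float,
                 snapshot_times: Sequence[float], seed: int,
                 method: str = "auto", D: float = 0.0,
                 init_ages=None) -> EnsembleSummary:
    """Simulate ``R`` independent trajectories and keep their snapshots.

    ``init`` is a fixed :class:`PopulationState` or a callable
    ``rng -> PopulationState`` (e.g. to draw founder ages per trajectory;
    the callable consumes the trajectory's event stream first, keeping
    runs reproducible).  ``kind`` is "budding", "fission" or "spatial".
    """
    snaps = sorted(float(s) for s in snapshot_times)
    states = [[] for _ in snaps]
    for r in range(R):
        ss = np.random.SeedSequence((seed, r))
        if callable(init):
            probe = np.random.default_rng(ss.spawn(3)[2])
            state0 = init(probe)
        else:
            state0 = init
        if kind == "budding":
            traj = simulate_budding(rates, state0, t_final, ss, snaps,
                                    method=method, record_events=False)
        elif kind == "fission":
            traj = simulate_fission_death(rates, state0, t_final, ss, snaps,
                                          method=method, record_events=False)
        elif kind == "spatial":
            traj = simulate_spatial(rates, D, state0, t_final, ss, snaps,
                                    record_events=False)
        else:
            raise ValueError(f"unknown simulation kind {kind!r}")
        for k, s in enumerate(snaps):
            st = traj.snapshots[s]
            entry = (st.singlet_tobs, st.doublet_tobs)
            if st.positions is not None:
                entry = entry + (st.positions,)
            states[k].append(entry)
    return EnsembleSummary(snapshot_times=np.array(snaps), states=states,
                           R=R, master_seed=seed,
                           meta={"kind": kind, "model": rates.name,
                                 "method": method})


def estimate_number_density(ens: EnsembleSummary, t: float) -> pd.Series:
    """Empirical population-size law rho_n(t); sums to one."""
    k = ens.snapshot_index(t)
    sizes = np.array([len(s) + 2 * len(d) for s, d, *_ in ens.states[k]])
    counts = np.bincount(sizes)
    return pd.Series(counts / ens.R,
                     index=pd.Index(np.arange(len(counts)), name="n"),
                     name=f"rho_n(t={t})")


@dataclass
class AgeDensityEstimate:
    """Binned marginal age density with per-bin standard errors.

    ``values`` integrate (over the bin measure) to the empirical
    probability ``weight`` of the conditioning event; ``empty`` flags a
    condition that no trajectory realised.
    """

    bins: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    weight: float
    k: int = 1
    empty: bool = False


def estimate_marginal_age_density(ens: EnsembleSummary, t: float,
                                  n_filter: Union[int, str] = "all",
                                  k: int = 1, bins=None) -> AgeDensityEstimate:
    """Estimate the k-point marginal age density at a snapshot.

    One uniformly chosen individual (k = 1) or unordered pair (k = 2) per
    qualifying trajectory keeps the samples i.i.d. across trajectories,
    giving clean per-bin standard errors; the k = 2 estimate is
    symmetrised across the diagonal.  Normalisation: the estimate
    integrates to the empirical probability of the size filter.
    """
    if k not in (1, 2):
        raise ValueError("only one- and two-point marginals are estimated")
    if bins is None:
        raise ValueError("bins (strictly increasing edges) are required")
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be strictly increasing")
    ki = ens.snapshot_index(t)
    picker = np.random.default_rng(
        np.random.SeedSequence((ens.master_seed, 2 ** 31 - 1, ki, k)))
    samples = []
    n_qual = 0
    for s, d, *_ in ens.states[ki]:
        ages = np.concatenate([t - s, np.repeat(t - d, 2)])
        n = len(ages)
        if n_filter != "all" and n != n_filter:
            continue
        if n < k:
            continue
        n_qual += 1
        if k == 1:
            samples.append(ages[picker.integers(n)])
        else:
            i, j = picker.choice(n, size=2, replace=False)
            samples.append((ages[i], ages[j]))
    weight = n_qual / ens.R
    nb = len(bins) - 1
    if n_qual == 0:
        shape = (nb,) if k == 1 else (nb, nb)
        return AgeDensityEstimate(bins, np.zeros(shape), np.zeros(shape),
                                  0.0, k, empty=True)
    if k == 1:
        samples = np.array(samples)
        counts, _ = np.histogram(samples, bins)
        width = np.diff(bins)
        p = counts / n_qual
        values = weight * p / width
        stderr = weight * np.sqrt(p * (1 - p) / n_qual) / width
    else:
        arr = np.array(samples)
        c1, _, _ = np.histogram2d(arr[:, 0], arr[:, 1], bins=(bins, bins))
        c2 = c1.T
        counts = 0.5 * (c1 + c2)
        area = np.outer(np.diff(bins), np.diff(bins))
        p = counts / n_qual
        values = weight * p / area
        stderr = weight * np.sqrt(p * (1 - p) / n_qual) / area
    return AgeDensityEstimate(bins, values, stderr, weight, k)


def estimate_window_count_moments(ens: EnsembleSummary, t: float,
                                  window) -> Tuple[float, float]:
    """Sample mean and unbiased variance of the count aged in [a, b)."""
    a, b = window
    if not a < b:
        raise ValueError("window requires a < b")
    ki = ens.snapshot_index(t)
    counts = np.empty(ens.R)
    for r, (s, d, *_) in enumerate(ens.states[ki]):
        ages = np.concatenate([t - s, np.repeat(t - d, 2)])
        counts[r] = np.count_nonzero((ages >= a) & (ages < b))
    return float(counts.mean()), float(counts.var(ddof=1))


def estimate_tob_density(ens: EnsembleSummary, t: float, which: str,
                         bins) -> AgeDensityEstimate:
    """Mean density of times of birth at a snapshot, with standard errors.

    ``which`` selects "singlet" (TOBs of twinless individuals), "doublet"
    (one TOB per living pair) or "individual" (every individual; pair
    members count twice).  The estimate is the expected *number* of
    entries per unit TOB, comparable with the mean-field densities
    X(x, t), Y(x, t) and T(x, t).
    """
    bins = np.asarray(bins, dtype=float)
    ki = ens.snapshot_index(t)
    width = np.diff(bins)
    per_traj = np.empty((ens.R, len(bins) - 1))
    for r, (s, d, *_) in enumerate(ens.states[ki]):
        if which == "singlet":
            x = s
        elif which == "doublet":
            x = d
        elif which == "individual":
            x = np.concatenate([s, np.repeat(d, 2)])
        else:
            raise ValueError(f"unknown selector {which!r}")
        per_traj[r], _ = np.histogram(x, bins)
    mean = per_traj.mean(axis=0) / width
    se = per_traj.std(axis=0, ddof=1) / math.sqrt(ens.R) / width
    return AgeDensityEstimate(bins, mean, se, 1.0, 1)
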