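"""Model definitions: hazards, propagators, and waiting-time conversions.

The central object is :class:`RateSpec`, a pair of per-individual hazard
functions ``beta_n(a)`` (birth or fission) and ``mu_n(a)`` (death), both of
which may depend on the current population size ``n`` and on the
individual's age ``a``.  The total event hazard is ``gamma_n(a) =
beta_n(a) + mu_n(a)``.  Everything downstream (the exact simulators, the
mean-field solvers, the factorial-moment solvers) consumes a ``RateSpec``.

Internally all state is stored as times of birth (TOB) ``b = t - a``; ages
are derived quantities.  TOB is constant along the characteristics of the
transport operator, which keeps both the simulator bookkeeping and the
analytic solutions simple.

Built-in constructors attach optional closed-form fast paths (cumulative
hazards, exact event-age samplers, Laplace transforms).  The generic slow
paths use adaptive quadrature and root finding, and the two are
cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "RateSpec",
    "WaitingTimeSpec",
    "InvalidModelError",
    "carrying_capacity_birth",
    "propagator",
    "hazards_from_waiting_time",
    "sample_initial_ages",
    "constant_rates",
    "linear_death_rates",
    "carrying_capacity_rates",
    "exponential_waiting",
    "gamma_waiting",
    "REFERENCE_GAMMA_SHAPE",
    "REFERENCE_GAMMA_RATE",
]

# Reference initial-age distribution used throughout: Gamma with unit mean
# and standard deviation 1/2, i.e. shape 4 and rate 4.
REFERENCE_GAMMA_SHAPE = 4.0
REFERENCE_GAMMA_RATE = 4.0

# Absolute tolerance for adaptive quadrature of hazard integrals.
QUAD_ABS_TOL = 1e-10


class InvalidModelError(ValueError):
    """A hazard specification violates a model invariant."""


@dataclass
class WaitingTimeSpec:
    """Inter-event waiting time distribution ``g`` with CDF ``G``.

    ``density`` must be a proper probability density on ``[0, inf)``.
    ``laplace`` (the transform ``g~(s)``), when available in closed form,
    enables the Laplace-domain solution paths; ``hazard_sup`` is a finite
    upper bound on the hazard ``g/(1-G)`` used by the thinning simulator.
    """

    density: Callable[[np.ndarray], np.ndarray]
    cdf: Callable[[np.ndarray], np.ndarray]
    sf: Callable[[np.ndarray], np.ndarray]
    isf: Callable[[np.ndarray], np.ndarray]
    laplace: Optional[Callable[[complex], complex]] = None
    hazard_sup: Optional[float] = None
    support_upper: float = math.inf
    fresh_sampler: Optional[Callable[[np.random.Generator], float]] = None
    name: str = "waiting-time"

    def hazard(self, a):
        """Event hazard ``g(a) / (1 - G(a))``."""
        a = np.asarray(a, dtype=float)
        s = self.sf(a)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s > 0, self.density(a) / np.where(s > 0, s, 1.0), np.inf)
        return out

    def sample(self, rng: np.random.Generator, size=None):
        """Draw waiting times by inverse-survival sampling."""
        return self.isf(rng.uniform(size=size))

    def sample_remaining(self, rng: np.random.Generator, a0: float) -> float:
        """Age at the next event for an individual already of age ``a0``.

        Exact conditional sampling: ``P(A > a | A > a0) = S(a)/S(a0)``.
        Newborns (``a0 = 0``) use the direct sampler when one is attached
        (same law, much cheaper than inverse-survival lookup).
        """
        if a0 == 0.0 and self.fresh_sampler is not None:
            return float(self.fresh_sampler(rng))
        s0 = float(self.sf(a0))
        if s0 <= 0.0:
            return a0  # at or beyond the support edge: forced event
        return float(self.isf(s0 * rng.uniform()))


def exponential_waiting(rate: float = 1.0) -> WaitingTimeSpec:
    """Exponential waiting times with the given rate (constant hazard)."""
    if rate <= 0:
        raise InvalidModelError(f"exponential rate must be positive, got {rate}")
    d = stats.expon(scale=1.0 / rate)
    return WaitingTimeSpec(
        density=d.pdf,
        cdf=d.cdf,
        sf=d.sf,
        isf=d.isf,
        laplace=lambda s: rate / (rate + s),
        hazard_sup=rate,
        fresh_sampler=lambda rng: rng.exponential(1.0 / rate),
        name=f"exponential(rate={rate})",
    )


def gamma_waiting(alpha: float) -> WaitingTimeSpec:
    """Gamma waiting times with unit mean and variance ``1/alpha``.

    Shape and rate both equal ``alpha``; the transform is
    ``g~(s) = (alpha / (alpha + s))**alpha``.  For ``alpha >= 1`` the hazard
    is nondecreasing with supremum ``alpha``, which doubles as the thinning
    bound.
    """
    if alpha <= 0:
        raise InvalidModelError(f"gamma shape must be positive, got {alpha}")
    d = stats.gamma(alpha, scale=1.0 / alpha)
    sup = float(alpha) if alpha >= 1 else None
    return WaitingTimeSpec(
        density=d.pdf,
        cdf=d.cdf,
        sf=d.sf,
        isf=d.isf,
        laplace=lambda s, a=float(alpha): (a / (a + s)) ** a,
        hazard_sup=sup,
        fresh_sampler=lambda rng, a=float(alpha): rng.gamma(a, 1.0 / a),
        name=f"gamma(alpha={alpha})",
    )


@dataclass
class RateSpec:
    """Hazard pair ``(beta_n(a), mu_n(a))`` defining a birth-death model.

    ``progeny_split = (h0, h2)`` marks a binary fission model: on an event,
    the individual either dies (probability ``h0``) or is replaced by a
    newborn twin pair (probability ``h2``).  Absent, events are budding
    births (parent survives, one age-0 offspring) or deaths.

    ``hazard_bound(n)`` is a finite bound on ``gamma_n(a)`` over all ages,
    required by the thinning simulator unless an exact sampler is attached.
    The optional closed-form hooks (cumulative hazards, event-age sampler,
    Laplace transforms) are fast paths; every built-in constructor attaches
    the ones it knows, and the generic quadrature path is always available
    for size-independent models.
    """

    birth_hazard: Callable[[int, np.ndarray], np.ndarray]
    death_hazard: Callable[[int, np.ndarray], np.ndarray]
    progeny_split: Optional[Tuple[float, float]] = None
    hazard_bound: Optional[Callable[[int], float]] = None
    size_independent: bool = True
    age_independent: bool = False
    # closed-form hooks (size-independent models only)
    death_cumhaz: Optional[Callable[[float, float], float]] = None
    total_cumhaz: Optional[Callable[[float, float], float]] = None
    event_age_sampler: Optional[Callable[[np.random.Generator, float], float]] = None
    # Laplace transform of the budding renewal kernel U_death(0,t)*beta(t)
    kernel_laplace: Optional[Callable[[complex], complex]] = None
    waiting_time: Optional[WaitingTimeSpec] = None
    # reserved: pairwise birth kernels beta(a_i, a_j) are part of the model
    # class but no solver or simulator consumes them yet
    pair_birth_kernel: Optional[Callable] = None
    name: str = "rates"

    def __post_init__(self):
        if self.pair_birth_kernel is not None:
            raise NotImplementedError(
                "multi-parent birth kernels are reserved but not implemented")
        if self.progeny_split is not None:
            h0, h2 = self.progeny_split
            if not (0.0 <= h0 <= 1.0 and 0.0 <= h2 <= 1.0):
                raise InvalidModelError("progeny probabilities must lie in [0, 1]")
            if abs(h0 + h2 - 1.0) > 1e-12:
                raise InvalidModelError("progeny probabilities must sum to 1")

    # -- hazard evaluation -------------------------------------------------

    def beta(self, n: int, a):
        return self.birth_hazard(n, np.asarray(a, dtype=float))

    def mu(self, n: int, a):
        return self.death_hazard(n, np.asarray(a, dtype=float))

    def gamma(self, n: int, a):
        a = np.asarray(a, dtype=float)
        return self.birth_hazard(n, a) + self.death_hazard(n, a)

    # -- cumulative hazards ------------------------------------------------

    def cumulative_hazard(self, a0: float, a1: float, which: str = "total",
                          n: int = 1) -> float:
        """Integral of the chosen hazard over ages ``[a0, a1]``."""
        if a1 <= a0:
            return 0.0
        if self.size_independent:
            if which == "death" and self.death_cumhaz is not None:
                return self.death_cumhaz(a0, a1)
            if which == "total" and self.total_cumhaz is not None:
                return self.total_cumhaz(a0, a1)
        if which == "death":
            h = lambda a: self.death_hazard(n, np.asarray(a, float))
        elif which == "total":
            h = lambda a: self.gamma(n, a)
        else:
            raise ValueError(f"unknown hazard selector {which!r}")

        def integrand(a):
            v = float(h(a))
            if v < -1e-12:
                raise InvalidModelError(f"negative hazard {v} at age {a}")
            return v

        val, _ = integrate.quad(integrand, a0, a1, epsabs=QUAD_ABS_TOL, limit=200)
        return val

    def sample_event_age(self, rng: np.random.Generator, a0: float) -> float:
        """Age at the next event for an individual of current age ``a0``.

        Exact inversion of the total-event survival; returns ``inf`` when
        the residual cumulative hazard is finite and the exponential draw
        exceeds it.  Only valid for size-independent hazards.
        """
        if not self.size_independent:
            raise InvalidModelError(
                "exact event-age sampling requires size-independent hazards")
        if self.event_age_sampler is not None:
            return self.event_age_sampler(rng, a0)
        # generic numeric inversion: solve Lambda(a0, a) = E
        target = rng.exponential()
        hi = a0 + 1.0
        lam = self.cumulative_hazard(a0, hi, "total")
        n_grow = 0
        while lam < target:
            hi = a0 + 2.0 * (hi - a0)
            lam = self.cumulative_hazard(a0, hi, "total")
            n_grow += 1
            if n_grow > 60:
                return math.inf
        f = lambda a: self.cumulative_hazard(a0, a, "total") - target
        return float(optimize.brentq(f, a0, hi, xtol=1e-12, rtol=1e-14))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def carrying_capacity_birth(beta0: float, K: float, n: int) -> float:
    """Per-individual birth rate ``beta0 * (1 - n/K)``, clamped at zero.

    The clamp keeps the hazard nonnegative when ``n`` transiently exceeds
    the ceiling ``K`` (e.g. through initial conditions).
    """
    if K <= 0:
        raise InvalidModelError(f"carrying capacity must be positive, got {K}")
    if beta0 < 0:
        raise InvalidModelError(f"intrinsic birth rate must be nonnegative, got {beta0}")
    return max(beta0 * (1.0 - n / K), 0.0)


def propagator(rate_spec: RateSpec, n: int, b: float, t0: float, t1: float,
               which: str = "death") -> float:
    """No-event probability ``exp(-int_{t0}^{t1} h(s - b) ds)``.

    ``which`` selects the hazard: ``"death"`` gives the survival
    probability (death hazard only); ``"total"`` the probability of no
    event at all (birth or death).  ``b`` is the individual's time of
    birth, so ``s - b`` is its age at clock time ``s``.
    """
    if t1 < t0:
        raise ValueError(f"require t0 <= t1, got {t0} > {t1}")
    if b > t0 + 1e-12:
        raise ValueError(f"time of birth {b} must precede interval start {t0}")
    key = {"death": "death", "death-only": "death",
           "total": "total", "total-event": "total"}[which]
    lam = rate_spec.cumulative_hazard(t0 - b, t1 - b, key, n=n)
    return math.exp(-lam)


def hazards_from_waiting_time(w: WaitingTimeSpec, h2: float) -> RateSpec:
    """Convert a waiting-time law plus progeny split into fission hazards.

    With event-time density ``g`` and survival ``1 - G``, the fission and
    death hazards are ``beta(a) = h2 g(a)/(1-G(a))`` and
    ``mu(a) = h0 g(a)/(1-G(a))``; the total-event propagator then equals
    ``1 - G(t - x)``, so the event-time law of each individual reproduces
    ``g`` exactly.  Hazards at or beyond the support edge of ``g`` are the
    simulator's problem: it treats the edge as a forced event.
    """
    if not (0.0 <= h2 <= 1.0):
        raise InvalidModelError(f"h2 must be a probability, got {h2}")
    h0 = 1.0 - h2

    def beta(n, a):
        return h2 * w.hazard(a)

    def mu(n, a):
        return h0 * w.hazard(a)

    def total_cumhaz(a0, a1):
        s0, s1 = float(w.sf(a0)), float(w.sf(a1))
        if s1 <= 0.0:
            if float(w.density(a1)) > 0:
                raise InvalidModelError(
                    f"waiting-time CDF reaches 1 before age {a1} with g > 0")
            return math.inf
        return math.log(s0 / s1)

    bound = (lambda n, s=w.hazard_sup: s) if w.hazard_sup is not None else None
    # No budding renewal-kernel transform is attached: U_death(0,t) beta(t)
    # = h2 g (1-G)^(h0-1) has no closed transform in general (and these
    # hazards are meant for fission dynamics, where the fission module
    # works from the waiting-time transform directly).
    kernel_laplace = None

    return RateSpec(
        birth_hazard=beta,
        death_hazard=mu,
        progeny_split=(h0, h2),
        hazard_bound=bound,
        size_independent=True,
        total_cumhaz=total_cumhaz,
        event_age_sampler=lambda rng, a0: w.sample_remaining(rng, a0),
        kernel_laplace=kernel_laplace,
        waiting_time=w,
        name=f"fission[{w.name}, h2={h2}]",
    )


def sample_initial_ages(dist, count: int, seed=None) -> np.ndarray:
    """Draw i.i.d. founder ages from a named initial-age distribution.

    ``dist`` is one of
      * ``"reference-gamma"`` - Gamma(shape 4, rate 4): unit mean, sd 1/2;
      * ``("exponential", rate)`` - exponential with the given *rate*;
      * ``("point-mass", a0)`` - all founders share age ``a0``.
    ``seed`` may be an int, a SeedSequence, or a Generator.
    """
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count}")
    rng = np.random.default_rng(seed)
    if dist == "reference-gamma" or dist == ("reference-gamma",):
        return rng.gamma(REFERENCE_GAMMA_SHAPE, 1.0 / REFERENCE_GAMMA_RATE, size=count)
    if isinstance(dist, tuple) and len(dist) == 2:
        tag, par = dist
        if tag == "exponential":
            if par <= 0:
                raise InvalidModelError(f"exponential rate must be positive: {par}")
            return rng.exponential(1.0 / par, size=count)
        if tag == "point-mass":
            return np.full(count, float(par))
    raise ValueError(f"unknown initial-age distribution {dist!r}")


# ---------------------------------------------------------------------------
# built-in hazard constructors
# ---------------------------------------------------------------------------

def constant_rates(beta: float = 0.0, mu: float = 0.0,
                   progeny_split: Optional[Tuple[float, float]] = None) -> RateSpec:
    """Age- and size-independent rates (the Markovian special case)."""
    if beta < 0 or mu < 0:
        raise InvalidModelError("rates must be nonnegative")
    g = beta + mu

    def sampler(rng, a0, g=g):
        if g <= 0:
            return math.inf
        return a0 + rng.exponential(1.0 / g)

    return RateSpec(
        birth_hazard=lambda n, a: np.broadcast_to(float(beta), np.shape(a)).copy()
        if np.ndim(a) else beta,
        death_hazard=lambda n, a: np.broadcast_to(float(mu), np.shape(a)).copy()
        if np.ndim(a) else mu,
        progeny_split=progeny_split,
        hazard_bound=lambda n: g,
        size_independent=True,
        age_independent=True,
        death_cumhaz=lambda a0, a1: mu * (a1 - a0),
        total_cumhaz=lambda a0, a1: g * (a1 - a0),
        event_age_sampler=sampler,
        kernel_laplace=(lambda s: beta / (s + mu)),
        name=f"constant(beta={beta}, mu={mu})",
    )


def linear_death_rates(slope: float = 1.0, beta: float = 0.0) -> RateSpec:
    """Linear death hazard ``mu(a) = slope * a`` with constant birth rate."""
    if slope < 0 or beta < 0:
        raise InvalidModelError("rates must be nonnegative")

    def death_cumhaz(a0, a1):
        return 0.5 * slope * (a1 * a1 - a0 * a0)

    def total_cumhaz(a0, a1):
        return death_cumhaz(a0, a1) + beta * (a1 - a0)

    def sampler(rng, a0):
        # solve (slope/2) tau^2 + (slope*a0 + beta) tau = E for tau > 0
        e = rng.exponential()
        if slope == 0.0:
            return math.inf if beta <= 0 else a0 + e / beta
        c = slope * a0 + beta
        tau = (-c + math.sqrt(c * c + 2.0 * slope * e)) / slope
        return a0 + tau

    return RateSpec(
        birth_hazard=lambda n, a: np.full_like(np.asarray(a, float), beta)
        if np.ndim(a) else beta,
        death_hazard=lambda n, a: slope * np.asarray(a, dtype=float),
        size_independent=True,
        death_cumhaz=death_cumhaz,
        total_cumhaz=total_cumhaz,
        event_age_sampler=sampler,
        name=f"linear-death(slope={slope}, beta={beta})",
    )


def carrying_capacity_rates(beta0: float, K: float, mu: float = 0.0) -> RateSpec:
    """Age-independent budding model with a birth-rate carrying capacity.

    Per-individual birth rate ``beta0 (1 - n/K)`` clamped at zero; constant
    death rate ``mu``.  Size-dependent, so only the thinning and
    master-equation paths apply.
    """
    if K <= 0:
        raise InvalidModelError(f"carrying capacity must be positive, got {K}")
    if beta0 < 0 or mu < 0:
        raise InvalidModelError("rates must be nonnegative")

    def beta(n, a):
        b = carrying_capacity_birth(beta0, K, n)
        return np.full_like(np.asarray(a, float), b) if np.ndim(a) else b

    return RateSpec(
        birth_hazard=beta,
        death_hazard=lambda n, a: np.full_like(np.asarray(a, float), mu)
        if np.ndim(a) else mu,
        hazard_bound=lambda n: carrying_capacity_birth(beta0, K, n) + mu,
        size_independent=False,
        age_independent=True,
        name=f"carrying-capacity(beta0={beta0}, K={K}, mu={mu})",
    )
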