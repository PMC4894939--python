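"""Deterministic mean-field layer for budding birth-death processes.

For size-independent hazards the expected age density rho(a, t) obeys the
McKendrick-von Foerster transport equation

    d rho/dt + d rho/da = -mu(a) rho,      rho(0, t) = B(t),

where the fecundity B(t) = int beta(a) rho(a,t) da satisfies a Volterra
renewal equation solved here by product-trapezoidal marching (optionally
Richardson-extrapolated) or, for models with closed-form transforms, by
numerical Laplace inversion on a fixed-Talbot contour.

For age-independent (possibly size-dependent) rates the population-size
law rho_n(t) obeys an ordinary master equation; :func:`solve_master_equation`
integrates it with a high-order ODE method at tight tolerance and serves
as the independent oracle for the stochastic simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import integrate, stats

from ._laplace import talbot_inverse
from .rates import InvalidModelError, RateSpec

__all__ = [
    "UnsupportedModelError",
    "InitialAgeDensity",
    "GridField",
    "VolterraSolution",
    "solve_renewal_B",
    "solve_mvf",
    "laplace_renewal_B",
    "solve_master_equation",
]


class UnsupportedModelError(ValueError):
    """The requested solver does not apply to this model class."""


@dataclass
class InitialAgeDensity:
    """Initial age distribution ``g(a)``, with total mass = founder count.

    Either a point mass at ``a0`` (``kind='point'``) or an absolutely
    continuous density (``kind='density'``) given by ``pdf`` (normalised to
    one; ``mass`` scales it).  ``upper`` truncates quadrature where the
    tail mass is negligible.
    """

    kind: str
    mass: float = 1.0
    a0: float = 0.0
    pdf: Optional[Callable[[np.ndarray], np.ndarray]] = None
    upper: float = math.inf

    @classmethod
    def point(cls, a0: float = 0.0, mass: float = 1.0) -> "InitialAgeDensity":
        return cls(kind="point", a0=float(a0), mass=float(mass))

    @classmethod
    def from_distribution(cls, frozen, mass: float = 1.0,
                          tail_eps: float = 1e-10) -> "InitialAgeDensity":
        """Wrap a frozen scipy.stats distribution on [0, inf)."""
        return cls(kind="density", mass=float(mass), pdf=frozen.pdf,
                   upper=float(frozen.isf(tail_eps)))

    @classmethod
    def exponential(cls, rate: float = 1.0, mass: float = 1.0) -> "InitialAgeDensity":
        return cls.from_distribution(stats.expon(scale=1.0 / rate), mass=mass)

    @classmethod
    def reference_gamma(cls, mass: float = 1.0) -> "InitialAgeDensity":
        from .rates import REFERENCE_GAMMA_RATE, REFERENCE_GAMMA_SHAPE
        return cls.from_distribution(
            stats.gamma(REFERENCE_GAMMA_SHAPE, scale=1.0 / REFERENCE_GAMMA_RATE), mass=mass)

    def density(self, a) -> np.ndarray:
        """Mass-scaled density values (zero everywhere for a point mass)."""
        a = np.asarray(a, dtype=float)
        if self.kind == "point":
            return np.zeros_like(a)
        return self.mass * self.pdf(a)


@dataclass
class GridField:
    """A function of (age-or-TOB, time) sampled on a rectangular grid."""

    a: np.ndarray           # first axis (age or TOB)
    t: np.ndarray           # second axis (time)
    values: np.ndarray      # shape (len(a), len(t))
    convention: str = "age"  # {"age", "tob"}
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.shape != (len(self.a), len(self.t)):
            raise ValueError("values shape must be (len(a), len(t))")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (axis value, t, value) table."""
        aa, tt = np.meshgrid(self.a, self.t, indexing="ij")
        return pd.DataFrame({
            self.convention: aa.ravel(), "t": tt.ravel(),
            "value": self.values.ravel(),
        })


@dataclass
class VolterraSolution:
    """Fecundity B(t) on a uniform time grid, with quadrature metadata."""

    t: np.ndarray
    B: np.ndarray
    h: float
    meta: dict = field(default_factory=dict)

    def __call__(self, times) -> np.ndarray:
        """Linear interpolation onto arbitrary times in the solved range."""
        return np.interp(np.asarray(times, dtype=float), self.t, self.B)


# ---------------------------------------------------------------------------
# survival helpers
# ---------------------------------------------------------------------------

def _cumhaz_grid(rates: RateSpec, a0, a1, which: str) -> np.ndarray:
    """Vectorised cumulative hazard over age intervals [a0, a1] (elementwise)."""
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    hook = rates.death_cumhaz if which == "death" else rates.total_cumhaz
    if hook is not None:
        try:
            return np.asarray(hook(a0, a1), dtype=float)
        except Exception:
            pass  # hook not vectorised; fall through to the loop
    flat0, flat1 = np.broadcast_arrays(a0, a1)
    out = np.empty(flat0.shape, dtype=float)
    it = np.nditer(flat0, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        out[idx] = rates.cumulative_hazard(float(flat0[idx]), float(flat1[idx]), which)
    return out


def survival(rates: RateSpec, a0, a1, which: str = "death") -> np.ndarray:
    """Propagator ``exp(-int_{a0}^{a1} hazard)`` over age intervals."""
    return np.exp(-_cumhaz_grid(rates, a0, a1, which))


def _check_size_independent(rates: RateSpec):
    if not rates.size_independent:
        raise UnsupportedModelError(
            "mean-field solvers require size-independent hazards; "
            "size-dependent models obey a moment hierarchy with no closed "
            "mean-field reduction")


# ---------------------------------------------------------------------------
# renewal equation for B(t)
# ---------------------------------------------------------------------------

def _g0_source(g0: InitialAgeDensity, rates: RateSpec, t_grid: np.ndarray,
               n_quad: int = 4001) -> np.ndarray:
    """The inhomogeneous term int g(a) U(a, a+t) beta(a+t) da on t_grid."""
    if g0.kind == "point":
        a0 = g0.a0
        u = survival(rates, a0, a0 + t_grid, "death")
        return g0.mass * u * np.asarray(rates.beta(1, a0 + t_grid), dtype=float)
    upper = g0.upper
    if not np.isfinite(upper):
        raise InvalidModelError(
            "initial density needs a finite quadrature cutoff (set `upper`)")
    a = np.linspace(0.0, upper, n_quad)
    ga = g0.density(a)
    # matrix of survivals U(a, a+t) and hazards beta(a+t)
    A, T = np.meshgrid(a, t_grid, indexing="ij")
    U = survival(rates, A, A + T, "death")
    Beta = np.asarray(rates.beta(1, A + T), dtype=float)
    return integrate.simpson(ga[:, None] * U * Beta, x=a, axis=0)


def solve_renewal_B(g0: InitialAgeDensity, rates: RateSpec, t_grid: np.ndarray,
                    richardson: bool = False) -> VolterraSolution:
    """March the renewal equation for the fecundity B(t).

        B(t) = int_0^t B(t-a) U(0,a) beta(a) da
               + int_0^inf g(a) U(a, a+t) beta(a+t) da

    by the product-trapezoidal rule on a uniform grid (second order in the
    step).  ``richardson=True`` solves again at half the step and combines
    the two solutions, cancelling the leading error term.
    """
    _check_size_independent(rates)
    t_grid = np.asarray(t_grid, dtype=float)
    h = t_grid[1] - t_grid[0]
    if not np.allclose(np.diff(t_grid), h):
        raise ValueError("renewal marching requires a uniform time grid")
    if abs(t_grid[0]) > 1e-12:
        raise ValueError("renewal marching requires a grid starting at t = 0")

    if richardson:
        coarse = solve_renewal_B(g0, rates, t_grid, richardson=False)
        fine_t = np.linspace(t_grid[0], t_grid[-1], 2 * (len(t_grid) - 1) + 1)
        fine = solve_renewal_B(g0, rates, fine_t, richardson=False)
        B = (4.0 * fine.B[::2] - coarse.B) / 3.0
        meta = dict(coarse.meta, richardson=True)
        return VolterraSolution(t=t_grid, B=B, h=h, meta=meta)

    K = survival(rates, 0.0, t_grid, "death") * np.asarray(
        rates.beta(1, t_grid), dtype=float)
    F = _g0_source(g0, rates, t_grid)
    M = len(t_grid)
    B = np.empty(M)
    B[0] = F[0]
    denom = 1.0 - 0.5 * h * K[0]
    for i in range(1, M):
        acc = F[i] + 0.5 * h * K[i] * B[0]
        if i > 1:
            acc += h * np.dot(K[1:i], B[i - 1:0:-1])
        B[i] = acc / denom
    return VolterraSolution(
        t=t_grid, B=B, h=h,
        meta={"rule": "product-trapezoid", "model": rates.name,
              "g0": g0.kind, "g0_cutoff": g0.upper})


def solve_mvf(g0: InitialAgeDensity, rates: RateSpec, t_grid: np.ndarray,
              a_grid: np.ndarray, B: Optional[VolterraSolution] = None,
              march_step: Optional[float] = None) -> GridField:
    """Characteristics solution of the McKendrick-von Foerster equation.

    rho(a,t) = B(t-a) U(0,a) below the diagonal a = t (individuals born
    after the start) and g(a-t) U(a-t, a) above it (surviving founders).
    Point-mass initial conditions are not representable on a density grid;
    use the renewal solution directly for those.
    """
    _check_size_independent(rates)
    if g0.kind == "point":
        raise UnsupportedModelError(
            "point-mass initial age has no bounded density; "
            "use solve_renewal_B for the boundary flux instead")
    t_grid = np.asarray(t_grid, dtype=float)
    a_grid = np.asarray(a_grid, dtype=float)
    if B is None:
        t_max = float(t_grid[-1])
        if march_step is None:
            march_step = max(t_max, 1e-6) / 1500.0
        n_b = max(int(round(t_max / march_step)), 2)
        B = solve_renewal_B(g0, rates, np.linspace(0.0, t_max, n_b + 1),
                            richardson=True)
    A, T = np.meshgrid(a_grid, t_grid, indexing="ij")
    young = A <= T  # born after t = 0; the tie a = t takes this branch
    vals = np.where(
        young,
        B(np.clip(T - A, 0.0, None)) * survival(rates, 0.0, A, "death"),
        g0.density(np.clip(A - T, 0.0, None)) * survival(
            rates, np.clip(A - T, 0.0, None), A, "death"),
    )
    return GridField(a=a_grid, t=t_grid, values=vals, convention="age",
                     meta={"model": rates.name})


def laplace_renewal_B(g0: InitialAgeDensity, rates: RateSpec,
                      M: int = 32) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form-transform solution of the renewal equation.

        B~(s) = N~(s) / (1 - K~(s)),   K(t) = U(0,t) beta(t),

    inverted by the fixed-Talbot rule.  Requires the model to carry a
    closed-form kernel transform (all built-in constant-rate and
    waiting-time models do); the source term N~ is currently available in
    closed form for age-independent hazards, where U(a, a+t) beta(a+t)
    does not depend on the founder age a.  Heavier-tailed or bespoke
    models should use :func:`solve_renewal_B`.
    """
    _check_size_independent(rates)
    beta0 = float(rates.beta(1, 0.0))
    if beta0 == 0.0 and float(np.max(np.asarray(rates.beta(1, np.linspace(0, 50, 256))))) == 0.0:
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    if rates.kernel_laplace is None:
        raise UnsupportedModelError(
            "laplace path needs a closed-form kernel transform; "
            "use solve_renewal_B instead")
    if rates.age_independent:
        # U(a, a+t) beta(a+t) = exp(-mu t) beta for every founder age
        numerator = lambda s: g0.mass * rates.kernel_laplace(s)
    elif g0.kind == "point" and g0.a0 == 0.0:
        numerator = lambda s: g0.mass * rates.kernel_laplace(s)
    else:
        raise UnsupportedModelError(
            "closed-form source term unavailable for this initial condition; "
            "use solve_renewal_B instead")

    def Btil(s):
        return numerator(s) / (1.0 - rates.kernel_laplace(s))

    def B_of_t(t):
        return talbot_inverse(Btil, t, M=M)

    return B_of_t


# ---------------------------------------------------------------------------
# master equation (age-independent rates)
# ---------------------------------------------------------------------------

def solve_master_equation(rates: RateSpec, n_max: int, init, t_grid,
                          boundary_tol: float = 1e-6) -> pd.DataFrame:
    """Population-size law rho_n(t) for age-independent hazards.

    The forward master equation with per-individual rates beta_n, mu_n

        d rho_n / dt = -n (beta_n + mu_n) rho_n
                       + (n-1) beta_{n-1} rho_{n-1}
                       + (n+1) mu_{n+1} rho_{n+1}

    is integrated as a stiff-safe initial-value problem with tight
    tolerances (the generator is conservative, so the total probability is
    preserved to the integrator tolerance).  ``init`` is a mapping
    n -> probability or a vector over 0..n_max.  Raises if truncation at
    ``n_max`` accrues more than ``boundary_tol`` probability.
    """
    if not rates.age_independent:
        raise UnsupportedModelError(
            "the master equation applies to age-independent hazards only")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    p0 = np.zeros(n_max + 1)
    if isinstance(init, dict):
        for n, p in init.items():
            if n > n_max:
                raise ValueError(f"initial state n={n} exceeds n_max={n_max}")
            p0[n] = p
    else:
        init = np.asarray(init, dtype=float)
        p0[: len(init)] = init
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("initial distribution must sum to 1")

    ns = np.arange(n_max + 1)
    b = np.array([float(rates.beta(int(n), 0.0)) for n in ns])
    m = np.array([float(rates.mu(int(n), 0.0)) for n in ns])
    Q = np.zeros((n_max + 1, n_max + 1))
    Q[ns, ns] = -ns * (b + m)
    Q[ns[1:], ns[:-1]] = ns[:-1] * b[:-1]      # n-1 -> n birth
    Q[ns[:-1], ns[1:]] = ns[1:] * m[1:]        # n+1 -> n death

    order = np.argsort(t_grid)
    sol = integrate.solve_ivp(
        lambda _, p: Q @ p, (0.0, max(float(t_grid.max()), 1e-12)), p0,
        t_eval=t_grid[order], method="DOP853", rtol=1e-11, atol=1e-13)
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    P = np.empty((len(t_grid), n_max + 1))
    P[order] = np.clip(sol.y.T, 0.0, None)
    if P[:, -1].max() > boundary_tol and n_max > 0 and b[-1] * n_max > 0:
        raise InvalidModelError(
            f"probability mass {P[:, -1].max():.2e} at the truncation "
            f"boundary n_max={n_max}; increase n_max")
    return pd.DataFrame(P, index=pd.Index(t_grid, name="t"),
                        columns=pd.Index(ns, name="n"))
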