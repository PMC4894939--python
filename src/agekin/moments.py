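"""Factorial moments of the age structure and window count statistics.

For size-independent hazards the k-th factorial moment density

    X^(k)(a_1..a_k; t) = sum_n (n)_k rho_n^(k)(a_1..a_k; t)

obeys a generalized McKendrick-von Foerster transport equation

    dX/dt + sum_i dX/da_i + X sum_i mu(a_i) = 0,

whose characteristics solution propagates boundary and initial data with
products of survival propagators.  The boundary surface at a_k = 0 couples
order k to order k-1 through a Volterra-type equation

    X^(k)(a_{k-1}, 0; t) = X^(k-1)(a_{k-1}; t) beta(a_{k-1})
                           + int X^(k)(a_{k-1}, y; t) beta(y) dy,

which this module marches on a uniform lattice for k = 2 (k = 1 is the
classical McKendrick-von Foerster solution).  The raw moments Y^(k)
(plain n^k weights) follow by Stirling-number conversion, and the mean
and variance of the number of individuals in an age window [a, b] are
window integrals of Y^(1) and Y^(2).

Order k = 2 is the ceiling here: it already delivers age-window
variances, and each further order consumes the full solved surface of
the one below along a moving boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional

import numpy as np

from .meanfield import (GridField, InitialAgeDensity, UnsupportedModelError,
                        VolterraSolution, solve_renewal_B)
from .rates import RateSpec

__all__ = [
    "stirling_first",
    "stirling_second",
    "pochhammer",
    "factorial_to_raw",
    "raw_to_factorial",
    "MomentField",
    "solve_Xk",
    "yule_furry_moments",
    "yule_furry_window_mean_var",
    "window_moments_from_fields",
]


# ---------------------------------------------------------------------------
# Stirling machinery (exact integer arithmetic)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def stirling_first(k: int, l: int) -> int:
    """Signed Stirling number of the first kind s(k, l)."""
    if k < 0 or l < 0:
        raise ValueError("Stirling numbers need nonnegative arguments")
    if k == 0:
        return 1 if l == 0 else 0
    if l == 0 or l > k:
        return 0
    return stirling_first(k - 1, l - 1) - (k - 1) * stirling_first(k - 1, l)


@lru_cache(maxsize=None)
def stirling_second(k: int, l: int) -> int:
    """Stirling number of the second kind S(k, l)."""
    if k < 0 or l < 0:
        raise ValueError("Stirling numbers need nonnegative arguments")
    if k == 0:
        return 1 if l == 0 else 0
    if l == 0 or l > k:
        return 0
    return l * stirling_second(k - 1, l) + stirling_second(k - 1, l - 1)


def pochhammer(n: int, k: int) -> int:
    """Falling factorial (n)_k = n (n-1) ... (n-k+1), exact integer."""
    if k < 0:
        raise ValueError("order must be nonnegative")
    out = 1
    for i in range(k):
        out *= n - i
    return out


def factorial_to_raw(x_series):
    """Convert factorial moments [X0..Xk] to raw moments [Y0..Yk]."""
    x = list(x_series)
    return [sum(stirling_second(k, l) * x[l] for l in range(k + 1))
            for k in range(len(x))]


def raw_to_factorial(y_series):
    """Convert raw moments [Y0..Yk] to factorial moments [X0..Xk]."""
    y = list(y_series)
    return [sum(stirling_first(k, l) * y[l] for l in range(k + 1))
            for k in range(len(y))]


# ---------------------------------------------------------------------------
# moment fields
# ---------------------------------------------------------------------------

@dataclass
class MomentField:
    """Factorial-moment surface on an age grid (symmetric for k = 2).

    ``evaluate`` is a side-aware closure over the solved boundary data:
    it returns the moment at arbitrary (ages, t), taking the limit from
    the later-listed region on measure-zero region boundaries.
    """

    order: int
    a: np.ndarray
    t: np.ndarray
    values: np.ndarray  # (Na, Nt) for k=1; (Na, Na, Nt) for k=2
    convention: str = "age"
    evaluate: Optional[Callable] = None
    meta: dict = field(default_factory=dict)


def _death_cumhaz_fn(rates: RateSpec):
    """Vectorised integrated death hazard from age 0, as a callable L(a)."""
    hook = rates.death_cumhaz
    if hook is not None:
        return lambda a: np.asarray(hook(np.zeros_like(np.asarray(a, float)),
                                         np.asarray(a, float)), dtype=float)

    def slow(a):
        a = np.atleast_1d(np.asarray(a, dtype=float))
        return np.array([rates.cumulative_hazard(0.0, ai, "death") for ai in a])

    return slow


# ---------------------------------------------------------------------------
# k = 1: McKendrick-von Foerster via characteristics
# ---------------------------------------------------------------------------

def _x1_evaluator(g0: InitialAgeDensity, rates: RateSpec, B: VolterraSolution):
    L = _death_cumhaz_fn(rates)

    def X1(a, t):
        a = np.asarray(a, dtype=float)
        t = np.asarray(t, dtype=float)
        a, t = np.broadcast_arrays(a, t)
        La = L(a)
        young = a <= t  # ties resolved toward the boundary-fed branch
        with np.errstate(over="ignore"):
            born = B(np.clip(t - a, 0.0, None)) * np.exp(-La)
            old_age = np.clip(a - t, 0.0, None)
            founders = g0.density(old_age) * np.exp(-(La - L(old_age)))
        return np.where(young, born, founders)

    return X1


# ---------------------------------------------------------------------------
# k = 2: boundary-surface Volterra march
# ---------------------------------------------------------------------------

def _march_phi(g0, rates, B_lattice, h, n_t, n_y, g2=None):
    """March the boundary surface phi(y; tau) = X2(y, 0; tau).

    Returns ``(phi, phi_above)``: ``phi[i, j]`` samples the surface on the
    lattice tau_i = i h, y_j = j h, with the diagonal entry j = i holding
    the one-sided limit from y < tau (the branch fed by post-start
    births); ``phi_above[i]`` holds the limit from y > tau (the
    founder-fed branch).  The surface jumps across y = tau, so the
    boundary integral is integrated with trapezoidal weights split at the
    moving breakpoint y' = tau, keeping each smooth piece second order.

    Writing U(a1, a2) for the death-only propagator and m = min of the
    arguments, the characteristics solution gives, under the integral,

        X2(y, y'; tau) = phi(y - y'; tau - y') U(0, y') U(y - y', y)   (y' <= min(y, tau))
                       = phi(y' - y; tau - y)  U(0, y)  U(y' - y, y')  (y  <= y' , y <= tau)
                       = g2(y - tau, y' - tau) U(y - tau, y) U(y' - tau, y')   (tau <= min)

    and the boundary condition closes the march:

        phi(y; tau) = X1(y; tau) beta(y) + int_0^inf beta(y') X2(y, y'; tau) dy'.

    The y' = 0 endpoint of the integral contains the unknown itself
    (weight h/2), which is absorbed into the left-hand side.
    """
    y = h * np.arange(n_y + 1)
    L = _death_cumhaz_fn(rates)(y)                 # integrated death hazard
    eL = np.exp(-L)
    beta_y = np.asarray(rates.beta(1, y), dtype=float)
    c = beta_y * eL                                # beta(y') U(0, y')
    g1 = g0.density(y)
    beta0 = float(beta_y[0])
    denom = 1.0 - 0.5 * h * beta0

    if n_y < n_t:
        raise ValueError("the age lattice must reach at least the horizon")

    have_g2 = g2 is not None
    if have_g2:
        G2 = np.asarray(g2(y[:, None], y[None, :]), dtype=float)
        if not np.allclose(G2, G2.T, atol=1e-12):
            raise ValueError("initial two-point density must be symmetric")

    phi = np.zeros((n_t + 1, n_y + 1))
    phi_above = np.zeros(n_t + 1)
    # The tau -> 0+ limit of the boundary condition seeds the march: it is
    # NOT the initial two-point density (the surface jumps across y = tau
    # all the way down to tau = 0):
    #   phi(y; 0+) = g1(y) beta(y) + int g2(y, y') beta(y') dy'.
    row0 = g1 * beta_y
    if have_g2:
        w = np.full(n_y + 1, h)
        w[0] = w[-1] = 0.5 * h
        row0 = row0 + G2 @ (w * beta_y)
    phi[0] = row0
    phi_above[0] = row0[0]
    # psi[i, j] = phi[i, j] exp(+L[j]); propagator ratios become products
    expL = np.exp(L)
    psi = phi * expL[None, :]
    psi_above = phi_above.copy()   # psi_above[m] = phi_above[m] exp(L[m])

    # Corner limit of the diagonal from below (y -> tau-, then tau -> 0+):
    # the below-side stretch of the boundary integral shrinks to measure
    # zero, so the integrand endpoint at y' = 0 takes the row-0 value and
    # the corner is explicit:
    #   phi_below(0) = B(0) beta(0) + int_0^inf beta(z) phi(z; 0+) dz.
    dbelow = np.zeros(n_t + 1)
    s = 0.5 * h * c[0] * psi[0, 0]
    s += h * np.sum(c[1:n_y] * psi[0, 1:n_y]) + 0.5 * h * c[n_y] * psi[0, n_y]
    dbelow[0] = B_lattice[0] * beta0 + s

    for i in range(1, n_t + 1):
        # X1 on the lattice (ties at j = i resolved to the y < tau branch)
        j_all = np.arange(n_y + 1)
        x1 = np.empty(n_y + 1)
        below = j_all <= i
        x1[below] = B_lattice[i - j_all[below]] * eL[below]
        ja = j_all[~below]
        x1[~below] = g1[ja - i] * np.exp(-(L[ja] - L[ja - i]))

        # ---- diagonal-gather part: j' = 1..min(j, i), full weight h ----
        S = np.zeros(n_y + 1)
        for jp in range(1, i + 1):
            S[jp:] += (h * c[jp]) * psi[i - jp, : n_y + 1 - jp]

        # ---- j > i: correct j' = i from weight h to h/2 (left value);
        #      founder correlations continue the integrand beyond tau ----
        jj = np.arange(i, n_y + 1)
        S[jj] -= 0.5 * h * c[i] * psi[0, jj - i]
        if have_g2:
            # piece [i, n_y]: values beta[j'] G2[j-i, j'-i]
            #   * exp(-(L[j]-L[j-i])) * exp(-(L[j']-L[j'-i])); the factor
            #   exp(-L[j]) is applied globally below, so weight rows by
            #   exp(+L[j-i]).
            w = np.full(n_y + 1 - i, h)
            w[0] = w[-1] = 0.5 * h
            col = w * beta_y[i:] * np.exp(-(L[i:] - L[: n_y + 1 - i]))
            S[jj] += (G2[: n_y + 1 - i, :][:, : n_y + 1 - i] @ col) * expL[jj - i]

        # ---- j < i: row part j' in (j, n_y], with the split at j' = i ----
        for j in range(1, i):
            row = psi[i - j]
            vals = c[j + 1:] * row[1: n_y + 1 - j]
            s = h * np.sum(vals)
            s -= 0.5 * h * c[n_y] * row[n_y - j]            # outer endpoint
            s -= 0.5 * h * c[i] * row[i - j]                # left half at jump
            s += 0.5 * h * c[i] * psi_above[i - j]          # right half at jump
            S[j] += s

        new_phi = (x1 * beta_y + eL * S) / denom

        # ---- one-sided limit from y > tau at j = i ----
        jp = np.arange(1, i + 1)
        s_above = h * np.sum(c[jp] * psi_above[i - jp])
        s_above -= 0.5 * h * c[i] * psi_above[0]
        if have_g2:
            w = np.full(n_y + 1 - i, h)
            w[0] = w[-1] = 0.5 * h
            col = w * beta_y[i:] * np.exp(-(L[i:] - L[: n_y + 1 - i]))
            s_above += float(G2[0, : n_y + 1 - i] @ col)
        phi_above_i = (g1[0] * eL[i] * beta_y[i] + eL[i] * s_above) / denom

        # ---- one-sided limit from y < tau at j = i ----
        # Approaching the diagonal from below, the y' > tau part of the
        # boundary integral collapses onto the tau -> 0+ boundary row
        # (row 0); the integrand jumps at y' = tau between the corner
        # limit of the diagonal (left) and the corner of row 0 (right).
        s_below = h * np.sum(c[jp[:-1]] * dbelow[i - jp[:-1]]
                             * expL[i - jp[:-1]]) if i > 1 else 0.0
        s_below += 0.5 * h * c[i] * (dbelow[0] + psi[0, 0])
        s_below += h * np.sum(c[i + 1: n_y] * psi[0, 1: n_y - i])
        s_below += 0.5 * h * c[n_y] * psi[0, n_y - i]
        phi_below_i = (B_lattice[0] * eL[i] * beta_y[i]
                       + eL[i] * s_below) / denom
        dbelow[i] = phi_below_i
        new_phi[i] = phi_below_i

        # ---- row j = 0: the integrand is the current row itself ----
        vals = beta_y * new_phi
        s0 = h * np.sum(vals[1:i]) + 0.5 * h * vals[i]      # piece [0, i]
        s0 += 0.5 * h * beta_y[i] * phi_above_i             # piece [i, n_y]
        s0 += h * np.sum(vals[i + 1: n_y]) + 0.5 * h * vals[n_y]
        new_phi[0] = (x1[0] * beta0 + s0) / denom

        phi[i] = new_phi
        phi_above[i] = phi_above_i
        psi[i] = new_phi * expL
        psi_above[i] = phi_above_i * expL[i]

    # The stored corner (0, 0) follows the same convention as the rest of
    # the diagonal: the limit from y < tau (posterity-fed side), so that
    # evaluation at age = age = elapsed-time points is consistent.
    phi[0, 0] = dbelow[0]
    return phi, phi_above


def solve_Xk(k: int, rates: RateSpec, g0: InitialAgeDensity,
             t_grid, a_grid, g2: Optional[Callable] = None,
             march_step: Optional[float] = None,
             richardson: bool = True) -> MomentField:
    """Solve the generalized McKendrick-von Foerster equation for X^(k).

    ``g0`` is the founder age density (with total mass = founder count);
    ``g2`` the symmetric initial two-point factorial density (``None``
    means a single founder, for which X^(2)(.,.;0) = 0).  ``march_step``
    sets the internal uniform lattice; evaluation grids aligned with the
    lattice incur no interpolation error.  Only k in {1, 2} is supported:
    higher orders would consume the full k-1 surface along a moving
    boundary and are out of scope.
    """
    if k not in (1, 2):
        raise UnsupportedModelError("only moment orders k = 1, 2 are supported")
    if not rates.size_independent:
        raise UnsupportedModelError(
            "factorial-moment transport requires size-independent hazards; "
            "size-dependent models couple all orders in a full hierarchy")
    t_grid = np.asarray(t_grid, dtype=float)
    a_grid = np.asarray(a_grid, dtype=float)
    T = float(t_grid[-1])
    if march_step is None:
        march_step = max(T, 1e-6) / 600.0

    if k == 1:
        n_b = max(int(round(T / march_step)), 2)
        B = solve_renewal_B(g0, rates, np.linspace(0.0, T, n_b + 1),
                            richardson=True)
        X1 = _x1_evaluator(g0, rates, B)
        A, Tm = np.meshgrid(a_grid, t_grid, indexing="ij")
        vals = X1(A, Tm)
        return MomentField(order=1, a=a_grid, t=t_grid, values=vals,
                           evaluate=lambda a, t: X1(a, t),
                           meta={"model": rates.name, "march_step": B.h})

    # ---- k = 2 ----
    y_max = max(float(a_grid[-1]), T) + (g0.upper if np.isfinite(g0.upper)
                                         else 0.0) + 2.0

    h = march_step
    n_t0 = max(int(round(T / h)), 2)
    n_y0 = max(int(math.ceil(y_max / h)), n_t0)

    def run(refine):
        hr = h / refine
        n_t, n_y = refine * n_t0, refine * n_y0
        Bl = solve_renewal_B(g0, rates, hr * np.arange(n_t + 1),
                             richardson=True)
        phi, phi_above = _march_phi(g0, rates, Bl.B, hr, n_t, n_y, g2=g2)
        return phi, phi_above, Bl

    phi_c, phi_above_c, B_c = run(1)
    if richardson:
        phi_f, phi_above_f, _ = run(2)
        phi = (4.0 * phi_f[::2, ::2] - phi_c) / 3.0
        phi_above = (4.0 * phi_above_f[::2] - phi_above_c) / 3.0
        B_latt = B_c
    else:
        phi, phi_above, B_latt = phi_c, phi_above_c, B_c

    n_t = phi.shape[0] - 1
    n_y = phi.shape[1] - 1
    L_fn = _death_cumhaz_fn(rates)
    X1_eval = _x1_evaluator(g0, rates, B_latt)

    # The boundary surface jumps across y = tau, so interpolation must not
    # mix the two sides.  Interpolate in diagonal-aligned coordinates:
    # below the diagonal in (y, tau - y), above it in (tau, y - tau), with
    # the stored one-sided diagonal values closing each table.
    i_idx = np.arange(n_t + 1)
    above_tab = np.full((n_t + 1, n_y + 1), np.nan)
    above_tab[:, 0] = phi_above
    for q in range(1, n_y + 1):
        top = min(n_t, n_y - q)
        above_tab[: top + 1, q] = phi[i_idx[: top + 1], i_idx[: top + 1] + q]

    def phi_lookup(yv, tv):
        yv = np.clip(np.asarray(yv, dtype=float), 0.0, n_y * h)
        tv = np.clip(np.asarray(tv, dtype=float), 0.0, n_t * h)
        out = np.empty(np.broadcast(yv, tv).shape)
        yv, tv = np.broadcast_arrays(yv, tv)
        below = yv <= tv
        # below: value at lattice (i = j + m, j), smooth in (y, sigma)
        yb, sb = yv[below], (tv - yv)[below]
        fj, fm = yb / h, sb / h
        j0 = np.minimum(fj.astype(int), n_y - 1)
        m0 = np.minimum(fm.astype(int), n_t - 1)
        wj, wm = fj - j0, fm - m0
        idx = lambda m, j: phi[np.minimum(j + m, n_t), j]
        out[below] = ((1 - wm) * (1 - wj) * idx(m0, j0)
                      + (1 - wm) * wj * idx(m0, j0 + 1)
                      + wm * (1 - wj) * idx(m0 + 1, j0)
                      + wm * wj * idx(m0 + 1, j0 + 1))
        up = ~below
        if np.any(up):
            ta, wa = tv[up], (yv - tv)[up]
            fi, fq = ta / h, wa / h
            i0 = np.minimum(fi.astype(int), n_t - 1)
            q0 = np.minimum(fq.astype(int), n_y - 1)
            wi, wq = fi - i0, fq - q0
            g = lambda i, q: above_tab[i, np.minimum(q, n_y)]
            out[up] = ((1 - wi) * (1 - wq) * g(i0, q0)
                       + (1 - wi) * wq * g(i0, q0 + 1)
                       + wi * (1 - wq) * g(i0 + 1, q0)
                       + wi * wq * g(i0 + 1, q0 + 1))
            out[up] = np.nan_to_num(out[up], nan=0.0)
        return out

    def X2(a, b, t):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        t = np.asarray(t, dtype=float)
        a, b, t = np.broadcast_arrays(a, b, t)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        out = np.zeros(lo.shape)
        L_lo = L_fn(lo)
        L_hi = L_fn(hi)
        young = lo <= t  # boundary a = t resolved toward the later region
        if np.any(young):
            yv = (hi - lo)[young]
            tv = (t - lo)[young]
            out[young] = (phi_lookup(yv, tv)
                          * np.exp(-L_lo[young])
                          * np.exp(-(L_hi[young] - L_fn(yv))))
        oldm = ~young
        if np.any(oldm) and g2 is not None:
            a0 = (lo - t)[oldm]
            b0 = (hi - t)[oldm]
            out[oldm] = (np.asarray(g2(a0, b0), dtype=float)
                         * np.exp(-(L_lo[oldm] - L_fn(a0)))
                         * np.exp(-(L_hi[oldm] - L_fn(b0))))
        return out

    A1, A2, Tm = np.meshgrid(a_grid, a_grid, t_grid, indexing="ij")
    vals = X2(A1, A2, Tm)
    return MomentField(order=2, a=a_grid, t=t_grid, values=vals,
                       evaluate=X2,
                       meta={"model": rates.name, "march_step": h,
                             "richardson": richardson, "y_max": y_max,
                             "X1": X1_eval})


# ---------------------------------------------------------------------------
# Yule-Furry closed forms
# ---------------------------------------------------------------------------

def yule_furry_moments(lambda_rate: float, beta: float, a: float,
                       b_age: float, t: float):
    """Closed-form X^(1)(a; t) and X^(2)(a, b; t) for the pure-birth process.

    Single founder with age drawn from an exponential with *rate* lambda;
    constant birth rate beta; no death.  Region boundaries take the limit
    from the later-listed region (so a = t evaluates the post-start
    branch).
    """
    lam, b_ = lambda_rate, beta
    a, b_age = min(a, b_age), max(a, b_age)
    if t < a:
        x1 = lam * math.exp(-lam * (a - t))
    else:
        x1 = b_ * math.exp(b_ * (t - a))
    if t < a:
        x2 = 0.0
    elif t < b_age:  # a <= t < b
        x2 = lam * b_ * math.exp(-lam * (b_age - a)) * math.exp(
            (lam + b_) * (t - a))
    else:  # a <= b <= t
        x2 = 2.0 * b_ * b_ * math.exp(-b_ * (b_age - a)) * math.exp(
            2.0 * b_ * (t - a))
    return x1, x2


def yule_furry_window_mean_var(lambda_rate: float, beta: float, a: float,
                               b_age: float, t: float):
    """Mean and variance of the count with age in [a, b] at time t.

    Pure-birth process with constant rate beta started from one founder
    with exponential(rate lambda) age.  ``b_age`` may be ``inf``.
    """
    if not a < b_age:
        raise ValueError("window requires a < b")
    lam, b_ = lambda_rate, beta

    def e(x):  # exp with -inf -> 0
        return 0.0 if x == -math.inf else math.exp(x)

    if t < a:
        mean = e(lam * (t - a)) - e(lam * (t - b_age))
        var = (e(2 * lam * t) * (e(-lam * a) - e(-lam * b_age))
               * (-e(-lam * a) + e(-lam * b_age) + e(-lam * t)))
    elif t < b_age:  # a <= t < b
        mean = e(b_ * (t - a)) - e(lam * (t - b_age))
        var = ((e(b_ * (t - a)) - e(lam * (t - b_age)))
               * (e(b_ * (t - a)) + e(lam * (t - b_age)) - 1.0))
    else:  # a <= b <= t
        mean = e(b_ * (t - a)) - e(b_ * (t - b_age))
        var = (e(2 * b_ * t) * (e(-b_ * a) - e(-b_ * b_age))
               * (e(-b_ * a) - e(-b_ * b_age) + e(-b_ * t)))
    return mean, var


# ---------------------------------------------------------------------------
# window moments from solved fields
# ---------------------------------------------------------------------------

def window_moments_from_fields(field1: MomentField, field2: MomentField,
                               window, t: float, n_gauss: int = 64):
    """Mean and variance of the age-window count from moment fields.

    mean = int_W Y1;  var = int_{W^2} Y2 - mean^2 with the raw second
    moment Y2 = X2 + (diagonal) X1, so in integral form

        var = int_{W^2} X2 + mean - mean^2.

    Uses the fields' side-aware evaluators with Gauss-Legendre panels
    split at the age-equals-elapsed-time line a = t, across which the
    moment surfaces jump.  A window reaching past the solved lattice
    triggers a truncation warning.
    """
    a, b = window
    if not a < b:
        if a == b:
            return 0.0, 0.0
        raise ValueError("window must satisfy a < b")
    if field1.evaluate is None or field2.evaluate is None:
        raise ValueError("fields must carry evaluators (as built by solve_Xk)")
    b_eff = b
    lattice_top = field2.meta.get("y_max", math.inf) if field2.meta else math.inf
    if math.isinf(b):
        # beyond max(founder support + t, lattice) the moments vanish
        b_eff = lattice_top
    elif b > lattice_top:
        warnings.warn(f"window edge {b} beyond solved range {lattice_top}; "
                      "truncating", stacklevel=2)
        b_eff = lattice_top

    nodes, wts = np.polynomial.legendre.leggauss(n_gauss)

    def panels(lo, hi):
        cuts = sorted({lo, hi} | ({t} if lo < t < hi else set()))
        return list(zip(cuts[:-1], cuts[1:]))

    def gauss1d(f, lo, hi):
        total = 0.0
        for p_lo, p_hi in panels(lo, hi):
            mid, half = 0.5 * (p_lo + p_hi), 0.5 * (p_hi - p_lo)
            total += half * np.sum(wts * f(mid + half * nodes))
        return total

    mean = gauss1d(lambda x: field1.evaluate(x, np.full_like(x, t)), a, b_eff)

    total2 = 0.0
    for p1 in panels(a, b_eff):
        for p2 in panels(a, b_eff):
            m1, h1 = 0.5 * (p1[0] + p1[1]), 0.5 * (p1[1] - p1[0])
            m2, h2_ = 0.5 * (p2[0] + p2[1]), 0.5 * (p2[1] - p2[0])
            xx = m1 + h1 * nodes
            yy = m2 + h2_ * nodes
            XX, YY = np.meshgrid(xx, yy, indexing="ij")
            vals = field2.evaluate(XX, YY, np.full_like(XX, t))
            total2 += h1 * h2_ * float(wts @ vals @ wts)

    var = total2 + mean - mean * mean
    return mean, var
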