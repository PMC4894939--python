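import math
import warnings

import numpy as np
import pytest

from agekin.fission import (bellman_harris_mean, bellman_harris_mean_laplace,
                            fission_fields, fission_total, gamma_fission_B,
                            gamma_fission_T, mvf_reduction_check,
                            solve_fission_B)
from agekin.meanfield import InitialAgeDensity, UnsupportedModelError
from agekin.rates import (constant_rates, exponential_waiting, gamma_waiting,
                          hazards_from_waiting_time)


GRID = np.linspace(0.0, 3.0, 3001)
REPORT = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])


def gamma_T_talbot(alpha, t):
    """Independent oracle: direct numerical inversion of the transform."""
    from agekin._laplace import talbot_inverse
    a = float(alpha)

    def F(s):
        sa = (s + a) ** a
        return (sa - a ** a) / (s * (sa - 2.0 * a ** a))

    return np.array([talbot_inverse(F, ti) for ti in np.atleast_1d(t)])


class TestVolterraRoute:
    def test_no_fission_no_flux(self):
        r = constant_rates(mu=1.0, progeny_split=(1.0, 0.0))
        sol = solve_fission_B(r, GRID)
        assert np.allclose(sol.B, 0.0)

    def test_exponential_growth_law(self):
        r = hazards_from_waiting_time(exponential_waiting(1.0), 1.0)
        B = solve_fission_B(r, GRID)
        T = fission_total(B, r)
        assert np.max(np.abs(T - np.exp(GRID)) / np.exp(GRID)) < 1e-6

    def test_critical_process_total_is_one(self):
        r = hazards_from_waiting_time(exponential_waiting(1.0), 0.5)
        B = solve_fission_B(r, GRID)
        T = fission_total(B, r)
        assert np.max(np.abs(T - 1.0)) < 1e-6


class TestFields:
    def test_doublets_decay_with_squared_propagator(self):
        w = gamma_waiting(2.0)
        r = hazards_from_waiting_time(w, 1.0)
        B = solve_fission_B(r, GRID)
        fs = fission_fields(B, r, x_grid=np.array([0.5, 1.0]),
                            t_grid=np.array([1.5, 2.0]))
        for i, x in enumerate((0.5, 1.0)):
            for j, t in enumerate((1.5, 2.0)):
                u = float(w.sf(t - x))
                assert fs.Y.values[i, j] == pytest.approx(B(x) * u * u,
                                                          rel=1e-10)

    def test_newborn_pair_has_no_singlet_weight(self):
        r = hazards_from_waiting_time(gamma_waiting(2.0), 1.0)
        B = solve_fission_B(r, GRID)
        fs = fission_fields(B, r, x_grid=np.array([1.0]),
                            t_grid=np.array([1.0]))
        assert fs.X.values[0, 0] == 0.0  # X(t, t) = 0

    def test_frozen_when_hazards_vanish(self):
        r = constant_rates(progeny_split=(0.5, 0.5))  # gamma = 0
        grid = np.linspace(0, 2, 201)
        B = solve_fission_B(r, grid,
                            X0=InitialAgeDensity.reference_gamma(mass=1.0),
                            Y0=InitialAgeDensity.reference_gamma(mass=1.0))
        fs = fission_fields(B, r, x_grid=np.array([-1.0, -0.5]),
                            t_grid=np.array([0.0, 2.0]),
                            X0=InitialAgeDensity.reference_gamma(mass=1.0),
                            Y0=InitialAgeDensity.reference_gamma(mass=1.0))
        assert np.allclose(fs.X.values[:, 0], fs.X.values[:, 1])
        assert np.allclose(fs.Y.values[:, 0], fs.Y.values[:, 1])

    def test_total_is_singlets_plus_twice_doublets(self):
        r = hazards_from_waiting_time(gamma_waiting(10.0), 1.0)
        B = solve_fission_B(r, GRID)
        x = np.linspace(0.0, 3.0, 61)
        fs = fission_fields(B, r, x, np.array([1.0, 2.0, 3.0]))
        assert np.max(np.abs(fs.T.values - fs.X.values
                             - 2 * fs.Y.values)) < 1e-10

    def test_transport_reduction_residual(self):
        r = hazards_from_waiting_time(exponential_waiting(1.0), 1.0)
        h = 2e-4
        grid = np.arange(0.0, 1.5 + h / 2, h)
        B = solve_fission_B(r, grid)
        fs = fission_fields(B, r, np.linspace(0.1, 1.4, 14), grid)
        rep = mvf_reduction_check(fs, r)
        assert rep["pde_residual_max"] < 1e-6

    def test_pure_death_exact_transport(self):
        r = constant_rates(mu=0.8, progeny_split=(1.0, 0.0))
        grid = np.linspace(0, 2, 2001)
        X0 = InitialAgeDensity.reference_gamma()
        B = solve_fission_B(r, grid, X0=X0)
        fs = fission_fields(B, r, np.array([-1.0, -0.2]), grid, X0=X0)
        for i, x in enumerate((-1.0, -0.2)):
            expect = X0.density(np.array([-x]))[0] * np.exp(-0.8 * grid)
            assert np.allclose(fs.T.values[i], expect, rtol=1e-12)


class TestBellmanHarris:
    def test_exponential_growth(self):
        T = bellman_harris_mean(exponential_waiting(1.0), 1.0, GRID)
        assert np.max(np.abs(T - np.exp(GRID))) / math.e ** 3 < 1e-6

    def test_critical_means_stay_at_one(self):
        for w in (exponential_waiting(1.0), gamma_waiting(2.0)):
            T = bellman_harris_mean(w, 0.5, GRID)
            assert np.max(np.abs(T - 1.0)) < 1e-6

    def test_starts_at_one(self):
        T = bellman_harris_mean(gamma_waiting(3.0), 1.0, GRID)
        assert T[0] == 1.0

    def test_pure_death_is_survival_function(self):
        w = gamma_waiting(2.0)
        T = bellman_harris_mean_laplace(w, 0.0)
        t = np.linspace(0.2, 3.0, 15)
        assert np.allclose(T(t), w.sf(t), atol=1e-8)

    @pytest.mark.parametrize("w", [exponential_waiting(1.0),
                                   gamma_waiting(2.0), gamma_waiting(10.0)])
    def test_equivalence_of_renewal_and_laplace_routes(self, w):
        """Kinetic (renewal) and generating-function (Laplace) means agree."""
        T_renewal = np.interp(REPORT, GRID,
                              bellman_harris_mean(w, 1.0, GRID))
        T_laplace = bellman_harris_mean_laplace(w, 1.0)(REPORT)
        assert np.max(np.abs(T_renewal - T_laplace) / T_laplace) < 1e-4


class TestGammaClosedForms:
    def test_markovian_case_is_pure_exponential(self):
        t = np.linspace(0.0, 3.0, 13)
        assert np.allclose(gamma_fission_T(1.0, t), np.exp(t), rtol=1e-10)
        assert np.allclose(gamma_fission_B(1.0, t), np.exp(t), rtol=1e-10)

    @pytest.mark.parametrize("alpha", [2.5, 3.0, 4.7, 10.0])
    def test_against_numerical_inversion(self, alpha):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = gamma_fission_T(alpha, REPORT)
        ref = gamma_T_talbot(alpha, REPORT)
        assert np.max(np.abs(got - ref) / ref) < 1e-6

    def test_starts_from_single_founder(self):
        for alpha in (1.0, 2.0, 3.0, 10.0, 100.0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert gamma_fission_T(alpha, 0.0) == pytest.approx(1.0,
                                                                    abs=1e-8)

    def test_even_integer_alpha_warns_and_falls_back(self):
        with pytest.warns(UserWarning, match="branch cut"):
            v = gamma_fission_T(2.0, 1.0)
        assert v == pytest.approx(gamma_T_talbot(2.0, 1.0)[0], rel=1e-10)

    def test_large_dispersion_against_renewal_march(self):
        """At alpha = 100 the residue evaluation must track the
        independent time-domain renewal solution (near-synchronous
        divisions; resonant transform poles)."""
        w = gamma_waiting(100.0)
        grid = np.linspace(0, 3, 6001)
        T_march = bellman_harris_mean(w, 1.0, grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for t in (1.0, 2.0, 3.0):
                v = gamma_fission_T(100.0, t)
                ref = T_march[np.searchsorted(grid, t)]
                assert v == pytest.approx(ref, rel=1e-8)

    def test_slower_branching_means_smaller_population(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for t in (1.0, 2.0, 3.0):
                vals = [gamma_fission_T(a, t) for a in (1.0, 2.0, 10.0, 100.0)]
                assert all(x >= y - 1e-10 for x, y in zip(vals, vals[1:]))

    def test_between_discrete_doubling_and_compounding(self):
        # lower envelope: left-continuous Galton-Watson staircase
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for t in (1.0, 2.0, 3.0):
                lower = 2.0 ** (math.ceil(t) - 1)
                for a in (1.0, 2.0, 10.0, 100.0):
                    v = gamma_fission_T(a, t)
                    assert lower - 1e-9 <= v <= math.exp(t) + 1e-9


class TestFourWayAgreement:
    @pytest.mark.parametrize("alpha", [1.0, 2.0, 2.5, 10.0])
    def test_all_solution_routes_agree(self, alpha):
        w = gamma_waiting(alpha)
        r = hazards_from_waiting_time(w, 1.0)
        B = solve_fission_B(r, GRID)
        T_vol = np.interp(REPORT, GRID, fission_total(B, r))
        T_ren = np.interp(REPORT, GRID, bellman_harris_mean(w, 1.0, GRID))
        T_lap = bellman_harris_mean_laplace(w, 1.0)(REPORT)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            T_con = np.atleast_1d(gamma_fission_T(alpha, REPORT))
        stack = np.vstack([T_vol, T_ren, T_lap, T_con])
        rel = (stack.max(0) - stack.min(0)) / stack.mean(0)
        assert rel.max() < 1e-4

    def test_size_dependent_rejected(self):
        from agekin.rates import carrying_capacity_rates, RateSpec
        base = carrying_capacity_rates(1.0, 5.0)
        r = RateSpec(birth_hazard=base.birth_hazard,
                     death_hazard=base.death_hazard,
                     progeny_split=(0.0, 1.0), size_independent=False,
                     age_independent=True)
        with pytest.raises(UnsupportedModelError):
            solve_fission_B(r, GRID)
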