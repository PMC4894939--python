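import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from agekin.meanfield import solve_master_equation
from agekin.rates import (RateSpec, carrying_capacity_rates, constant_rates,
                          exponential_waiting, gamma_waiting,
                          hazards_from_waiting_time, linear_death_rates)
from agekin.simulate import (BoundViolationError, PopulationState,
                             estimate_marginal_age_density,
                             estimate_number_density, estimate_tob_density,
                             estimate_window_count_moments, run_ensemble,
                             simulate_budding, simulate_fission_death,
                             simulate_spatial)


def events_equal(e1, e2):
    return len(e1) == len(e2) and all(
        a.time == b.time and a.kind == b.kind and a.parent_tob == b.parent_tob
        and a.child_tobs == b.child_tobs and a.n_before == b.n_before
        for a, b in zip(e1, e2))


class TestBudding:
    def test_no_hazards_no_events(self):
        init = PopulationState.from_ages(np.linspace(0, 3, 7))
        traj = simulate_budding(constant_rates(), init, 5.0, 0, [1.0, 5.0])
        assert traj.events == []
        for s in (1.0, 5.0):
            assert len(traj.snapshots[s].singlet_tobs) == 7

    def test_linear_death_survival_probability(self):
        r = linear_death_rates(slope=1.0)
        init = PopulationState.from_ages([0.0])
        R = 40_000
        ens = run_ensemble("budding", r, init, R, 1.0, [1.0], seed=5)
        p_hat = float(estimate_number_density(ens, 1.0).get(1, 0.0))
        p = math.exp(-0.5)
        assert abs(p_hat - p) < 3 * math.sqrt(p * (1 - p) / R)

    def test_pure_birth_mean_population(self):
        r = constant_rates(beta=1.0)
        init = PopulationState.from_ages([0.0])
        R = 40_000
        ens = run_ensemble("budding", r, init, R, 1.0, [1.0], seed=9)
        mean, var = estimate_window_count_moments(ens, 1.0, (0.0, np.inf))
        assert abs(mean - math.e) < 3 * math.sqrt(var / R)

    def test_bitwise_reproducibility(self):
        r = constant_rates(beta=1.0, mu=0.3)
        init = PopulationState.from_ages([0.5, 0.0])
        t1 = simulate_budding(r, init, 2.0, 1234, [2.0])
        t2 = simulate_budding(r, init, 2.0, 1234, [2.0])
        assert events_equal(t1.events, t2.events)
        assert np.array_equal(t1.snapshots[2.0].singlet_tobs,
                              t2.snapshots[2.0].singlet_tobs)

    def test_thinning_requires_bound(self):
        r = RateSpec(birth_hazard=lambda n, a: np.zeros_like(a),
                     death_hazard=lambda n, a: np.asarray(a, float),
                     size_independent=False)
        with pytest.raises(Exception):
            simulate_budding(r, PopulationState.from_ages([0.0]), 1.0, 0,
                             method="thinning")

    def test_bound_violation_raised(self):
        r = RateSpec(birth_hazard=lambda n, a: np.full_like(
            np.asarray(a, float), 2.0),
            death_hazard=lambda n, a: np.zeros_like(np.asarray(a, float)),
            hazard_bound=lambda n: 1.0, size_independent=False)
        with pytest.raises(BoundViolationError):
            simulate_budding(r, PopulationState.from_ages([0.0]), 5.0, 0,
                             method="thinning")


class TestThinningVersusInversion:
    def test_first_event_times_same_law(self):
        """Thinning and exact inversion sample the same event-time law."""
        r = hazards_from_waiting_time(gamma_waiting(2.0), h2=0.0)
        init = PopulationState.from_ages([0.0])

        def first_times(method, n, base):
            out = np.empty(n)
            for i in range(n):
                traj = simulate_fission_death(r, init, 50.0, (base, i),
                                              method=method)
                out[i] = traj.events[0].time
            return out

        x_inv = first_times("inversion", 50_000, 101)
        x_thin = first_times("thinning", 50_000, 202)
        assert ks_2samp(x_inv, x_thin).pvalue > 0.01

    def test_carrying_capacity_matches_master_equation(self):
        r = carrying_capacity_rates(1.0, 5.0)
        init = PopulationState.from_ages([0.0])
        R = 20_000
        ens = run_ensemble("budding", r, init, R, 5.0, [5.0], seed=31,
                           method="thinning")
        emp = estimate_number_density(ens, 5.0)
        ode = solve_master_equation(r, 8, {1: 1.0}, [5.0]).loc[5.0]
        tv = 0.5 * sum(abs(emp.get(n, 0.0) - ode.get(n, 0.0))
                       for n in range(9))
        assert tv < 4 * 5 / math.sqrt(R)

    def test_fixed_step_converges_to_exact(self):
        # the biased fixed-step scheme approaches the exact mean as dt -> 0
        r = constant_rates(beta=1.0)
        init = PopulationState.from_ages([0.0])
        means = []
        for dt in (0.2, 0.02):
            tot = 0
            for i in range(4000):
                traj = simulate_budding(r, init, 1.0, (77, i, int(dt * 1000)),
                                        [1.0], method="fixed-step", dt=dt)
                tot += len(traj.snapshots[1.0].singlet_tobs)
            means.append(tot / 4000)
        assert abs(means[1] - math.e) < abs(means[0] - math.e)
        assert abs(means[1] - math.e) < 0.15


class TestFission:
    def test_pure_death_pair_founder_structure(self):
        r = hazards_from_waiting_time(exponential_waiting(1.0), h2=0.0)
        init = PopulationState(t=0.0, singlet_tobs=np.empty(0),
                               doublet_tobs=np.array([0.0]))
        traj = simulate_fission_death(r, init, 100.0, 8)
        kinds = [e.kind for e in traj.events]
        assert kinds == ["death", "death"]
        assert traj.events[0].n_before == 2
        assert traj.events[1].n_before == 1

    def test_every_event_changes_total_by_one(self):
        r = hazards_from_waiting_time(gamma_waiting(3.0), h2=0.6)
        init = PopulationState.from_ages([0.0, 0.2])
        traj = simulate_fission_death(r, init, 4.0, 12)
        n = 2
        for e in traj.events:
            assert e.n_before == n
            n += 1 if e.kind == "fission" else -1
        assert n >= 0

    def test_exponential_pure_fission_growth(self):
        r = hazards_from_waiting_time(exponential_waiting(1.0), h2=1.0)
        init = PopulationState.from_ages([0.0])
        R = 30_000
        ens = run_ensemble("fission", r, init, R, 1.0, [1.0], seed=21)
        mean, var = estimate_window_count_moments(ens, 1.0, (0.0, np.inf))
        assert abs(mean - math.e) < 3 * math.sqrt(var / R)

    def test_critical_process_constant_mean(self):
        r = hazards_from_waiting_time(exponential_waiting(1.0), h2=0.5)
        init = PopulationState.from_ages([0.0])
        R = 30_000
        ens = run_ensemble("fission", r, init, R, 2.0, [1.0, 2.0], seed=22)
        for t in (1.0, 2.0):
            mean, var = estimate_window_count_moments(ens, t, (0.0, np.inf))
            assert abs(mean - 1.0) < 3 * math.sqrt(var / R)

    def test_reproducible(self):
        r = hazards_from_waiting_time(gamma_waiting(2.0), h2=0.7)
        init = PopulationState.from_ages([0.0])
        t1 = simulate_fission_death(r, init, 3.0, 5)
        t2 = simulate_fission_death(r, init, 3.0, 5)
        assert events_equal(t1.events, t2.events)


class TestSpatial:
    @staticmethod
    def spatial_rates(beta, mu, bound):
        return RateSpec(birth_hazard=lambda n, a, q: beta,
                        death_hazard=lambda n, a, q: mu,
                        hazard_bound=lambda n: bound,
                        size_independent=False)

    def test_pure_diffusion_variance(self):
        r = self.spatial_rates(0.0, 0.0, 0.0)
        init = PopulationState.from_ages([0.0], positions=[0.0])
        R = 20_000
        qs = np.empty(R)
        for i in range(R):
            traj = simulate_spatial(r, 1.0, init, 2.0, (55, i), [2.0])
            qs[i] = traj.snapshots[2.0].positions[0]
        # Var(q) = 2 D t
        assert abs(qs.var() - 4.0) < 3 * 4.0 * math.sqrt(2.0 / R)
        assert abs(qs.mean()) < 3 * 2.0 / math.sqrt(R)

    def test_zero_diffusivity_reduces_to_budding(self):
        rs = self.spatial_rates(1.0, 0.2, 1.2)
        rb = constant_rates(beta=1.0, mu=0.2)
        rb = RateSpec(birth_hazard=rb.birth_hazard,
                      death_hazard=rb.death_hazard,
                      hazard_bound=lambda n: 1.2, size_independent=False)
        init_s = PopulationState.from_ages([0.0], positions=[0.0])
        init_b = PopulationState.from_ages([0.0])
        ts = simulate_spatial(rs, 0.0, init_s, 2.0, 404, [2.0])
        tb = simulate_budding(rb, init_b, 2.0, 404, [2.0], method="thinning")
        assert events_equal(ts.events, tb.events)

    def test_motion_does_not_alter_size_statistics(self):
        r = self.spatial_rates(1.0, 0.0, 1.0)
        init = PopulationState.from_ages([0.0], positions=[0.0])
        R = 10_000
        tot = np.empty(R)
        for i in range(R):
            traj = simulate_spatial(r, 1.0, init, 1.0, (66, i), [1.0])
            tot[i] = traj.snapshots[1.0].size
        assert abs(tot.mean() - math.e) < 3 * tot.std(ddof=1) / math.sqrt(R)

    def test_negative_diffusivity_rejected(self):
        r = self.spatial_rates(0.0, 0.0, 0.0)
        init = PopulationState.from_ages([0.0], positions=[0.0])
        with pytest.raises(Exception):
            simulate_spatial(r, -1.0, init, 1.0, 0)


@pytest.fixture(scope="module")
def frozen_ensemble():
    # no events: 10 founders with fixed ages
    r = constant_rates()
    init = PopulationState.from_ages(np.linspace(0.1, 2.0, 10))
    return run_ensemble("budding", r, init, 200, 1.0, [1.0], seed=77)


class TestEstimators:

    def test_number_density_point_mass(self, frozen_ensemble):
        nd = estimate_number_density(frozen_ensemble, 1.0)
        assert nd.loc[10] == 1.0
        assert nd.sum() == pytest.approx(1.0)

    def test_window_count_moments_degenerate(self, frozen_ensemble):
        mean, var = estimate_window_count_moments(frozen_ensemble, 1.0,
                                                  (0.0, np.inf))
        assert mean == 10.0 and var == 0.0

    def test_marginal_density_normalisation(self, frozen_ensemble):
        est = estimate_marginal_age_density(frozen_ensemble, 1.0, "all", 1,
                                            bins=np.linspace(0, 4, 17))
        total = np.sum(est.values * np.diff(est.bins))
        assert total == pytest.approx(est.weight)
        assert est.weight == 1.0

    def test_pair_density_symmetry(self, frozen_ensemble):
        est = estimate_marginal_age_density(frozen_ensemble, 1.0, "all", 2,
                                            bins=np.linspace(0, 4, 9))
        assert np.allclose(est.values, est.values.T)

    def test_unrealised_filter_flags_empty(self, frozen_ensemble):
        est = estimate_marginal_age_density(frozen_ensemble, 1.0, 3, 1,
                                            bins=np.linspace(0, 4, 5))
        assert est.empty and est.weight == 0.0

    def test_tob_density_counts_pairs_once(self):
        r = constant_rates(progeny_split=(0.5, 0.5))
        init = PopulationState(t=0.0, singlet_tobs=np.array([-1.0]),
                               doublet_tobs=np.array([-0.5]))
        ens = run_ensemble("fission", r, init, 50, 1.0, [1.0], seed=3)
        sing = estimate_tob_density(ens, 1.0, "singlet",
                                    np.linspace(-2, 1, 13))
        dbl = estimate_tob_density(ens, 1.0, "doublet",
                                   np.linspace(-2, 1, 13))
        width = 0.25
        assert np.sum(sing.values) * width == pytest.approx(1.0)
        assert np.sum(dbl.values) * width == pytest.approx(1.0)
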