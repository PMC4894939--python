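# agekin

Exact stochastic simulation and kinetic mean-field theory of
age-structured populations undergoing budding birth, death, and binary
fission.

## Who this is for

Quantitative biologists and applied mathematicians modelling populations
whose event rates depend on individual age — cell cultures with
non-exponential cycle times, demographic cohorts, lymphocyte expansion —
who need *both* exact trajectory-level stochastic sampling and the
deterministic theory (means, age-resolved variances) that the
trajectories should obey, in one consistent framework.

## The model

The state of a population is its **age chart**: the times of birth (TOB)
`b = t − a` of every living individual. A model is a pair of
per-individual hazards, the birth/fission rate `β_n(a)` and the death
rate `μ_n(a)`, possibly depending on population size `n` (e.g. a carrying
capacity `β_n = β₀(1 − n/K)`). Core quantities:

* the **propagator** `U(b; t0, t1) = exp(−∫ h(s − b) ds)`, the no-event
  probability over an interval, for `h = μ` (survival) or
  `h = γ = β + μ`;
* the mean age density `ρ(a, t)`, which for size-independent hazards
  obeys the McKendrick–von Foerster transport equation
  `∂ρ/∂t + ∂ρ/∂a = −μρ` with renewal boundary
  `ρ(0, t) = B(t) = ∫ β ρ da` (a Volterra equation for `B`);
* the **factorial moments** `X^(k)(a_1..a_k; t) = Σ_n (n)_k ρ_n^(k)`,
  which satisfy the same transport operator and deliver age-window
  variances via `Var(Y_[a,b]) = ∬ X^(2) + mean − mean²`;
* for binary fission (parent replaced by two age-0 twins with
  probability `h₂`, dies with `h₀ = 1 − h₂`), singlet/doublet mean densities
  driven by the pair-creation flux `B(t)`, whose total mean equals the
  Bellman–Harris branching-process mean with Laplace transform
  `T̃(s) = (1 − g̃)/(s(1 − 2h₂ g̃))` for inter-event density `g`.

The simulators are statistically exact (per-individual clock inversion
for size-independent hazards; Ogata thinning against a declared hazard
bound otherwise), and every deterministic result is cross-checked against
them and against independent solution routes. See `docs/methods.md`.

## Worked example

Mean population of a fission-only process whose cycle times are Gamma
distributed with unit mean and variance 1/10 (α = 10), by two independent
deterministic routes and by simulation:

```python
import numpy as np
from agekin import (gamma_waiting, hazards_from_waiting_time,
                    solve_fission_B, fission_total, gamma_fission_T,
                    PopulationState, run_ensemble,
                    estimate_window_count_moments)

grid = np.linspace(0.0, 3.0, 3001)
rates = hazards_from_waiting_time(gamma_waiting(10.0), h2=1.0)
B = solve_fission_B(rates, grid)          # Volterra march for the pair flux
T = fission_total(B, rates)               # total mean population
for t in (1.0, 2.0, 3.0):
    i = np.searchsorted(grid, t)
    print(f"t={t:.0f}: volterra T={T[i]:.4f}  "
          f"closed form T={gamma_fission_T(10.0, t):.4f}")

ens = run_ensemble("fission", rates, PopulationState.from_ages([0.0]),
                   R=20_000, t_final=3.0, snapshot_times=[3.0], seed=7)
mean, var = estimate_window_count_moments(ens, 3.0, (0.0, np.inf))
print(f"simulated mean at t=3: {mean:.3f} +/- {np.sqrt(var/20_000):.3f}")
```

Output:

```
t=1: volterra T=1.5490  closed form T=1.5490
t=2: volterra T=3.1422  closed form T=3.1422
t=3: volterra T=6.4317  closed form T=6.4317
simulated mean at t=3: 6.439 +/- 0.014
```

The two deterministic routes (renewal quadrature and the residue/
branch-cut evaluation of the inverse Laplace transform) agree to the
printed precision, and the simulated mean sits within one standard error
of the theory. With exponential cycle times (α = 1) all routes give
`T(t) = e^t`; larger α synchronises divisions and lowers the mean toward
the discrete Galton–Watson doubling staircase.

A command-line interface mirrors the library:

```sh
agekin fission --alpha 1 --alpha 10 --t-final 3 --out out/
agekin fixtures carrying-capacity --scale desk   # ready-to-run config
agekin simulate --config cfg.yaml --seed 1 --out out/
```

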