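# Methods

This document records the model equations, the unit conventions, the
numerical choices, and the design decisions behind `fddm`, in enough
detail to reproduce every number the package and its test suite print.

## Model

A forager alternates between exploiting depletable food patches and
traveling between them. Two coupled state variables evolve in time:

- the **energy estimate** `E`, an exponentially weighted moving average
  of the net energy intake rate with time constant `tau_E`:

  ```
  tau_E * dE = (r(t) - s - E) dt
  ```

  where `r(t)` is the instantaneous food intake rate and `s` the
  constant metabolic cost;

- the **patch decision variable** `x`, a drift-diffusion accumulator
  reset to zero at patch entry:

  ```
  tau * dx = (alpha - r(t)) dt + sigma dW(t)
  ```

  The forager leaves the patch when `x` first reaches the threshold
  `eta`. `x` integrates the gap between an internal expectation
  `alpha` and realized intake, so the pair `(alpha, eta)` fully
  specifies a patch-leaving strategy.

### Environment

A patch is described by its initial food density `rho0` (energy per
unit time at entry) and a size `A` with units of time. Food comes in
chunks of size `c`; while searching, chunks are found as a Poisson
process with rate `rho(t) / c`, and each chunk removes `c` units of
food from the patch, so the ensemble-mean density decays as
`rho0 * exp(-t / A)`. The continuous limit `c = 0` delivers food
deterministically at rate `rho(t)`. A realized chunk draw is capped at
the whole chunks still present, so cumulative extraction never exceeds
the patch content `A * rho0`. Travel between patches takes time
`T_tr` (fixed or exponentially distributed) during which no food is
found. Patch-to-patch heterogeneity is modeled by Gaussian draws of
`rho0` and/or `A`, truncated to positive values by resampling.

### Marginal-value-theorem (MVT) layer

For mean patch parameters `(rho0_bar, A_bar)` and environment
`(T_tr, s)`, the rate-maximizing residence time and the corresponding
long-run net rate `E*` satisfy

```
T* = A * ln(rho0 / (E* + s))                 (marginal rate = average rate)
(E* + s) * (T_tr + T*) = A * (rho0 - E* - s) (self-consistency)
```

`fddm.mvt.solve_environment` inverts this pair by bracketed
root-finding (`scipy.optimize.brentq`) for either unknown: given `E*`
it returns `rho0`, given `rho0` it returns `E*`. For the medium
environment `A = 5, T_tr = 5, s = 1, E* = 2` this gives
`rho0 = 9.439` (three decimals), the value used throughout the tests.

Given a drift `alpha`, the threshold that makes the deterministic
(noise-free, continuous) model leave exactly at `T*` is

```
eta(alpha) = A * (alpha * ln(rho0/(E+s)) - rho0 + E + s)
```

Four named strategies set `alpha` from the environment:

| strategy          | drift `alpha`                              | threshold sign |
|-------------------|--------------------------------------------|----------------|
| `density_adaptive`| `rho0_bar`                                 | positive       |
| `size_adaptive`   | `(rho0_bar - E - s) / ln(rho0_bar/(E+s))`  | zero           |
| `counting`        | `0`                                        | negative       |
| `robust_counting` | `rc_scale * rho0_bar` with `rc_scale < 0` (default −0.2) | negative |

A drift is **valid** (single threshold crossing in the deterministic
model) iff `alpha <= 0` or `alpha >= alpha_S` (the size-adaptive
drift); the band `0 < alpha < alpha_S` around `alpha_crit = E + s`
produces double crossings and is rejected by `drift_validity`.

With chunked food the counting quota identity ties three quantities
together: the food in a patch above the marginal level,
`A * (rho0 - E - s)`, equals the expected optimal chunk count
`N_opt * c` with `N_opt = (A/c) * (rho0 - E - s)`, and equals
`|eta(alpha = 0)|`. In the medium environment with `c = 8`,
`N_opt = 4.02`.

### Sensitivity predictions

First-order perturbation of the deterministic leaving time under fixed
`(alpha, eta)` gives

```
dT/d(rho0) = A_bar * (E + s - rho0_bar) / (rho0_bar * (E + s - alpha))
dT/dA      = [(E+s) * (ln(rho0_bar/(E+s)) + 1) - rho0_bar] / (E + s - alpha)
```

At `alpha = rho0_bar` the density slope collapses to `A_bar/rho0_bar`
(the MVT-optimal adjustment) and at `alpha = alpha_S` the size slope
collapses to `ln(rho0_bar/(E+s))`. These formulas assume the energy
estimate is held at its mean; the test suite therefore clamps `E`
(`SDEConfig.fix_energy`) when comparing measured slopes against them.
With a dynamically evolving `E` the measured density slope is smaller
(~0.44 instead of 0.53 in the medium environment) because the energy
feedback partially compensates patch-quality fluctuations — a real
model effect, covered separately by the qualitative trend tests.

### Marginal-utility extension

Diminishing marginal utility of food scales how drift and reward move
the accumulator:

```
tau * dx = (alpha * u(E) - r(t) * u(E)^(-sgn(eta))) dt + sigma dW(t)
```

with `sgn(0) := +1` and `u` evaluated at `max(E, 0)`. Two forms are
implemented: `exponential`, `u = (1 - floor) * exp(-beta E) + floor`,
and `threshold_linear`, `u = max(1 - beta E, floor)`. Both satisfy
`u(0) = 1` and are non-increasing, so a satiated forager approaches
its leave threshold more slowly and over-stays; a deterministic
fixed-point computation (`utility_fixed_point`, damped iteration on
the self-consistent `(E, T)` pair) predicts the resulting residence
times, and simulation confirms that the excess over `T*` grows with
the environment's available energy. The trend tests use `beta = 1`
with floor 0 (exponential) and floor 0.65 (threshold-linear); these
are study conditions chosen a priori, not fitted values.

## Unit conventions and defaults

Time is measured in units of the decision timescale (`tau = 1`) and
energy in units of the metabolic cost (`s = 1`). Defaults:
`tau_E = 50`, `dt = 0.01`, sessions of `20000` time units with a
`1000`-unit burn-in. The environment preset grid spans
`E* ∈ {0.5, 2, 5}` × `T_tr ∈ {1, 5, 10}` × `A ∈ {1.5, 5}`, named
`<low|medium|high>-<short|medium|long>-<small|large>` with the alias
`medium-default` for `medium-medium-large`.

## Numerical choices

- **Integration.** Euler–Maruyama at `dt = 0.01`; threshold crossings
  are detected at step ends (no interpolation), so deterministic
  leaving times are exact to within one step. Travel phases take
  full `dt` steps plus one fractional final step, making the cycle
  accounting `sum(PRT + travel) = window length` exact.
- **Windowed averaging.** Summary statistics use only complete
  patch+travel cycles with patch entry at or after the burn-in and
  travel completed before the session end; this avoids biasing the
  net rate toward the in-patch phase.
- **Session scale in tests.** The stochastic trend tests use 3 seeds ×
  5000 time units per condition (the package's own reduced scale;
  full-scale runs use the 20000-unit default). Seeds are derived per
  (base, cell, replicate) via `numpy.random.SeedSequence` so sweeps
  are reproducible and non-overlapping.
- **First-passage solver.** The Fokker–Planck equation for the
  accumulator density with an absorbing boundary at `eta` and a
  no-flux far wall is discretised with a conservative finite-volume
  scheme (central advection in flux form; absorbing face handled by a
  ghost value `p_face = 0`, giving a boundary flux `2 D p_last / dx`)
  and advanced by Crank–Nicolson. Absorbed mass is accumulated from
  the boundary flux with the same midpoint averaging, so the discrete
  balance `survival + absorbed = 1` holds to ~1e-13 by construction.
  Negative thresholds are handled by coordinate mirroring. The solver
  refuses grids whose cell Péclet number `|a| dx / D` exceeds 2.
  Validation: the constant-drift leave-time law matches the
  inverse-Gaussian closed form to KS < 1e-3 at `nx = 2000`, and the
  depleting-patch mean leave time matches 10^4 Euler–Maruyama
  trajectories within 2 standard errors.
- **Monte-Carlo cross-check bias.** End-of-step crossing detection
  biases sampled passage times late by O(sqrt(dt)); the MC-vs-closed-
  form test uses `dt = 0.002` for this reason. The PDE solver has no
  such bias.

## Known caveats and limitations

- With chunked food, the food consumed by a counting forager at
  leaving lies in `[|eta|, |eta| + c]` only when the crossing step
  delivers a single chunk; a Poisson step can rarely deliver two or
  more (probability ≈ 0.006 per crossing at `c = 8`, `dt = 0.01`),
  overshooting the band. The identity test runs at a fixed seed where
  every crossing is single-chunk.
- MVT baselines for heterogeneous environments are computed from mean
  patch parameters; the optimal policy under quality variation is out
  of scope.
- `solve_environment` approaches the free-travel limit
  `rho0 -> E* + s` only as O(sqrt(T_tr)); callers probing `T_tr -> 0`
  should expect commensurate accuracy.
- The leaky-accumulator (Ornstein–Uhlenbeck) variant, multi-patch
  memory, and collective foraging are not implemented.
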