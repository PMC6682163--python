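"""Coupled stochastic dynamics of the foraging drift-diffusion model.

Two coupled state variables are integrated with Euler-Maruyama steps:

* the energy estimate E, a moving average of the net intake rate with
  timescale tau_E:   tau_E * dE = (r(t) - s - E) dt;
* the patch decision variable x, a drift-diffusion accumulator reset to
  zero at patch entry:   tau * dx = (alpha - r(t)) dt + sigma dW(t).

The forager leaves the patch when x reaches the threshold eta, which is
recomputed from the running energy estimate (and, for the size-adaptive
strategy, so is the drift).  A marginal-utility extension scales how
drift and food move the accumulator,

    tau * dx = (alpha * u(E) - r(t) * u(E)^(-sgn(eta))) dt + sigma dW(t),

so that a satiated forager (u < 1) drifts toward the leave threshold
more slowly, producing longer-than-optimal patch residence times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import environment as envmod
from . import mvt
from .environment import EnvironmentSpec, PatchState
from .mvt import StrategyConfig

__all__ = [
    "SDEConfig",
    "UtilityConfig",
    "ForagerState",
    "ThresholdUndefinedError",
    "utility_value",
    "current_threshold",
    "current_drift_and_threshold",
    "step_in_patch",
    "step_travel",
    "crossed",
]

UTILITY_FORMS = ("none", "exponential", "threshold_linear")


class ThresholdUndefinedError(ValueError):
    """Raised when the running E makes the optimal threshold undefined
    (E >= rho0_bar - s): the forager should leave immediately."""


@dataclass(frozen=True)
class SDEConfig:
    """Integration controls for the coupled stochastic system.

    tau        : decision timescale (unit of time; default 1).
    tau_E      : energy-averaging timescale (default 50 * tau).
    sigma      : noise amplitude on the decision variable.
    dt         : Euler-Maruyama step (default 0.01 * tau).
    seed       : RNG seed for the session.
    fix_energy : if set, clamp the energy estimate at this value (used to
                 study the E = <E> limit in which the model is exactly
                 MVT-equivalent).
    """

    tau: float = 1.0
    tau_E: float = 50.0
    sigma: float = 0.0
    dt: float = 0.01
    seed: int = 0
    fix_energy: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau <= 0 or self.tau_E <= 0:
            raise ValueError("dt, tau and tau_E must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class UtilityConfig:
    """Marginal utility of additional food as a function of the energy estimate.

    form  : "none" (u = 1), "exponential" (u = (1-floor)*exp(-beta*E) + floor)
            or "threshold_linear" (u = max(1 - beta*E, floor)).
    beta  : decay rate of utility with energy (>= 0).
    floor : lower asymptote/floor of the utility in [0, 1].

    By construction u(0) = 1, u is non-increasing in E, and negative
    energy estimates receive full utility (the argument is a surplus).
    """

    form: str = "none"
    beta: float = 0.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in UTILITY_FORMS:
            raise ValueError(f"unknown utility form {self.form!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.floor <= 1.0:
            raise ValueError("floor must lie in [0, 1]")


@dataclass
class ForagerState:
    """Mutable state of one forager."""

    x: float = 0.0
    E: float = 0.0
    phase: str = "traveling"
    t: float = 0.0
    t_phase: float = 0.0
    patch: PatchState | None = None
    alpha: float = 0.0  # drift used in the last step
    eta: float = 0.0  # threshold used in the last step
    leave: bool = False  # set when the last step triggered patch exit
    chunks: int = 0  # chunks eaten since patch entry
    food: float = 0.0  # energy eaten since patch entry

    def enter_patch(self, patch: PatchState) -> None:
        self.patch = patch
        self.phase = "in_patch"
        self.x = 0.0
        self.t_phase = 0.0
        self.leave = False
        self.chunks = 0
        self.food = 0.0

    def start_travel(self) -> None:
        self.patch = None
        self.phase = "traveling"
        self.x = 0.0
        self.t_phase = 0.0
        self.leave = False


def utility_value(u: UtilityConfig, E: float) -> float:
    """Marginal utility u(E); u = 1 for the unmodified model."""
    if u.form == "none" or u.beta == 0.0:
        return 1.0
    Epos = E if E > 0.0 else 0.0
    if u.form == "exponential":
        return (1.0 - u.floor) * math.exp(-u.beta * Epos) + u.floor
    # threshold_linear
    val = 1.0 - u.beta * Epos
    return val if val >= u.floor else u.floor


def current_drift_and_threshold(
    strategy: StrategyConfig,
    E: float,
    rho0_bar: float,
    A_bar: float,
    s: float,
) -> tuple[float, float]:
    """(alpha, eta) at the current energy estimate.

    Raises ThresholdUndefinedError when E >= rho0_bar - s, in which case
    the environment looks better than any patch and the forager leaves
    immediately (degenerate exit).
    """
    if E >= rho0_bar - s:
        raise ThresholdUndefinedError(
            f"threshold undefined: E={E} >= rho0_bar - s = {rho0_bar - s}"
        )
    alpha = mvt.resolve_drift(strategy, rho0_bar, E, s)
    eta = mvt.optimal_threshold(alpha, rho0_bar, A_bar, E, s)
    return alpha, eta


def current_threshold(
    strategy: StrategyConfig, E: float, rho0_bar: float, A_bar: float, s: float
) -> float:
    """Threshold at the current energy estimate (see current_drift_and_threshold)."""
    return current_drift_and_threshold(strategy, E, rho0_bar, A_bar, s)[1]


def crossed(x: float, eta: float) -> bool:
    """Threshold-crossing test, evaluated at step ends (no interpolation)."""
    return x >= eta if eta >= 0 else x <= eta


def step_in_patch(
    state: ForagerState,
    strategy: StrategyConfig,
    u: UtilityConfig,
    cfg: SDEConfig,
    env: EnvironmentSpec,
    rng: np.random.Generator,
) -> ForagerState:
    """One Euler-Maruyama step of the in-patch dynamics (in place).

    Draws the food found in this step, updates x (drift + reward impulse +
    noise), updates the energy estimate, depletes the patch, advances the
    clocks, and sets ``state.leave`` if the threshold was crossed (or the
    threshold became undefined at the current energy estimate).
    """
    if state.phase != "in_patch" or state.patch is None:
        raise ValueError("step_in_patch requires phase == 'in_patch'")
    dt = cfg.dt
    E_eff = cfg.fix_energy if cfg.fix_energy is not None else state.E

    if strategy.update_per_step or state.t_phase == 0.0:
        try:
            alpha, eta = current_drift_and_threshold(
                strategy, E_eff, env.rho0_mean, env.A_mean, env.s
            )
        except ThresholdUndefinedError:
            state.leave = True
            return state
        state.alpha, state.eta = alpha, eta
    else:
        alpha, eta = state.alpha, state.eta

    k, food = envmod.sample_reward(state.patch, dt, rng)

    uval = utility_value(u, E_eff)
    if uval == 1.0:
        dx = (alpha * dt - food) / cfg.tau
    else:
        f = uval ** (-1.0 if eta >= 0 else 1.0)
        dx = (alpha * uval * dt - food * f) / cfg.tau
    if cfg.sigma > 0.0:
        dx += (cfg.sigma / cfg.tau) * math.sqrt(dt) * rng.standard_normal()
    state.x += dx

    if cfg.fix_energy is None:
        state.E += (food - (env.s + state.E) * dt) / cfg.tau_E
    else:
        state.E = cfg.fix_energy

    envmod.deplete(state.patch, food)
    state.patch.t_in += dt
    state.t += dt
    state.t_phase += dt
    state.chunks += k
    state.food += food
    state.leave = crossed(state.x, eta)
    return state


def step_travel(
    state: ForagerState, cfg: SDEConfig, env: EnvironmentSpec, dt: float | None = None
) -> ForagerState:
    """One Euler step of the travel phase (in place): no reward, so the
    energy estimate relaxes toward -s; x is held at zero.

    ``dt`` defaults to cfg.dt; a shorter final fractional step lets
    callers land exactly on a drawn travel duration.
    """
    if state.phase != "traveling":
        raise ValueError("step_travel requires phase == 'traveling'")
    h = cfg.dt if dt is None else dt
    if cfg.fix_energy is None:
        state.E += h * (-env.s - state.E) / cfg.tau_E
    else:
        state.E = cfg.fix_energy
    state.x = 0.0
    state.t += h
    state.t_phase += h
    return state
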