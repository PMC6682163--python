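"""Marginal-value-theorem optimality layer for patch foraging.

With exponentially depleting patches (mean reward rate rho0*exp(-t/A)),
constant cost s and travel time T_tr, the MVT-optimal residence time is

    T* = A * ln(rho0 / (<E> + s)),

where the average net energy rate <E> and T* are linked through the
self-consistency condition r(T*) - s = <E>, i.e.

    (<E> + s) * (T_tr + T*) = A * (rho0 - <E> - s).

The drift-diffusion leaving rule x(T) = eta reproduces T* for any drift
alpha provided the threshold is set to

    eta = A * (alpha * ln(rho0/(E+s)) - rho0 + E + s),

which defines a one-parameter family of strategies: density-adaptive
(alpha = rho0_bar), size-adaptive (alpha such that eta = 0), counting
(alpha = 0) and robust counting (alpha < 0).  This module provides those
closed forms, their validity range, first-order sensitivity predictions
for uncertain environments, and the deterministic fixed point of the
utility-modified dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "MVTSolution",
    "StrategyConfig",
    "StrategyParams",
    "DriftValidity",
    "SensitivityPrediction",
    "STRATEGY_KINDS",
    "optimal_patch_time",
    "solve_environment",
    "optimal_threshold",
    "size_adaptive_drift",
    "resolve_drift",
    "strategy_params",
    "drift_validity",
    "n_opt",
    "prt_sensitivity_density",
    "prt_sensitivity_size",
    "prt_sensitivity",
    "deterministic_leave_time",
    "utility_fixed_point",
]

STRATEGY_KINDS = ("density_adaptive", "size_adaptive", "counting", "robust_counting")

_ROOT_XTOL = 1e-12


@dataclass(frozen=True)
class MVTSolution:
    """Simultaneous solution of the MVT conditions for one environment."""

    T_star: float
    E_star: float
    rho0: float
    A: float
    T_tr: float
    s: float


@dataclass(frozen=True)
class StrategyConfig:
    """Run-time choice of a patch-leaving strategy.

    kind            : one of STRATEGY_KINDS.
    rc_scale        : drift multiplier for robust counting, alpha = rc_scale * rho0_bar
                      (must be < 0; default -0.2).
    update_per_step : recompute drift/threshold from the running energy
                      estimate every integration step (default) or freeze
                      them at patch entry.
    """

    kind: str
    rc_scale: float = -0.2
    update_per_step: bool = True

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "robust_counting" and not self.rc_scale < 0:
            raise ValueError("robust_counting requires rc_scale < 0")


@dataclass(frozen=True)
class StrategyParams:
    """Resolved (alpha, eta) pair for a strategy at a given energy estimate."""

    kind: str
    alpha: float
    eta: float
    rc_scale: float = -0.2


@dataclass(frozen=True)
class DriftValidity:
    """Single-crossing validity of a drift value.

    Valid drifts are alpha <= 0 (decremental branch) or alpha >= alpha_S
    (increment-decrement branch); the band 0 < alpha < alpha_S contains
    either double threshold crossings (alpha_crit < alpha < alpha_S) or
    opposite signs of alpha and eta (0 < alpha < alpha_crit).
    """

    alpha_crit: float
    alpha_S: float
    valid: bool


@dataclass(frozen=True)
class SensitivityPrediction:
    """First-order PRT adjustments to patch-to-patch parameter deviations."""

    dT_drho0: float
    dT_dA: float


def _check_domain(rho0: float, E: float, s: float) -> None:
    if not rho0 > E + s:
        raise ValueError(
            f"rho0 must exceed E + s (got rho0={rho0}, E+s={E + s}); "
            "the patch is not worth entering and T* is undefined"
        )


def optimal_patch_time(rho0: float, A: float, E: float, s: float) -> float:
    """MVT-optimal patch residence time T* = A * ln(rho0 / (E + s))."""
    _check_domain(rho0, E, s)
    return A * math.log(rho0 / (E + s))


def _mvt_residual(rho0: float, A: float, T_tr: float, s: float, E: float) -> float:
    """(E+s)(T_tr + T*) - A(rho0 - E - s); zero at the MVT solution."""
    T_star = A * math.log(rho0 / (E + s))
    return (E + s) * (T_tr + T_star) - A * (rho0 - E - s)


def solve_environment(
    A: float,
    T_tr: float,
    s: float,
    *,
    rho0: float | None = None,
    E_star: float | None = None,
) -> MVTSolution:
    """Solve the MVT self-consistency for the missing one of {rho0, E_star}.

    Exactly one of ``rho0`` / ``E_star`` must be given.  Uses a bracketing
    root-finder (Brent) on a monotone residual.
    """
    if (rho0 is None) == (E_star is None):
        raise ValueError("give exactly one of rho0 or E_star")
    if min(A, T_tr, s) <= 0:
        raise ValueError("A, T_tr and s must be positive")

    if E_star is not None:
        E = float(E_star)
        if E <= -s:
            raise ValueError("E_star must exceed -s")
        lo = (E + s) * (1 + 1e-12)
        hi = 2.0 * (E + s) + 1.0
        # residual is positive at rho0 -> (E+s)+ and decreasing in rho0;
        # expand the bracket upward until it turns negative
        while _mvt_residual(hi, A, T_tr, s, E) > 0:
            hi *= 2.0
            if hi > 1e12:
                raise ValueError("no MVT solution: E_star infeasible for this environment")
        if _mvt_residual(lo, A, T_tr, s, E) < 0:
            raise ValueError("no MVT solution: rho0 bracket degenerate")
        r0 = brentq(lambda r: _mvt_residual(r, A, T_tr, s, E), lo, hi, xtol=_ROOT_XTOL)
    else:
        r0 = float(rho0)
        if r0 <= s:
            raise ValueError("rho0 must exceed s for a net-positive-feasible patch")
        lo = -s + 1e-12 * s
        hi = r0 - s - 1e-12 * r0
        # residual is negative at E -> -s and increasing in E
        if _mvt_residual(r0, A, T_tr, s, hi) < 0 or _mvt_residual(r0, A, T_tr, s, lo) > 0:
            raise ValueError("no MVT solution for given rho0")
        E = brentq(lambda e: _mvt_residual(r0, A, T_tr, s, e), lo, hi, xtol=_ROOT_XTOL)

    return MVTSolution(
        T_star=optimal_patch_time(r0, A, E, s),
        E_star=E,
        rho0=r0,
        A=A,
        T_tr=T_tr,
        s=s,
    )


def optimal_threshold(alpha: float, rho0: float, A: float, E: float, s: float) -> float:
    """Threshold that makes a drift-alpha forager leave exactly at T*:
    eta = A * (alpha * ln(rho0/(E+s)) - rho0 + E + s)."""
    _check_domain(rho0, E, s)
    return A * (alpha * math.log(rho0 / (E + s)) - rho0 + E + s)


def size_adaptive_drift(rho0: float, E: float, s: float) -> float:
    """Drift making eta = 0: alpha_S = (rho0 - E - s) / ln(rho0/(E+s))."""
    _check_domain(rho0, E, s)
    return (rho0 - E - s) / math.log(rho0 / (E + s))


def resolve_drift(
    strategy: StrategyConfig, rho0_bar: float, E: float, s: float
) -> float:
    """Drift rate of a strategy; size-adaptive depends on the current E."""
    kind = strategy.kind
    if kind == "density_adaptive":
        return rho0_bar
    if kind == "size_adaptive":
        return size_adaptive_drift(rho0_bar, E, s)
    if kind == "counting":
        return 0.0
    return strategy.rc_scale * rho0_bar  # robust_counting


def strategy_params(
    kind: str,
    rho0_bar: float,
    A_bar: float,
    E: float,
    s: float,
    rc_scale: float = -0.2,
) -> StrategyParams:
    """Resolve a named strategy to its (alpha, eta) pair at energy estimate E."""
    cfg = StrategyConfig(kind=kind, rc_scale=rc_scale)
    alpha = resolve_drift(cfg, rho0_bar, E, s)
    eta = optimal_threshold(alpha, rho0_bar, A_bar, E, s)
    return StrategyParams(kind=kind, alpha=alpha, eta=eta, rc_scale=rc_scale)


def drift_validity(
    alpha: float, rho0: float, A: float, E: float, s: float
) -> DriftValidity:
    """Classify a drift value by the single-threshold-crossing requirement."""
    alpha_crit = E + s
    alpha_S = size_adaptive_drift(rho0, E, s)
    valid = alpha <= 0.0 or alpha >= alpha_S
    return DriftValidity(alpha_crit=alpha_crit, alpha_S=alpha_S, valid=valid)


def n_opt(rho0: float, A: float, c: float, E: float, s: float) -> float:
    """Expected chunks eaten per patch under the optimal policy:
    N_opt = (A / c) * (rho0 - E - s)."""
    if c <= 0:
        raise ValueError("n_opt requires a discrete chunk size c > 0")
    _check_domain(rho0, E, s)
    return (A / c) * (rho0 - E - s)


def prt_sensitivity_density(
    alpha: float, rho0_bar: float, A_bar: float, E: float, s: float
) -> float:
    """First-order change of the leaving time per unit deviation of a
    patch's rho0 from rho0_bar, under fixed (alpha, eta):

        dT/drho0 = A_bar * (E + s - rho0_bar) / (rho0_bar * (E + s - alpha)).

    Reduces to A_bar / rho0_bar at alpha = rho0_bar (the MVT-optimal
    adjustment), which is what makes the density-adaptive choice optimal.
    """
    if alpha == E + s:
        raise ValueError("sensitivity is singular at alpha = E + s")
    return A_bar * (E + s - rho0_bar) / (rho0_bar * (E + s - alpha))


def prt_sensitivity_size(
    alpha: float, rho0_bar: float, E: float, s: float
) -> float:
    """First-order change of the leaving time per unit deviation of a
    patch's size from A_bar, under fixed (alpha, eta):

        dT/dA = [(E+s)(ln(rho0_bar/(E+s)) + 1) - rho0_bar] / (E + s - alpha).

    Reduces to ln(rho0_bar/(E+s)) (the MVT-optimal adjustment) at the
    size-adaptive drift.
    """
    if alpha == E + s:
        raise ValueError("sensitivity is singular at alpha = E + s")
    num = (E + s) * (math.log(rho0_bar / (E + s)) + 1.0) - rho0_bar
    return num / (E + s - alpha)


def prt_sensitivity(
    alpha: float, rho0_bar: float, A_bar: float, E: float, s: float
) -> SensitivityPrediction:
    """Both first-order PRT sensitivities bundled together."""
    return SensitivityPrediction(
        dT_drho0=prt_sensitivity_density(alpha, rho0_bar, A_bar, E, s),
        dT_dA=prt_sensitivity_size(alpha, rho0_bar, E, s),
    )


def deterministic_leave_time(
    alpha: float,
    eta: float,
    rho0: float,
    A: float,
    tau: float = 1.0,
    u: float = 1.0,
    t_max: float = 1e7,
) -> float:
    """Zero-noise, continuous-reward crossing time of x = eta.

    Integrates tau*dx = (alpha*u - r(t)*u^(-sgn(eta))) dt with the mean
    reward r(t) = rho0 * exp(-t/A), i.e. solves

        alpha*u*T - f*rho0*A*(1 - exp(-T/A)) = tau * eta,
        f = u^(-sgn(eta)),  sgn(0) := +1,

    for the crossing relevant to the strategy's branch.  For incremental
    strategies (eta >= 0) this is the late crossing after the initial dip
    of x below zero; for decremental strategies (eta < 0) it is the first
    crossing.  Returns math.inf when the threshold is never reached
    (e.g. a counting forager in a patch without enough food).
    """
    if u <= 0:
        raise ValueError("utility u must be > 0")
    sgn = 1.0 if eta >= 0 else -1.0
    a_eff = alpha * u
    f = u ** (-sgn)

    def g(T: float) -> float:
        return a_eff * T - f * rho0 * A * (1.0 - math.exp(-T / A)) - tau * eta

    if eta >= 0:
        if a_eff <= 0:
            return math.inf
        # x dips while the reward rate exceeds the drift, then rises
        lo = A * math.log(f * rho0 / a_eff) if f * rho0 > a_eff else 0.0
        if eta == 0 and lo == 0.0:
            return 0.0
        hi = max(lo, A) * 2.0
        while g(hi) < 0:
            hi *= 2.0
            if hi > t_max:
                return math.inf
        if g(lo) > 0:  # crossing at (or numerically before) the dip start
            return lo
        return brentq(g, lo, hi, xtol=_ROOT_XTOL)

    # decremental branch: x decreases monotonically toward eta < 0
    if a_eff == 0.0 and f * rho0 * A <= -tau * eta:
        return math.inf  # patch asymptote never reaches the threshold
    hi = A
    while g(hi) > 0:
        hi *= 2.0
        if hi > t_max:
            return math.inf
    return brentq(g, 0.0, hi, xtol=_ROOT_XTOL)


def utility_fixed_point(
    strategy: StrategyConfig | str,
    utility,
    A: float,
    T_tr: float,
    s: float,
    rho0: float,
    *,
    damping: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> tuple[float, float]:
    """Self-consistent (E, T) of the utility-modified deterministic model.

    Alternates (i) the deterministic leaving time T(E) from integrating
    the utility-scaled dynamics with the mean reward, threshold eta(E),
    and marginal utility u(E); and (ii) the realized average net rate
    E(T) = (rho0*A*(1 - exp(-T/A)) - s*(T_tr + T)) / (T_tr + T), using a
    damped fixed-point iteration to absolute tolerance ``tol``.  With
    beta = 0 (utility identically 1) this recovers the MVT solution.
    """
    from .core import UtilityConfig, utility_value  # deferred: avoids cycle

    if isinstance(strategy, str):
        strategy = StrategyConfig(kind=strategy)
    if utility is None:
        utility = UtilityConfig(form="none")

    base = solve_environment(A, T_tr, s, rho0=rho0)
    E = base.E_star
    T = base.T_star
    for _ in range(max_iter):
        u = utility_value(utility, E)
        alpha = resolve_drift(strategy, rho0, E, s)
        eta = optimal_threshold(alpha, rho0, A, E, s)
        T = deterministic_leave_time(alpha, eta, rho0, A, tau=1.0, u=u)
        if not math.isfinite(T):
            raise RuntimeError("utility fixed point diverged: threshold unreachable")
        gained = rho0 * A * (1.0 - math.exp(-T / A))
        E_new = (gained - s * (T_tr + T)) / (T_tr + T)
        if abs(E_new - E) < tol:
            return E_new, T
        E += damping * (E_new - E)
    raise RuntimeError(f"utility fixed point did not converge in {max_iter} iterations")
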