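"""Patches, travel segments, and the stochastic reward stream.

A forager alternates between exploiting depletable food patches and
traveling between them.  A patch is characterised by its initial food
density ``rho0`` (energy per unit time at entry), a "size" ``A`` with
units of time (the patch area divided by the search rate, which is fixed
at v = 1), and a chunk size ``c`` that interpolates between continuous
(``c = 0``) and discrete (``c > 0``) rewards.  While the forager searches,
chunks are found as a Poisson process with rate ``rho(t)/c`` and each
chunk eaten removes ``c`` units of food from the patch, so the ensemble
mean density decays exponentially, ``<rho(t)> = rho0 * exp(-t / A)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "Fixed",
    "Gaussian",
    "Exponential",
    "PatchSpec",
    "PatchState",
    "EnvironmentSpec",
    "draw_patch",
    "draw_travel_time",
    "sample_reward",
    "deplete",
    "mean_density",
]

_MAX_TRUNCATION_RETRIES = 1000


@dataclass(frozen=True)
class Fixed:
    """Degenerate distribution: always returns ``value``."""

    value: float

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng: np.random.Generator) -> float:
        return self.value


@dataclass(frozen=True)
class Gaussian:
    """Gaussian with given mean and sd; used for patch-to-patch variation."""

    mean: float
    sd: float

    def sample(self, rng: np.random.Generator) -> float:
        return self.mean + self.sd * rng.standard_normal()


@dataclass(frozen=True)
class Exponential:
    """Exponential with given mean; used for travel times between scattered patches."""

    mean: float

    def sample(self, rng: np.random.Generator) -> float:
        return rng.exponential(self.mean)


Distribution = Union[Fixed, Gaussian, Exponential]


@dataclass(frozen=True)
class PatchSpec:
    """Parameters of one patch.

    rho0 : initial food density (energy per unit time at entry), > 0.
    A    : patch size in time units (area / search rate, v = 1), > 0.
    c    : food chunk size (energy units); c = 0 means continuous reward.
    """

    rho0: float
    A: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not self.rho0 > 0:
            raise ValueError(f"rho0 must be > 0, got {self.rho0}")
        if not self.A > 0:
            raise ValueError(f"A must be > 0, got {self.A}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")


@dataclass
class PatchState:
    """A patch together with its current (depleting) food density."""

    spec: PatchSpec
    rho: float = field(default=None)  # type: ignore[assignment]
    t_in: float = 0.0

    def __post_init__(self) -> None:
        if self.rho is None:
            self.rho = self.spec.rho0


@dataclass(frozen=True)
class EnvironmentSpec:
    """Distributions defining a foraging environment.

    rho0_dist : initial patch food density (Fixed or Gaussian).
    A_dist    : patch size (Fixed or Gaussian).
    c         : chunk size, shared by all patches.
    Ttr_dist  : travel time between patches (Fixed or Exponential).
    s         : constant metabolic cost (energy per unit time), > 0.
    """

    rho0_dist: Distribution
    A_dist: Distribution
    c: float = 0.0
    Ttr_dist: Distribution = Fixed(5.0)
    s: float = 1.0

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError("cost s must be > 0")
        for name in ("rho0_dist", "A_dist", "Ttr_dist"):
            if getattr(self, name).mean <= 0:
                raise ValueError(f"{name} must have positive mean")
        if self.c < 0:
            raise ValueError("chunk size c must be >= 0")

    @property
    def rho0_mean(self) -> float:
        return self.rho0_dist.mean

    @property
    def A_mean(self) -> float:
        return self.A_dist.mean


def _sample_positive(dist: Distribution, rng: np.random.Generator) -> float:
    """Draw from ``dist``, resampling until the draw is positive.

    Rejects after 1000 consecutive non-positive draws, which signals a
    pathological sd relative to the mean.
    """
    for _ in range(_MAX_TRUNCATION_RETRIES):
        value = dist.sample(rng)
        if value > 0:
            return value
    raise ValueError(
        f"failed to draw a positive value from {dist!r} after "
        f"{_MAX_TRUNCATION_RETRIES} attempts; sd is pathological"
    )


def draw_patch(env: EnvironmentSpec, rng: np.random.Generator) -> PatchState:
    """Draw a fresh patch: rho0 and A from the configured distributions,
    truncated to be positive by resampling; entry state has rho = rho0."""
    rho0 = _sample_positive(env.rho0_dist, rng)
    A = _sample_positive(env.A_dist, rng)
    return PatchState(spec=PatchSpec(rho0=rho0, A=A, c=env.c))


def draw_travel_time(env: EnvironmentSpec, rng: np.random.Generator) -> float:
    """Draw the travel duration to the next patch (strictly positive)."""
    return _sample_positive(env.Ttr_dist, rng)


def sample_reward(
    state: PatchState, dt: float, rng: np.random.Generator
) -> tuple[int, float]:
    """Realize the food found in one step of length ``dt``.

    For c > 0 the chunk count is Poisson with rate rho * dt / c (the
    pre-step density) and the food is k * c; for c = 0 the continuous
    limit applies and food = rho * dt deterministically.  In both modes
    the expected food is rho * dt (up to the conservation cap: the draw
    cannot exceed the whole chunks still present in the patch, so total
    extraction never exceeds A * rho0).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    c = state.spec.c
    if c == 0.0:
        return 0, state.rho * dt
    if state.rho <= 0.0:
        return 0, 0.0
    k = int(rng.poisson(state.rho * dt / c))
    if k:
        remaining = int(state.rho * state.spec.A / c + 1e-12)
        k = min(k, remaining)
    return k, k * c


def deplete(state: PatchState, food: float) -> PatchState:
    """Remove eaten food from the patch (in place): the total food A*rho
    drops by ``food``, floored at zero density.  Returns the state."""
    if food < 0:
        raise ValueError("food must be >= 0")
    if food:
        state.rho = max(0.0, state.rho - food / state.spec.A)
    return state


def mean_density(spec: PatchSpec, t: float) -> float:
    """Ensemble-mean food density after time ``t`` in the patch:
    rho0 * exp(-t / A)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    return spec.rho0 * np.exp(-np.asarray(t, dtype=float) / spec.A) if np.ndim(t) else spec.rho0 * math.exp(-t / spec.A)
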