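"""Full foraging sessions, burn-in/full-cycle averaging, and parameter sweeps.

A session alternates patch exploitation and travel from t = 0 with an
initial energy estimate of zero.  Summary statistics are computed on a
measurement window that starts at the first patch entry at or after the
burn-in time and ends with the last complete patch+travel cycle, so that
every included cycle contributes both its residence time and its travel
segment (otherwise the realized net rate would be biased toward the
in-patch phase).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import environment as envmod
from .core import ForagerState, SDEConfig, UtilityConfig, step_in_patch, step_travel
from .environment import EnvironmentSpec, Fixed
from .mvt import StrategyConfig, solve_environment

log = logging.getLogger("fddm.experiments")

__all__ = [
    "PatchVisit",
    "SessionSummary",
    "simulate_session",
    "sweep",
    "sweep_seed",
    "environment_presets",
    "preset_environment",
    "PRESET_GRID",
    "prt_regression",
    "write_visits",
    "read_visits",
    "write_summary",
    "read_summary",
    "config_hash",
    "VISIT_COLUMNS",
    "SUMMARY_SCHEMA",
]


@dataclass(frozen=True)
class PatchVisit:
    """Record of one patch visit and the travel segment that follows it."""

    t_enter: float
    t_leave: float
    prt: float
    chunks: int
    food: float
    E_exit: float
    travel_after: float
    rho0_actual: float
    A_actual: float
    degenerate: bool = False


@dataclass(frozen=True)
class SessionSummary:
    """Windowed statistics of one session."""

    mean_energy_rate: float
    sd_energy_rate: float
    mean_prt: float
    sd_prt: float
    chunk_histogram: dict[int, int]
    n_patches: int
    window: tuple[float, float]
    total_food: float
    degenerate_exits: int


VISIT_COLUMNS = [
    "t_enter",
    "t_leave",
    "prt",
    "chunks",
    "food",
    "E_exit",
    "travel_after",
    "rho0_actual",
    "A_actual",
    "degenerate",
]

#: Required keys and JSON types of a written summary.
SUMMARY_SCHEMA = {
    "mean_energy_rate": float,
    "sd_energy_rate": float,
    "mean_prt": float,
    "sd_prt": float,
    "chunk_histogram": dict,
    "n_patches": int,
    "window": list,
    "total_food": float,
    "degenerate_exits": int,
}


def simulate_session(
    env: EnvironmentSpec,
    strategy: StrategyConfig,
    utility: UtilityConfig | None,
    cfg: SDEConfig,
    total_time: float = 20000.0,
    burn_in: float = 1000.0,
    *,
    E0: float = 0.0,
    max_prt: float = 2000.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[PatchVisit], SessionSummary]:
    """Run one session and summarize it over the measurement window.

    ``E0`` is the initial energy estimate (ignored when cfg.fix_energy is
    set).  ``max_prt`` caps a single residence time; a capped visit is
    recorded as degenerate (a zero-drift counting forager in a depleted
    patch would otherwise never leave).  A fresh Generator is derived
    from cfg.seed unless ``rng`` is supplied.
    """
    if not total_time > burn_in >= 0:
        raise ValueError("need total_time > burn_in >= 0")
    if utility is None:
        utility = UtilityConfig(form="none")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    state = ForagerState(E=cfg.fix_energy if cfg.fix_energy is not None else E0)
    visits: list[PatchVisit] = []
    while state.t < total_time:
        patch = envmod.draw_patch(env, rng)
        t_enter = state.t
        state.enter_patch(patch)
        degenerate = False
        while True:
            step_in_patch(state, strategy, utility, cfg, env, rng)
            if state.leave:
                degenerate = state.t_phase == 0.0
                break
            if state.t_phase >= max_prt:
                degenerate = True
                break
        prt = state.t_phase
        t_leave = state.t
        E_exit = state.E
        chunks, food = state.chunks, state.food

        if log.isEnabledFor(logging.DEBUG):
            log.debug(
                "leave patch: t=%.2f prt=%.3f food=%.3f chunks=%d E=%.4f degenerate=%s",
                t_leave, prt, food, chunks, E_exit, degenerate,
            )
        travel = envmod.draw_travel_time(env, rng)
        state.start_travel()
        n_full = int(travel // cfg.dt)
        for _ in range(n_full):
            step_travel(state, cfg, env)
        rem = travel - n_full * cfg.dt
        if rem > 0.0:
            step_travel(state, cfg, env, dt=rem)

        visits.append(
            PatchVisit(
                t_enter=t_enter,
                t_leave=t_leave,
                prt=prt,
                chunks=chunks,
                food=food,
                E_exit=E_exit,
                travel_after=travel,
                rho0_actual=patch.spec.rho0,
                A_actual=patch.spec.A,
                degenerate=degenerate,
            )
        )

    summary = summarize(visits, burn_in=burn_in, total_time=total_time, s=env.s)
    return visits, summary


def summarize(
    visits: list[PatchVisit], burn_in: float, total_time: float, s: float
) -> SessionSummary:
    """Windowed means/SDs over complete cycles inside [burn_in, total_time]."""
    window_visits = [
        v for v in visits if v.t_enter >= burn_in and v.t_leave + v.travel_after <= total_time
    ]
    if not window_visits:
        raise ValueError("measurement window is empty: no complete cycle fits")

    window_length = sum(v.prt + v.travel_after for v in window_visits)
    total_food = sum(v.food for v in window_visits)
    prts = np.array([v.prt for v in window_visits])
    cycle_rates = np.array(
        [(v.food - s * (v.prt + v.travel_after)) / (v.prt + v.travel_after) for v in window_visits]
    )
    counts: dict[int, int] = {}
    for v in window_visits:
        counts[v.chunks] = counts.get(v.chunks, 0) + 1

    t_start = window_visits[0].t_enter
    return SessionSummary(
        mean_energy_rate=(total_food - s * window_length) / window_length,
        sd_energy_rate=float(np.std(cycle_rates, ddof=1)) if len(cycle_rates) > 1 else 0.0,
        mean_prt=float(prts.mean()),
        sd_prt=float(np.std(prts, ddof=1)) if len(prts) > 1 else 0.0,
        chunk_histogram=counts,
        n_patches=len(window_visits),
        window=(t_start, t_start + window_length),
        total_food=total_food,
        degenerate_exits=sum(v.degenerate for v in window_visits),
    )


def sweep_seed(base_seed: int, cell: int, replicate: int) -> int:
    """Deterministic per-cell, per-replicate seed below 2**31, derived by
    spawning a SeedSequence keyed on (base_seed, cell, replicate)."""
    return int(np.random.SeedSequence([base_seed, cell, replicate]).generate_state(1)[0] % (2**31))


def sweep(
    grid: list[tuple[EnvironmentSpec, StrategyConfig, UtilityConfig | None, SDEConfig]],
    replicates: int = 3,
    base_seed: int = 0,
    *,
    total_time: float = 20000.0,
    burn_in: float = 1000.0,
    labels: list[dict] | None = None,
    **session_kwargs,
) -> pd.DataFrame:
    """One summary row per (cell, replicate); per-cell failures are
    recorded in the ``error`` column instead of aborting the sweep."""
    if not grid:
        raise ValueError("grid must be non-empty")
    rows = []
    for i, (env, strategy, utility, cfg) in enumerate(grid):
        for j in range(replicates):
            seed = sweep_seed(base_seed, i, j)
            row: dict = {
                "cell": i,
                "replicate": j,
                "seed": seed,
                "strategy": strategy.kind,
                "sigma": cfg.sigma,
                "c": env.c,
                "rho0_mean": env.rho0_mean,
                "A_mean": env.A_mean,
                "Ttr_mean": env.Ttr_dist.mean,
                "error": "",
            }
            if labels is not None:
                row.update(labels[i])
            try:
                _, summary = simulate_session(
                    env,
                    strategy,
                    utility,
                    dataclasses.replace(cfg, seed=seed),
                    total_time=total_time,
                    burn_in=burn_in,
                    **session_kwargs,
                )
                row.update(
                    mean_energy_rate=summary.mean_energy_rate,
                    sd_energy_rate=summary.sd_energy_rate,
                    mean_prt=summary.mean_prt,
                    sd_prt=summary.sd_prt,
                    n_patches=summary.n_patches,
                    degenerate_exits=summary.degenerate_exits,
                )
            except Exception as exc:  # noqa: BLE001 - sweep must not abort
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


#: (label, value) axes of the study's 3 x 3 x 2 environment grid.
PRESET_GRID = {
    "E_star": {"low": 0.5, "medium": 2.0, "high": 5.0},
    "T_tr": {"short": 1.0, "medium": 5.0, "long": 10.0},
    "A": {"small": 1.5, "large": 5.0},
}

PRESET_ALIASES = {"medium-default": "medium-medium-large"}


def preset_environment(
    E_star: float, T_tr: float, A: float, *, c: float = 0.0, s: float = 1.0
) -> EnvironmentSpec:
    """Fixed-parameter environment with rho0 solved from the MVT conditions."""
    sol = solve_environment(A, T_tr, s, E_star=E_star)
    return EnvironmentSpec(
        rho0_dist=Fixed(sol.rho0),
        A_dist=Fixed(A),
        c=c,
        Ttr_dist=Fixed(T_tr),
        s=s,
    )


def environment_presets() -> dict[str, EnvironmentSpec]:
    """The full grid of E* in {0.5, 2, 5} x T_tr in {1, 5, 10} x A in {1.5, 5}
    (cost s = 1, continuous reward), keyed "<energy>-<travel>-<size>",
    plus the alias "medium-default" for the intermediate configuration."""
    presets = {}
    for e_label, e in PRESET_GRID["E_star"].items():
        for t_label, ttr in PRESET_GRID["T_tr"].items():
            for a_label, a in PRESET_GRID["A"].items():
                presets[f"{e_label}-{t_label}-{a_label}"] = preset_environment(e, ttr, a)
    for alias, target in PRESET_ALIASES.items():
        presets[alias] = presets[target]
    return presets


def prt_regression(visits: list[PatchVisit], min_visits: int = 30) -> float:
    """Least-squares slope of patch residence time against the visited
    patch's drawn rho0 (centered), for comparison with the first-order
    sensitivity prediction."""
    usable = [v for v in visits if not v.degenerate]
    if len(usable) < min_visits:
        raise ValueError(f"need >= {min_visits} visits, got {len(usable)}")
    rho0 = np.array([v.rho0_actual for v in usable])
    prt = np.array([v.prt for v in usable])
    d = rho0 - rho0.mean()
    var = float(d @ d)
    if var < 1e-12 * len(usable):
        raise ValueError("rho0 is (numerically) constant across visits")
    return float(d @ (prt - prt.mean()) / var)


# ---------------------------------------------------------------------------
# serialization


def config_hash(obj) -> str:
    """Short stable hash of a (nested dataclass / dict) configuration."""

    def norm(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__, **{k: norm(v) for k, v in dataclasses.asdict(o).items()}}
        if isinstance(o, dict):
            return {k: norm(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [norm(v) for v in o]
        return o

    payload = json.dumps(norm(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_visits(visits: list[PatchVisit], path, *, config=None, seed=None) -> None:
    """Write the visit table as CSV with a fixed column order; provenance
    (config hash and seed) is embedded as a leading comment line."""
    df = pd.DataFrame([dataclasses.asdict(v) for v in visits], columns=VISIT_COLUMNS)
    try:
        with open(path, "w") as fh:
            fh.write(f"# fddm-visits config_hash={config_hash(config)} seed={seed}\n")
            df.to_csv(fh, index=False)
    except OSError as exc:
        raise OSError(f"could not write visits to {path}: {exc}") from exc


def read_visits(path) -> pd.DataFrame:
    """Read a visit table written by write_visits."""
    try:
        return pd.read_csv(path, comment="#")
    except OSError as exc:
        raise OSError(f"could not read visits from {path}: {exc}") from exc


def summary_to_dict(summary: SessionSummary) -> dict:
    d = dataclasses.asdict(summary)
    d["chunk_histogram"] = {str(k): v for k, v in summary.chunk_histogram.items()}
    d["window"] = list(summary.window)
    return d


def validate_summary(d: dict) -> None:
    """Check a summary dict against SUMMARY_SCHEMA (required keys + types)."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in d:
            raise ValueError(f"summary missing required key {key!r}")
        value = d[key]
        if typ is float and isinstance(value, int):
            continue
        if not isinstance(value, typ):
            raise ValueError(f"summary key {key!r} has type {type(value).__name__}, expected {typ.__name__}")


def write_summary(summary: SessionSummary, path, *, config=None, seed=None) -> None:
    """Write a session summary as JSON with stable keys and embedded provenance."""
    d = summary_to_dict(summary)
    d["config_hash"] = config_hash(config)
    d["seed"] = seed
    validate_summary(d)
    try:
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"could not write summary to {path}: {exc}") from exc


def read_summary(path) -> dict:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except OSError as exc:
        raise OSError(f"could not read summary from {path}: {exc}") from exc
    validate_summary(d)
    return d
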