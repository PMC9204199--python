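"""Closed-loop coupling of a controller to a plant variant, cycle by cycle.

Every cardiac cycle: measure (HR, MAP) from the plant, update the
disturbance estimate (offset-free only), solve the configured MPC, and apply
the first optimized action through the stimulation device model for one
cycle. The controller only ever sees the plant's two measured outputs; the
surrogate's recurrent state is advanced with the measured output and applied
command so its internal state tracks the plant trajectory.

Five named scenarios are shipped: three healthy-plant designs (sparsity,
min_energy, min_overshoot) on a 150-cycle three-segment schedule, and two
offset-free designs on mismatched plants (intra_patient: perturbed
recruitment concentrations; sympathetic: overactive-sympathetic dynamics).
Closed-loop performance is summarized by the steady-state mean absolute
error (SS-MAE): per set-point segment, the mean |HR error| plus the mean
|MAP error| over the segment's last 10 cycles, averaged over segments.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .actuation import RecruitmentParams, build_variant, firing_deltas_from_vectors
from .cardio import resting_state
from .datagen import normalize
from .mpc import (ControllerConfig, DisturbanceState, disturbance_update,
                  solve_offset_free, solve_receding_horizon)
from .params import PlantParameters
from .surrogate import SurrogateModel

__all__ = [
    "SetpointSchedule", "ScenarioSpec", "ClosedLoopLog", "scenario_preset",
    "run_closed_loop", "ss_mae", "settle_cycles", "horizon_sweep",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("sparsity", "min_energy", "min_overshoot",
                  "offset_free_intra_patient", "offset_free_sympathetic")


@dataclass(frozen=True)
class SetpointSchedule:
    """Ordered (duration_cycles, target HR bpm, target MAP mmHg) segments."""

    segments: tuple[tuple[int, float, float], ...]

    def __post_init__(self):
        for dur, hr, mp in self.segments:
            if dur < 1:
                raise ValueError("segment durations must be >= 1 cycle")
            if not (np.isfinite(hr) and np.isfinite(mp)):
                raise ValueError("targets must be finite")

    @property
    def total_cycles(self) -> int:
        return sum(s[0] for s in self.segments)

    def targets(self) -> np.ndarray:
        """Per-cycle reference array (total_cycles, 2)."""
        return np.concatenate([
            np.tile([[hr, mp]], (dur, 1)) for dur, hr, mp in self.segments])

    def segment_slices(self) -> list[slice]:
        out, k = [], 0
        for dur, _, _ in self.segments:
            out.append(slice(k, k + dur))
            k += dur
        return out


@dataclass(frozen=True)
class ScenarioSpec:
    """A named closed-loop experiment: plant variant, schedule, controller."""

    name: str
    plant_variant: str
    schedule: SetpointSchedule
    config: ControllerConfig
    initial: tuple[float, float]


def scenario_preset(name: str) -> ScenarioSpec:
    """The five published closed-loop scenarios with their settings."""
    healthy_sched = SetpointSchedule((
        (50, 392.0, 111.0), (50, 346.0, 144.0), (50, 393.0, 125.0)))
    mismatch_sched = SetpointSchedule((
        (150, 356.0, 150.0), (150, 393.0, 129.0), (150, 377.0, 143.0)))
    sympath_sched = SetpointSchedule((
        (300, 356.0, 150.0), (300, 393.0, 129.0), (300, 377.0, 143.0)))
    if name in ("sparsity", "min_energy", "min_overshoot"):
        return ScenarioSpec(
            name=name, plant_variant="healthy", schedule=healthy_sched,
            config=ControllerConfig(variant=name, Np=10, Nc=5, lam=1e-3,
                                    lam1=1e-3, lam2=5e-5, tol=1e-5,
                                    max_iter=50),
            initial=(409.0, 138.0))
    if name == "offset_free_intra_patient":
        return ScenarioSpec(
            name=name, plant_variant="intra_patient", schedule=mismatch_sched,
            config=ControllerConfig(variant="offset_free", Np=20, Nc=10,
                                    Ld=np.array([0.06, 0.05]), tol=1e-4,
                                    max_iter=500),
            initial=(409.0, 138.0))
    if name == "offset_free_sympathetic":
        return ScenarioSpec(
            name=name, plant_variant="sympathetic", schedule=sympath_sched,
            config=ControllerConfig(variant="offset_free", Np=20, Nc=10,
                                    Ld=np.array([0.06, 0.018]), tol=1e-4,
                                    max_iter=500),
            initial=(452.0, 152.0))
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")


@dataclass
class ClosedLoopLog:
    """One row per simulated cycle of a closed-loop run."""

    u: np.ndarray          # (N, 6) applied commands
    y: np.ndarray          # (N, 2) measured plant outputs under control
    r: np.ndarray          # (N, 2) targets
    y_pred: np.ndarray     # (N, 2) controller's one-step predictions
    d: np.ndarray          # (N, 2) disturbance estimate (normalized units)
    cost: np.ndarray
    status: np.ndarray
    n_iter: np.ndarray
    initial: tuple[float, float]
    failure: str | None = None
    wall_time_per_cycle: float = float("nan")

    def __len__(self) -> int:
        return self.y.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"cycle": np.arange(1, len(self) + 1)}
        for j, nm in enumerate(("pw1", "pf1", "pw2", "pf2", "pw3", "pf3")):
            cols[nm] = self.u[:, j]
        cols.update(hr=self.y[:, 0], map=self.y[:, 1],
                    r_hr=self.r[:, 0], r_map=self.r[:, 1],
                    pred_hr=self.y_pred[:, 0], pred_map=self.y_pred[:, 1],
                    d_hr=self.d[:, 0], d_map=self.d[:, 1],
                    cost=self.cost, status=self.status, iters=self.n_iter)
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _plant_for(variant: str, params: PlantParameters | None):
    preset, rp = build_variant(variant)
    if params is not None:
        if variant == "sympathetic":
            from .params import sympathetic_parameters
            preset = sympathetic_parameters(params)
        else:
            preset = params
    return preset, rp


def run_closed_loop(spec: ScenarioSpec, model: SurrogateModel,
                    plant_params: PlantParameters | None = None,
                    rp: RecruitmentParams | None = None) -> ClosedLoopLog:
    """Run one scenario to completion and return its per-cycle log.

    ``plant_params`` optionally supplies the calibrated healthy parameter
    set (the sympathetic variant's substitutions are applied on top of it);
    the surrogate is always the healthy-trained model.
    """
    params, rp_default = _plant_for(spec.plant_variant, plant_params)
    if rp is None:
        rp = rp_default
    plant, last = resting_state(params)
    n = spec.schedule.total_cycles
    targets = spec.schedule.targets()
    sy = model.norm.slice(slice(0, 2))
    su = model.norm.slice(slice(2, 8))
    state = model.init_state(1)
    offset_free = spec.config.variant == "offset_free"
    ds = DisturbanceState(Ld=spec.config.Ld.copy()) if offset_free else None
    log = ClosedLoopLog(
        u=np.zeros((n, 6)), y=np.zeros((n, 2)), r=targets.copy(),
        y_pred=np.zeros((n, 2)), d=np.zeros((n, 2)), cost=np.zeros(n),
        status=np.zeros(n, dtype=int), n_iter=np.zeros(n, dtype=int),
        initial=(last.hr, last.map))
    y_meas = np.array([last.hr, last.map])
    warm = None
    t0 = time.perf_counter()
    for k in range(n):
        y_meas_n = normalize(y_meas, sy)
        try:
            if offset_free:
                ds = disturbance_update(ds, y_meas_n)
                sol = solve_offset_free(model, state, y_meas, targets[k], ds,
                                        spec.config, warm_start=warm)
                warm = np.concatenate([
                    (np.vstack([sol.u_seq[1:], sol.u_seq[-1:]])
                     / su.span).ravel(),
                    sol.u_s / su.span, normalize(sol.y_s, sy)])
            else:
                # current target held over the horizon: the controller reacts
                # at the set-point change rather than manoeuvring ahead of it
                sol = solve_receding_horizon(
                    model, state, y_meas, targets[k:k + 1], spec.config,
                    u_prev=log.u[k - 1] if k else None, warm_start=warm)
                warm = np.vstack([sol.u_seq[1:], sol.u_seq[-1:]])
            u_k = sol.first
            out = plant.step(firing_deltas_from_vectors(u_k, rp))
        except Exception as exc:  # truncate on hard plant/solver failure
            log.failure = f"cycle {k}: {exc!r}"
            log.u, log.y, log.r = log.u[:k], log.y[:k], log.r[:k]
            log.y_pred, log.d = log.y_pred[:k], log.d[:k]
            log.cost, log.status, log.n_iter = (log.cost[:k], log.status[:k],
                                                log.n_iter[:k])
            break
        # advance the surrogate's recurrent state along the realized
        # trajectory; its one-step output is the next augmented prediction
        x = np.concatenate([y_meas_n, normalize(u_k, su)]).reshape(1, -1)
        y1n, state, _ = model.step(x, state)
        if offset_free:
            ds.y_aug_pred = y1n[0] + ds.d
            log.d[k] = ds.d
        log.u[k] = u_k
        log.y[k] = [out.hr, out.map]
        log.y_pred[k] = sol.y_pred[0]
        log.cost[k] = sol.cost
        log.status[k] = sol.status
        log.n_iter[k] = sol.n_iter
        y_meas = log.y[k]
    log.wall_time_per_cycle = (time.perf_counter() - t0) / max(len(log), 1)
    return log


def ss_mae(log: ClosedLoopLog | np.ndarray, schedule: SetpointSchedule,
           window: int = 10) -> float:
    """Steady-state mean absolute error of a closed-loop run.

    Per segment: mean |HR - r_HR| + mean |MAP - r_MAP| over the last
    ``window`` cycles; averaged across segments.
    """
    y = log.y if isinstance(log, ClosedLoopLog) else np.asarray(log, dtype=float)
    if y.shape[0] != schedule.total_cycles:
        raise ValueError("log length does not match the schedule")
    targets = schedule.targets()
    errs = []
    for sl in schedule.segment_slices():
        if sl.stop - sl.start < window:
            raise ValueError(f"segment shorter than the {window}-cycle window")
        e = np.abs(y[sl][-window:] - targets[sl][-window:])
        errs.append(e[:, 0].mean() + e[:, 1].mean())
    return float(np.mean(errs))


def settle_cycles(log: ClosedLoopLog, schedule: SetpointSchedule,
                  tol_hr: float = 1.0, tol_map: float = 1.0) -> list[int]:
    """Cycles needed after each set-point change to reach and hold the target.

    For each segment, the first 1-based cycle index (within the segment)
    from which |HR error| < tol_hr and |MAP error| < tol_map hold through
    the segment's end; the segment length + 1 if never reached.
    """
    targets = schedule.targets()
    out = []
    for sl in schedule.segment_slices():
        e = np.abs(log.y[sl] - targets[sl])
        ok = (e[:, 0] < tol_hr) & (e[:, 1] < tol_map)
        n = len(ok)
        idx = n  # sentinel: never settled
        for i in range(n - 1, -1, -1):
            if ok[i]:
                idx = i
            else:
                break
        out.append(idx + 1)
    return out


def horizon_sweep(model: SurrogateModel, grid, variants=("sparsity",),
                  plant_params: PlantParameters | None = None,
                  schedule: SetpointSchedule | None = None) -> pd.DataFrame:
    """Re-run closed loops across a grid of (Nc, Np) horizon pairs.

    All λ weights are fixed at 0.001 for comparability. Returns a table of
    (variant, Nc, Np, decision variables, SS-MAE, wall time per cycle);
    timings are reported but are hardware-dependent and never asserted.
    """
    rows = []
    for variant in variants:
        base = scenario_preset(
            variant if variant in SCENARIO_NAMES else "sparsity")
        sched = schedule if schedule is not None else base.schedule
        for Nc, Np in grid:
            cfg = ControllerConfig(variant=base.config.variant, Np=Np, Nc=Nc,
                                   lam=1e-3, lam1=1e-3, lam2=1e-3,
                                   Ld=base.config.Ld, tol=base.config.tol,
                                   max_iter=base.config.max_iter)
            spec = ScenarioSpec(name=f"{variant}-Nc{Nc}-Np{Np}",
                                plant_variant=base.plant_variant,
                                schedule=sched, config=cfg,
                                initial=base.initial)
            log = run_closed_loop(spec, model, plant_params=plant_params)
            rows.append({
                "variant": variant, "Nc": Nc, "Np": Np,
                "variables": cfg.n_decision,
                "ss_mae": ss_mae(log, sched) if log.failure is None else np.nan,
                "time_per_cycle_s": log.wall_time_per_cycle,
            })
    return pd.DataFrame(rows)


def metrics_json(log: ClosedLoopLog, schedule: SetpointSchedule,
                 path: str | Path | None = None) -> dict:
    """SS-MAE, per-segment errors and solver statistics for a run."""
    targets = schedule.targets()
    seg = []
    for sl in schedule.segment_slices():
        e = np.abs(log.y[sl][-10:] - targets[sl][-10:])
        seg.append({"hr_mae": float(e[:, 0].mean()),
                    "map_mae": float(e[:, 1].mean())})
    out = {
        "ss_mae": ss_mae(log, schedule),
        "segments": seg,
        "settle_cycles": settle_cycles(log, schedule),
        "solver_failures": int(np.sum(log.status != 0)),
        "mean_iterations": float(log.n_iter.mean()),
        "time_per_cycle_s": log.wall_time_per_cycle,
    }
    if path is not None:
        Path(path).write_text(json.dumps(out, indent=1))
    return out
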