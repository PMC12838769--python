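"""Parameter sweeps over tendon stiffness, resting length and torque.

The parameter search mirrors the study design: tendon stiffness 0-60 N/cm
in steps of 10 (10-60 for the wing-section sweeps), resting length 0-9 cm
in steps of 1 cm, proximal fold torque 0-50 N·cm in steps of 10, unfold
torque on both joint families up to 100 N·cm in steps of 10, a constant
500 N·cm accelerated fold before every unfold run, and a timestep
sensitivity scan over h = 0.0030-0.0050 s in steps of 0.0005 s.

Cells are independent; the whole sweep is evaluated as one vectorised
batch, so results do not depend on execution order.  Per-cell divergence
is recorded as a failure diagnostic and never aborts the sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .actuation import (
    ACCELERATED_FOLD_TORQUE,
    DetectionConfig,
    detect_state,
    folding_time,
    make_fold_schedule,
    make_unfold_schedule,
)
from .dynamics import BatchSim, SimConfig, Trajectory, phase_to_trajectories, run_phase
from .energetics import fold_input_energy, tendon_energy, unfold_input_energy
from .model import WingModel

__all__ = ["SweepGrid", "SweepResult", "run_fold_sweep", "run_unfold_sweep", "timestep_scan", "export_sweep"]


@dataclass(frozen=True)
class SweepGrid:
    """Ranges and increments of the parameter search."""

    k_values: tuple = tuple(float(k) for k in range(10, 70, 10))  # N/cm
    l_r_values: tuple = tuple(float(l) for l in range(0, 10))  # cm
    fold_torques: tuple = tuple(float(m) for m in range(0, 60, 10))  # N·cm
    unfold_torques: tuple = tuple(float(m) for m in range(10, 110, 10))  # N·cm
    accelerated_fold_torque: float = ACCELERATED_FOLD_TORQUE
    h_values: tuple = (0.0030, 0.0035, 0.0040, 0.0045, 0.0050)  # s
    fold_duration: float = 300.0  # s; exceeds the slowest expected fold
    unfold_duration: float = 100.0
    accel_fold_duration: float = 60.0

    def __post_init__(self):
        for name in ("k_values", "l_r_values", "fold_torques", "unfold_torques", "h_values"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if len(vals) > 1 and not np.all(np.diff(vals) > 0):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass
class SweepResult:
    """Per-cell classification and energies plus aggregate counts.

    ``runs`` carries the underlying per-(cell, torque) outcomes, so any
    individual grid run (e.g. a particular cell at a particular torque)
    can be read off the same batched computation.
    """

    cells: pd.DataFrame
    aggregates: dict = field(default_factory=dict)
    runs: pd.DataFrame | None = None


def _detcfg(config: SimConfig | None) -> DetectionConfig:
    return DetectionConfig()


def run_fold_sweep(
    grid: SweepGrid,
    model: WingModel,
    config: SimConfig | None = None,
    detection: DetectionConfig | None = None,
) -> SweepResult:
    """Classify fold success over the (k, l_r) grid.

    For each cell the fold torques are tried in ascending order (as one
    vectorised batch); the cell's minimum successful torque, its folding
    time, the fold input energy E_ab and the state energies U_a / U_b are
    recorded from the run at that minimum torque.
    """
    cfg = config or SimConfig(duration=grid.fold_duration, record_stride=40)
    det = detection or DetectionConfig()
    ks, lrs, mas = [], [], []
    for k in grid.k_values:
        for lr in grid.l_r_values:
            for ma in grid.fold_torques:
                ks.append(k), lrs.append(lr), mas.append(ma)
    ks, lrs, mas = map(np.array, (ks, lrs, mas))

    sched = make_fold_schedule(0.0)  # direction conventions only
    sim = BatchSim(model, ks, lrs, cfg)
    rec = run_phase(sim, grid.fold_duration, mas, np.zeros_like(mas), sched.dir_alpha, sched.dir_delta)
    trajs = phase_to_trajectories(sim, rec)

    run_rows = []
    by_cell: dict[tuple, dict] = {}
    for k, lr, ma, tr in zip(ks, lrs, mas, trajs):
        ft_run = folding_time(tr, det)
        run_rows.append(
            {
                "k": k,
                "l_r": lr,
                "torque": ma,
                "fold_success": ft_run is not None and not tr.diverged,
                "folding_time_s": ft_run if ft_run is not None else np.nan,
                "diverged": tr.diverged,
            }
        )
        key = (k, lr)
        cell = by_cell.setdefault(
            key,
            {
                "k": k,
                "l_r": lr,
                "fold_success": False,
                "min_fold_torque": np.nan,
                "folding_time_s": np.nan,
                "E_ab_J": np.nan,
                "U_a_J": np.nan,
                "U_b_J": np.nan,
                "t_b_s": np.nan,
                "diverged": False,
            },
        )
        cell["diverged"] = cell["diverged"] or tr.diverged
        if cell["fold_success"]:
            continue
        if ft_run is None or tr.diverged:
            continue
        cell["fold_success"] = True
        cell["min_fold_torque"] = ma
        cell["folding_time_s"] = ft_run
        cell["E_ab_J"] = fold_input_energy(tr, ma, config=det)
        u_t = tendon_energy(tr.k, tr.tendon_lengths, tr.l_r)
        b = detect_state(tr, "b", det)
        cell["U_a_J"] = float(u_t[0].sum())
        cell["U_b_J"] = float(u_t[b.index].sum())
        cell["t_b_s"] = b.t

    cells = pd.DataFrame([by_cell[(k, lr)] for k in grid.k_values for lr in grid.l_r_values])
    n_success = int(cells["fold_success"].sum())
    aggregates = {
        "n_cells": len(cells),
        "n_fold_success": n_success,
        "min_E_ab_J": float(cells["E_ab_J"].min()) if n_success else None,
        "max_E_ab_J": float(cells["E_ab_J"].max()) if n_success else None,
        "min_folding_time_s": float(cells["folding_time_s"].min()) if n_success else None,
    }
    return SweepResult(cells=cells, aggregates=aggregates, runs=pd.DataFrame(run_rows))


def run_unfold_sweep(
    grid: SweepGrid,
    model: WingModel,
    config: SimConfig | None = None,
    detection: DetectionConfig | None = None,
) -> SweepResult:
    """Classify unfold success over the (k, l_r) grid.

    Every cell starts from the settled folded state (placed there
    directly, which makes the unfolding analysis independent of any
    particular folding run); the unfold torques (equal magnitude on distal
    and proximal joints, alternating directions) are then tried in
    ascending order.  A cell that leaves the folded band before actuation
    is flagged as a fold-stall diagnostic rather than attempted.
    """
    det = detection or DetectionConfig()
    ks, lrs, mus = [], [], []
    for k in grid.k_values:
        for lr in grid.l_r_values:
            for mu in grid.unfold_torques:
                ks.append(k), lrs.append(lr), mus.append(mu)
    ks, lrs, mus = map(np.array, (ks, lrs, mus))
    cfg = config or SimConfig(duration=grid.unfold_duration, record_stride=40)

    unfold_sched = make_unfold_schedule(1.0, 1.0)
    sim = BatchSim(model, ks, lrs, cfg)
    sim.set_folded()
    rec = run_phase(
        sim, grid.unfold_duration, mus, mus, unfold_sched.dir_alpha, unfold_sched.dir_delta
    )
    trajs = phase_to_trajectories(sim, rec)

    run_rows = []
    by_cell: dict[tuple, dict] = {}
    for k, lr, mu, traj in zip(ks, lrs, mus, trajs):
        c_run = detect_state(traj, "c", det)
        run_rows.append(
            {
                "k": k,
                "l_r": lr,
                "torque": mu,
                "unfold_success": c_run is not None and not traj.diverged,
                "unfold_time_s": c_run.t if c_run is not None else np.nan,
                "diverged": traj.diverged,
            }
        )
        key = (k, lr)
        cell = by_cell.setdefault(
            key,
            {
                "k": k,
                "l_r": lr,
                "folded_start_ok": False,
                "stall_delta_deg": np.nan,
                "unfold_success": False,
                "min_unfold_torque": np.nan,
                "E_bc_J": np.nan,
                "U_b_J": np.nan,
                "U_c_J": np.nan,
                "t_c_s": np.nan,
                "diverged": False,
            },
        )
        cell["diverged"] = cell["diverged"] or traj.diverged
        fold_depth = float(np.min(np.abs(traj.delta[0] * traj.signs)))
        if fold_depth < det.fold_band_deg:
            if np.isnan(cell["stall_delta_deg"]):
                cell["stall_delta_deg"] = fold_depth
            continue
        cell["folded_start_ok"] = True
        if cell["unfold_success"]:
            continue
        c = c_run
        if c is None or traj.diverged:
            continue
        cell["unfold_success"] = True
        cell["min_unfold_torque"] = mu
        cell["E_bc_J"] = unfold_input_energy(traj, mu, mu, t_b=0.0, config=det)
        u_t = tendon_energy(traj.k, traj.tendon_lengths, traj.l_r)
        cell["U_b_J"] = float(u_t[0].sum())
        cell["U_c_J"] = float(u_t[c.index].sum())
        cell["t_c_s"] = c.t

    cells = pd.DataFrame([by_cell[(k, lr)] for k in grid.k_values for lr in grid.l_r_values])
    n_success = int(cells["unfold_success"].sum())
    ok = cells[cells["unfold_success"]]
    aggregates = {
        "n_cells": len(cells),
        "n_unfold_success": n_success,
        "min_E_bc_J": float(ok["E_bc_J"].min()) if n_success else None,
        "argmin_E_bc": (
            {
                "k": float(ok.loc[ok["E_bc_J"].idxmin(), "k"]),
                "l_r": float(ok.loc[ok["E_bc_J"].idxmin(), "l_r"]),
            }
            if n_success
            else None
        ),
        "n_folded_start_failures": int((~cells["folded_start_ok"]).sum()),
    }
    return SweepResult(cells=cells, aggregates=aggregates, runs=pd.DataFrame(run_rows))


def timestep_scan(
    model: WingModel,
    h_values=SweepGrid.h_values,
    fold_torque: float = 30.0,
    unfold_torque: float = 40.0,
    fold_duration: float = 60.0,
    unfold_duration: float = 100.0,
    detection: DetectionConfig | None = None,
) -> pd.DataFrame:
    """Timestep sensitivity of the reference fold/unfold events.

    Runs the same folding protocol (and an unfolding run from the settled
    folded state) at each timestep width and tabulates the detected event
    times; the relative spread across ``h`` is the convergence diagnostic.
    The defaults use a reference cell where both transitions complete
    robustly.
    """
    det = detection or DetectionConfig()
    fold_sched = make_fold_schedule(fold_torque)
    unfold_sched = make_unfold_schedule(unfold_torque, unfold_torque)
    elastic = model.elastic_tendons()
    rows = []
    trajs = {}
    for h in h_values:
        cfg = SimConfig(h=float(h), duration=unfold_duration, record_stride=max(int(round(0.2 / h)), 1))
        sim = BatchSim(model, elastic[0].k, elastic[0].l_r, cfg)
        rec1 = run_phase(sim, fold_duration, fold_sched.M_alpha, fold_sched.M_delta,
                         fold_sched.dir_alpha, fold_sched.dir_delta)
        t1 = phase_to_trajectories(sim, rec1)[0]
        sim2 = BatchSim(model, elastic[0].k, elastic[0].l_r, cfg)
        sim2.set_folded()
        rec2 = run_phase(sim2, unfold_duration, unfold_sched.M_alpha, unfold_sched.M_delta,
                         unfold_sched.dir_alpha, unfold_sched.dir_delta)
        t2 = phase_to_trajectories(sim2, rec2)[0]
        b = detect_state(t1, "b", det)
        c = detect_state(t2, "c", det)
        rows.append(
            {
                "h_s": float(h),
                "t_fold_s": b.t if b is not None else np.nan,
                "t_unfold_s": c.t if c is not None else np.nan,
                "diverged": t1.diverged or t2.diverged,
            }
        )
        trajs[float(h)] = (t1, t2)
    table = pd.DataFrame(rows)
    for col in ("t_fold_s", "t_unfold_s"):
        vals = table[col].to_numpy(dtype=float)
        if np.all(np.isfinite(vals)) and np.nanmean(vals) > 0:
            table[col + "_rel_spread"] = (np.nanmax(vals) - np.nanmin(vals)) / np.nanmean(vals)
        else:
            table[col + "_rel_spread"] = np.nan
    table.attrs["trajectories"] = trajs
    return table


def _boundary_cells(cells: pd.DataFrame, flag: str) -> list[dict]:
    """Successful cells with at least one failing 4-neighbour on the grid."""
    ok = {(r.k, r.l_r): bool(getattr(r, flag)) for r in cells.itertuples()}
    ks = sorted({r for r, _ in ok})
    lrs = sorted({c for _, c in ok})
    dk = ks[1] - ks[0] if len(ks) > 1 else 1.0
    dl = lrs[1] - lrs[0] if len(lrs) > 1 else 1.0
    out = []
    for (k, lr), good in sorted(ok.items()):
        if not good:
            continue
        neighbours = [(k + dk, lr), (k - dk, lr), (k, lr + dl), (k, lr - dl)]
        if any(n in ok and not ok[n] for n in neighbours):
            out.append({"k": k, "l_r": lr})
    return out


def export_sweep(result: SweepResult, csv_path, json_path=None) -> Path:
    """Write one CSV row per cell plus a JSON summary.

    The JSON carries the aggregate counts and the feasibility-boundary
    cells (successful cells bordering failures).  Re-export of the same
    result is byte-identical.
    """
    csv_path = Path(csv_path)
    result.cells.to_csv(csv_path, index=False, float_format="%.10g")
    if json_path is not None:
        flag = "unfold_success" if "unfold_success" in result.cells.columns else "fold_success"
        payload = {
            "aggregates": result.aggregates,
            "feasibility_boundary": _boundary_cells(result.cells, flag),
        }
        Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=float))
    return csv_path
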