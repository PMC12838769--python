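"""Actuation schedules and canonical state detection.

The wing section is driven by constant torques on the proximal and distal
``rx`` joints, alternating in direction for every second strut (the
mountain/valley alternation).  Folding applies proximal torque only: the
pleating motion unlocks the distal joints and the tendons then drive the
ring fold passively.  Unfolding applies torque directly on the distal
joints (standing in for the cerci pulling the wing open) plus proximal
torque to re-open the radial fold.

Three canonical states are tracked: the initial flat state ``a``, the
folded state ``b`` (all fold angles at/beyond the 175-degree band,
sustained), and the re-opened state ``c`` (all joints back in the
0..3-degree overbend band after an unfold schedule).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import BatchSim, SimConfig, Trajectory, phase_to_trajectories, run_phase
from .model import WingModel

__all__ = [
    "ActuationSchedule",
    "StateLabel",
    "DetectionConfig",
    "make_fold_schedule",
    "make_unfold_schedule",
    "detect_state",
    "folding_time",
    "run_fold_unfold",
    "ACCELERATED_FOLD_TORQUE",
]

# the torque used to guarantee a rapid, complete fold before unfolding runs
ACCELERATED_FOLD_TORQUE = 500.0  # N·cm

# Global direction conventions (per-strut signs multiply these): delta
# ranges put the fold at -180 deg for positive-sign struts, so folding
# torque on delta is negative and opening torque positive for them.
_DIR_DELTA_FOLD = -1.0
_DIR_DELTA_UNFOLD = +1.0
_DIR_ALPHA_FOLD = +1.0
_DIR_ALPHA_UNFOLD = -1.0


@dataclass(frozen=True)
class ActuationSchedule:
    """Constant-torque actuation of one phase.

    ``M_alpha`` / ``M_delta`` are magnitudes in N·cm; the torque applied to
    strut ``i`` is ``(-1)**(i+1) * dir * M``, encoding the alternating
    directions of neighbouring radial folds.
    """

    M_alpha: float
    M_delta: float
    phase: str  # "fold" | "unfold"
    dir_alpha: float
    dir_delta: float

    def __post_init__(self):
        if self.M_alpha < 0 or self.M_delta < 0:
            raise ValueError("torque magnitudes must be >= 0")

    def torques(self, signs: np.ndarray):
        """Per-strut applied torques (tau_alpha, tau_delta), N·cm."""
        return (
            signs * self.dir_alpha * self.M_alpha,
            signs * self.dir_delta * self.M_delta,
        )


@dataclass(frozen=True)
class StateLabel:
    """A detected canonical state."""

    label: str  # "a_flat" | "b_folded" | "c_opened"
    t: float  # detection time, s
    snapshot_alpha: np.ndarray  # degrees
    snapshot_delta: np.ndarray  # degrees
    index: int  # trajectory sample index


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for state detection (degrees, seconds).

    The folded band and dwell are chosen to be robust to the oscillation
    around the folded minimum that the compliant joint limits allow; they
    are configuration, not physics.
    """

    fold_band_deg: float = 175.0
    open_band_deg: tuple[float, float] = (0.0, 3.0)
    # the compliant overbend limit yields by ~2 deg under the stiffest
    # tendons, so the open band carries a matching tolerance
    open_tol_deg: float = 3.0
    dwell_s: float = 1.0
    ke_max: float = 1e-2  # raw N·cm units, state a only


def make_fold_schedule(M_alpha: float) -> ActuationSchedule:
    """Folding: torque on the proximal joints only.

    The distal folding is passive — proximal pleating unlocks the distal
    joints and the contracting tendons close the ring fold.
    """
    return ActuationSchedule(
        M_alpha=M_alpha,
        M_delta=0.0,
        phase="fold",
        dir_alpha=_DIR_ALPHA_FOLD,
        dir_delta=_DIR_DELTA_FOLD,
    )


def make_unfold_schedule(M_delta: float, M_alpha: float) -> ActuationSchedule:
    """Unfolding: distal torque opens the ring fold first, proximal torque
    re-opens the radial fold."""
    return ActuationSchedule(
        M_alpha=M_alpha,
        M_delta=M_delta,
        phase="unfold",
        dir_alpha=_DIR_ALPHA_UNFOLD,
        dir_delta=_DIR_DELTA_UNFOLD,
    )


def _open_angles(traj: Trajectory) -> np.ndarray:
    """Sign-adjusted fold angles: positive = overbend side, degrees."""
    return traj.delta * traj.signs[None, :]


def _fold_angles(traj: Trajectory) -> np.ndarray:
    """Sign-adjusted fold depth: +180 = fully folded, degrees."""
    return -traj.delta * traj.signs[None, :]


def _sustained(mask: np.ndarray, times: np.ndarray, dwell: float) -> int | None:
    """First index i such that mask holds on [t_i, t_i + dwell]."""
    if not mask.any():
        return None
    n = len(mask)
    dt = times[1] - times[0] if n > 1 else dwell
    win = max(int(round(dwell / max(dt, 1e-12))), 1)
    ok = np.convolve(mask.astype(int), np.ones(win, dtype=int), mode="valid") == win
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        # accept a fold that holds to the very end of the recording
        tail = np.flatnonzero(~mask)
        start = tail[-1] + 1 if tail.size else 0
        if start < n and times[-1] - times[start] >= 0.5 * dwell:
            return int(start)
        return None
    return int(idx[0])


def detect_state(
    traj: Trajectory,
    which: str,
    config: DetectionConfig | None = None,
    after_t: float = 0.0,
) -> StateLabel | None:
    """Locate canonical state ``a``/``b``/``c`` in a trajectory.

    Returns the first detection as a :class:`StateLabel`, or ``None`` when
    the state is not reached within the recording ("not reached"; sweep
    classification counts these as failures).  ``after_t`` restricts the
    search, e.g. to samples after the unfold onset for state ``c``.
    """
    cfg = config or DetectionConfig()
    which = which.lower()[0]  # accepts "a", "b", "c" or "a_flat" etc.
    lo, hi = cfg.open_band_deg
    lo -= cfg.open_tol_deg
    hi += cfg.open_tol_deg
    start = int(np.searchsorted(traj.times, after_t))
    times = traj.times[start:]
    if times.size == 0:
        return None

    if which == "a":
        open_ok = np.all((_open_angles(traj)[start:] >= lo) & (_open_angles(traj)[start:] <= hi), axis=1)
        calm = traj.kinetic_energy[start:] <= cfg.ke_max
        idx = np.flatnonzero(open_ok & calm)
        if idx.size == 0:
            return None
        i = start + int(idx[0])
        label = "a_flat"
    elif which == "b":
        folded = np.all(_fold_angles(traj)[start:] >= cfg.fold_band_deg, axis=1)
        j = _sustained(folded, times, cfg.dwell_s)
        if j is None:
            return None
        i = start + j
        label = "b_folded"
    elif which == "c":
        opened = np.all((_open_angles(traj)[start:] >= lo) & (_open_angles(traj)[start:] <= hi), axis=1)
        j = _sustained(opened, times, cfg.dwell_s)
        if j is None:
            return None
        i = start + j
        label = "c_opened"
    else:
        raise ValueError(f"unknown state {which!r}; expected 'a', 'b' or 'c'")

    return StateLabel(
        label=label,
        t=float(traj.times[i]),
        snapshot_alpha=traj.alpha[i].copy(),
        snapshot_delta=traj.delta[i].copy(),
        index=i,
    )


def folding_time(
    traj: Trajectory, config: DetectionConfig | None = None, onset_t: float = 0.0
) -> float | None:
    """Simulated time from torque onset to folded-state detection, s."""
    b = detect_state(traj, "b", config, after_t=onset_t)
    if b is None:
        return None
    return b.t - onset_t


def run_fold_unfold(
    model: WingModel,
    unfold_schedule: ActuationSchedule,
    config: SimConfig,
    fold_schedule: ActuationSchedule | None = None,
    fold_duration: float = 60.0,
    unfold_duration: float | None = None,
) -> Trajectory:
    """A full fold-then-unfold run of one model.

    Without a ``fold_schedule`` the run starts from the settled folded
    state directly (a short unactuated segment is recorded first), which
    makes the unfolding independent of any particular folding process;
    passing a fold schedule simulates the folding phase instead.  Events
    ``fold_onset`` and ``unfold_onset`` are recorded on the trajectory.
    """
    unfold_duration = unfold_duration or config.duration
    elastic = model.elastic_tendons()
    sim = BatchSim(model, elastic[0].k, elastic[0].l_r, config)
    if fold_schedule is None:
        sim.set_folded()
        rec1 = run_phase(sim, max(2.0, 10 * config.h * config.record_stride), 0.0, 0.0, 1.0, 1.0)
    else:
        rec1 = run_phase(
            sim, fold_duration, fold_schedule.M_alpha, fold_schedule.M_delta,
            fold_schedule.dir_alpha, fold_schedule.dir_delta,
        )
    t1 = phase_to_trajectories(sim, rec1)[0]
    rec2 = run_phase(
        sim, unfold_duration, unfold_schedule.M_alpha, unfold_schedule.M_delta,
        unfold_schedule.dir_alpha, unfold_schedule.dir_delta,
    )
    t2 = phase_to_trajectories(sim, rec2)[0]
    traj = t1.extend(t2)
    traj.events["fold_onset"] = 0.0
    traj.events["unfold_onset"] = float(t1.times[-1])
    return traj
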