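"""Tendon potential energies and actuation input energies.

The tendons are linear tension-only springs, so one tendon at length
``l_t`` with resting length ``l_r`` stores

    U_t = 1e-2 * 1/2 * k * (l_t - l_r)^2      [J]

with ``k`` in N/cm and lengths in cm (the 1e-2 converts N·cm to N·m).
Input energies over a state transition are the work of the constant
applied torques: the torque magnitude times the net change of each
actuated joint angle (radians), with the alternating per-strut signs, also
converted from N·cm to J by 1e-2.  Net angular displacement between the
state-detection snapshots is used — not the path-integrated swept angle —
which for constant torques equals the mechanical work done.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .actuation import DetectionConfig, StateLabel, detect_state
from .dynamics import Trajectory
from .model import WingModel

__all__ = [
    "tendon_energy",
    "fold_input_energy",
    "unfold_input_energy",
    "energy_landscape",
    "theoretical_minima",
    "EnergyReport",
    "build_energy_report",
]

_NCM_TO_J = 1e-2


def tendon_energy(k, l_t, l_r) -> np.ndarray | float:
    """Potential energy of a tendon, Joules (vectorised).

    Zero at or below the resting length: the tendon contracts freely and
    stores no compression energy.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("tendon stiffness must be >= 0")
    ext = np.maximum(np.asarray(l_t, dtype=float) - np.asarray(l_r, dtype=float), 0.0)
    out = _NCM_TO_J * 0.5 * k * ext**2
    return float(out) if out.ndim == 0 else out


def _net_delta(series: np.ndarray, i0: int, i1: int) -> np.ndarray:
    """Net angular change per joint between two samples, radians."""
    return np.radians(series[i1] - series[i0])


def fold_input_energy(
    traj: Trajectory,
    M_alpha: float,
    t_a: float | None = None,
    t_b: float | None = None,
    config: DetectionConfig | None = None,
) -> float:
    """Input energy E_ab of the folding transition, Joules.

    ``E_ab = 1e-2 * sum_i (-1)**(i+1) * M_alpha * d(alpha_i)`` with the net
    proximal-joint displacements between the flat and folded snapshots.
    Snapshot times default to the detected states; they can be overridden
    because the energies are sensitive to the exact timestep chosen.
    """
    i0 = _snap_index(traj, "a", t_a, default=0, config=config)
    i1 = _snap_index(traj, "b", t_b, default=len(traj) - 1, config=config)
    dalpha = _net_delta(traj.alpha, i0, i1)
    signs = traj.signs  # (-1)**(i+1)
    return float(_NCM_TO_J * np.sum(signs * M_alpha * dalpha))


def unfold_input_energy(
    traj: Trajectory,
    M_alpha: float,
    M_delta: float,
    t_b: float | None = None,
    t_c: float | None = None,
    config: DetectionConfig | None = None,
) -> float:
    """Input energy E_bc of the unfolding transition, Joules.

    ``E_bc = 1e-2 * sum_i [(-1)**i * M_alpha * d(alpha_i)
    + (-1)**(i+1) * M_delta * d(delta_i)]``: the proximal torque acts in
    the direction opposite to folding, the distal torque with the
    alternating fold signs.
    """
    after = traj.events.get("unfold_onset", 0.0)
    i0 = _snap_index(traj, "b", t_b, default=0, config=config, after_t=0.0)
    i1 = _snap_index(traj, "c", t_c, default=len(traj) - 1, config=config, after_t=after)
    dalpha = _net_delta(traj.alpha, i0, i1)
    ddelta = _net_delta(traj.delta, i0, i1)
    signs = traj.signs
    return float(
        _NCM_TO_J * np.sum(-signs * M_alpha * dalpha + signs * M_delta * ddelta)
    )


def _snap_index(traj, which, t, default, config=None, after_t=0.0) -> int:
    if t is not None:
        return int(np.searchsorted(traj.times, t))
    st = detect_state(traj, which, config, after_t=after_t)
    if st is None:
        return default
    return st.index


def energy_landscape(
    traj: Trajectory, tendon_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Tendon energy over the deformation of its distal joint.

    Returns the paired series ``(delta_deg, U_t_J)`` for the selected
    tendon of a run driven from flat through folded — the asymmetric
    bistable landscape with minima at the 3-degree overbend and near the
    180-degree fold, separated by the barrier at 0 degrees.
    """
    delta = traj.delta[:, tendon_index]
    u = tendon_energy(traj.k, traj.tendon_lengths[:, tendon_index], traj.l_r)
    return delta, u


def theoretical_minima(model: WingModel, k: float | None = None, l_r: float | None = None):
    """Local minima of the decoupled multi-tendon energy landscape, Joules.

    Treating the tendons independently, folding ``m`` of the ``S`` joints
    releases their flat-state energy, so the landscape has minima at
    ``(S - m) * U_flat`` for ``m = 0 .. S`` (descending order returned).
    The folded tendon is slack (length below resting length) and stores
    nothing.
    """
    elastic = model.elastic_tendons()
    k = elastic[0].k if k is None else k
    l_r = elastic[0].l_r if l_r is None else l_r
    u_flat = [tendon_energy(k, t.l_init, l_r) for t in elastic]
    u_sorted = sorted(u_flat, reverse=True)
    total = sum(u_sorted)
    minima = [total]
    for u in u_sorted:
        total -= u
        minima.append(total)
    return minima


@dataclass
class EnergyReport:
    """State and transition energies of one fold/unfold run (Joules).

    ``t_a``/``t_b``/``t_c`` are the snapshot times actually used: the
    values are sensitive to the exact timestep selected, so the report
    carries them instead of hiding them.  ``U_b`` may exceed zero for
    short resting lengths because the model oscillates and self-penetrates
    in the folded state (no contact forces), leaving residual elongation.
    """

    U_a: float
    U_b: float
    U_c: float | None
    E_ab: float | None
    E_bc: float | None
    t_a: float
    t_b: float | None
    t_c: float | None
    U_tendons_a: np.ndarray | None = None
    U_tendons_b: np.ndarray | None = None


def build_energy_report(
    traj: Trajectory,
    M_alpha: float,
    M_delta: float = 0.0,
    config: DetectionConfig | None = None,
) -> EnergyReport:
    """Assemble the energy bookkeeping of a fold (and optional unfold) run."""
    a = detect_state(traj, "a", config)
    b = detect_state(traj, "b", config)
    unfold_onset = traj.events.get("unfold_onset")
    c = (
        detect_state(traj, "c", config, after_t=unfold_onset)
        if unfold_onset is not None
        else None
    )
    i_a = a.index if a is not None else 0
    u_t = tendon_energy(traj.k, traj.tendon_lengths, traj.l_r)

    U_a = float(u_t[i_a].sum())
    U_b = float(u_t[b.index].sum()) if b is not None else float("nan")
    U_c = float(u_t[c.index].sum()) if c is not None else None
    E_ab = fold_input_energy(traj, M_alpha, config=config) if b is not None else None
    E_bc = (
        unfold_input_energy(traj, M_alpha, M_delta, config=config)
        if (c is not None and b is not None)
        else None
    )
    return EnergyReport(
        U_a=U_a,
        U_b=U_b,
        U_c=U_c,
        E_ab=E_ab,
        E_bc=E_bc,
        t_a=float(traj.times[i_a]),
        t_b=float(traj.times[b.index]) if b is not None else None,
        t_c=float(traj.times[c.index]) if c is not None else None,
        U_tendons_a=u_t[i_a].copy(),
        U_tendons_b=u_t[b.index].copy() if b is not None else None,
    )
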