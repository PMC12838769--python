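"""Actuation schedules, state detection, and the flat-state lock."""

import numpy as np
import pytest

from fanfold import (
    ACCELERATED_FOLD_TORQUE,
    SimConfig,
    detect_state,
    folding_time,
    make_fold_schedule,
    make_unfold_schedule,
    run_simulation,
)
from fanfold.dynamics import BatchSim, phase_to_trajectories, run_phase
from fanfold.model import build_wing_model


def test_fold_schedule_has_no_distal_torque():
    sched = make_fold_schedule(20.0)
    assert sched.M_delta == 0.0
    ta, td = sched.torques(np.array([1.0, -1.0, 1.0]))
    assert np.all(td == 0.0)
    assert abs(ta[0]) == 20.0 and ta[0] == -ta[1] == ta[2]  # alternating


def test_unfold_schedule_actuates_both_families():
    sched = make_unfold_schedule(M_delta=20.0, M_alpha=20.0)
    ta, td = sched.torques(np.array([1.0, -1.0, 1.0]))
    assert np.all(np.abs(ta) == 20.0) and np.all(np.abs(td) == 20.0)
    # joint i and i+1 receive opposite torque signs
    assert td[0] == -td[1] == td[2]


def test_negative_magnitude_rejected():
    with pytest.raises(ValueError):
        make_fold_schedule(-1.0)
    with pytest.raises(ValueError):
        make_unfold_schedule(-1.0, 0.0)


def test_accelerated_fold_torque_constant():
    assert ACCELERATED_FOLD_TORQUE == 500.0


def test_initial_state_is_flat(standard_model):
    cfg = SimConfig(duration=2.0, record_stride=4)
    traj = run_simulation(standard_model, make_fold_schedule(0.0), cfg)
    a = detect_state(traj, "a")
    assert a is not None and a.t == 0.0
    assert a.label == "a_flat"


def test_fold_detection_and_folding_time(pattern):
    model = build_wing_model(pattern, k=10.0, l_r=0.0)
    cfg = SimConfig(duration=30.0, record_stride=10)
    traj = run_simulation(model, make_fold_schedule(20.0), cfg)
    b = detect_state(traj, "b")
    assert b is not None and b.label == "b_folded"
    ft = folding_time(traj)
    assert ft is not None and 0.0 < ft < 30.0
    # fold angles sustained at the stack
    fold_depth = np.abs(traj.delta[b.index:] * traj.signs[None, :])
    assert fold_depth.min() >= 170.0


def test_not_reached_returns_none(standard_model):
    cfg = SimConfig(duration=2.0, record_stride=4)
    traj = run_simulation(standard_model, make_fold_schedule(0.0), cfg)
    assert detect_state(traj, "b") is None
    assert folding_time(traj) is None


def test_unfold_reaches_opened_state(pattern):
    """From the settled folded state, distal + proximal torque re-opens the
    ring fold and the radial fold."""
    model = build_wing_model(pattern, k=10.0, l_r=9.0)
    cfg = SimConfig(duration=30.0, record_stride=10)
    sched = make_unfold_schedule(40.0, 40.0)
    sim = BatchSim(model, 10.0, 9.0, cfg)
    sim.set_folded()
    rec = run_phase(sim, cfg.duration, 40.0, 40.0, sched.dir_alpha, sched.dir_delta)
    traj = phase_to_trajectories(sim, rec)[0]
    c = detect_state(traj, "c")
    assert c is not None and c.label == "c_opened"


def test_folded_state_is_stable_without_input(pattern):
    """Bistability: with zero torque the folded state persists."""
    model = build_wing_model(pattern, k=10.0, l_r=0.0)
    cfg = SimConfig(duration=10.0, record_stride=10)
    sim = BatchSim(model, 10.0, 0.0, cfg)
    sim.set_folded()
    rec = run_phase(sim, cfg.duration, 0.0, 0.0, 1.0, 1.0)
    traj = phase_to_trajectories(sim, rec)[0]
    assert np.all(np.abs(traj.delta[-1] * traj.signs) > 170.0)


def test_flat_lock_against_small_perturbations(standard_model):
    """Perturbing every fold angle by up to 1 degree decays back into the
    flat band: the structural lock of the open wing."""
    cfg = SimConfig(duration=20.0, record_stride=10)
    sim = BatchSim(standard_model, 10.0, 0.0, cfg)
    sim.settle()
    sim._settled = True
    sim.state.q[..., 1] -= sim.c.signs * np.radians(1.0)  # toward the barrier
    rec = run_phase(sim, cfg.duration, 0.0, 0.0, 1.0, 1.0)
    traj = phase_to_trajectories(sim, rec)[0]
    open_end = traj.delta[-1] * traj.signs
    assert np.all(open_end > 0.0) and np.all(open_end < 6.0)
    assert traj.kinetic_energy[-1] < 1e-4


def test_detect_state_rejects_unknown_label(standard_model):
    cfg = SimConfig(duration=1.0, record_stride=4)
    traj = run_simulation(standard_model, make_fold_schedule(0.0), cfg)
    with pytest.raises(ValueError):
        detect_state(traj, "x")
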