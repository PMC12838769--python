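"""Tendon potentials and transition input energies."""

import numpy as np
import pytest

from fanfold import (
    SimConfig,
    build_energy_report,
    build_wing_model,
    energy_landscape,
    fold_input_energy,
    make_fold_schedule,
    run_simulation,
    tendon_energy,
    theoretical_minima,
    unfold_input_energy,
)
from fanfold.dynamics import Trajectory


def _traj(alpha, delta, k=10.0, l_r=0.0, signs=(1, -1, 1)):
    alpha = np.asarray(alpha, dtype=float)
    delta = np.asarray(delta, dtype=float)
    n, s = alpha.shape
    z = np.zeros((n, s))
    return Trajectory(
        times=np.arange(n, dtype=float),
        alpha=alpha,
        delta=delta,
        tendon_lengths=np.full((n, s), 11.0),
        guide_lengths=np.zeros((n, 2)),
        tendon_forces=z.copy(),
        torque_alpha=z.copy(),
        torque_delta=z.copy(),
        kinetic_energy=np.zeros(n),
        signs=np.array(signs, dtype=float),
        k=k,
        l_r=l_r,
        h=0.005,
    )


def test_tendon_energy_closed_form():
    # 1e-2 * 0.5 * k * (l - l_r)^2
    assert tendon_energy(10.0, 11.0, 0.0) == pytest.approx(6.05)
    assert tendon_energy(60.0, 11.0, 0.0) == pytest.approx(36.3)
    assert tendon_energy(10.0, 5.0, 5.0) == 0.0
    assert tendon_energy(10.0, 3.0, 5.0) == 0.0  # slack stores nothing
    arr = tendon_energy(10.0, np.array([11.0, 5.0]), 5.0)
    assert arr == pytest.approx([1.8, 0.0])


def test_negative_stiffness_rejected():
    with pytest.raises(ValueError):
        tendon_energy(-1.0, 11.0, 0.0)


def test_fold_input_energy_single_joint():
    """One joint displaced by pi at 20 N·cm: E = 1e-2 * 20 * pi ~ 0.628 J."""
    alpha = np.zeros((3, 3))
    alpha[-1, 0] = 180.0
    traj = _traj(alpha, np.zeros((3, 3)))
    e = fold_input_energy(traj, 20.0, t_a=0.0, t_b=2.0)
    assert e == pytest.approx(1e-2 * 20.0 * np.pi, rel=1e-12)


def test_fold_input_energy_zero_displacement():
    traj = _traj(np.zeros((3, 3)), np.zeros((3, 3)))
    assert fold_input_energy(traj, 50.0, t_a=0.0, t_b=2.0) == 0.0


def test_unfold_input_energy_alternating_signs():
    """Eq: E_bc = 1e-2 sum_i [(-1)^i Ma da_i + (-1)^(i+1) Md dd_i]."""
    alpha = np.zeros((2, 3))
    delta = np.zeros((2, 3))
    delta[-1] = [180.0, -180.0, 180.0]  # opening displacement, alternating
    alpha[-1] = [-10.0, 10.0, -10.0]
    traj = _traj(alpha, delta)
    e = unfold_input_energy(traj, M_alpha=20.0, M_delta=20.0, t_b=0.0, t_c=1.0)
    expected = 1e-2 * (3 * 20.0 * np.pi + 3 * 20.0 * np.radians(10.0))
    assert e == pytest.approx(expected, rel=1e-12)
    assert unfold_input_energy(traj, 0.0, 0.0, t_b=0.0, t_c=1.0) == 0.0


def test_theoretical_three_tendon_minima(standard_model):
    minima = theoretical_minima(standard_model, k=10.0, l_r=0.0)
    assert [round(m) for m in minima] == [18, 12, 6, 0]
    assert all(a > b for a, b in zip(minima, minima[1:]))


def test_flat_energy_monotone_in_k_and_lr(standard_model):
    """U_a increases with stiffness and decreases with resting length."""
    l_i = standard_model.elastic_tendons()[0].l_init
    by_k = [tendon_energy(k, l_i, 0.0) for k in range(10, 70, 10)]
    assert np.all(np.diff(by_k) > 0)
    by_lr = [tendon_energy(10.0, l_i, lr) for lr in range(0, 10)]
    assert np.all(np.diff(by_lr) < 0)


def test_energy_landscape_is_bistable(pattern):
    """Driving through the fold traces two minima separated by the barrier
    at zero: energy high near 0 deg, released at the fold."""
    model = build_wing_model(pattern, k=10.0, l_r=0.0)
    cfg = SimConfig(duration=30.0, record_stride=5)
    traj = run_simulation(model, make_fold_schedule(20.0), cfg)
    delta, u = energy_landscape(traj, tendon_index=0)
    assert delta.min() < -175.0 and delta.max() > 2.0
    near_barrier = np.abs(delta) < 5.0
    folded = delta < -170.0
    assert near_barrier.any() and folded.any()
    assert u[near_barrier].max() > 5.0  # ~6 J stored at the barrier crest
    assert u[folded].max() < 0.2  # released at the fold


def test_energy_report_orders_states(pattern):
    model = build_wing_model(pattern, k=10.0, l_r=0.0)
    cfg = SimConfig(duration=30.0, record_stride=10)
    traj = run_simulation(model, make_fold_schedule(20.0), cfg)
    rep = build_energy_report(traj, M_alpha=20.0)
    assert rep.U_a > rep.U_b  # flat state stores far more than the fold
    assert rep.t_b is not None and rep.t_b > rep.t_a
    assert rep.U_tendons_a.shape == (3,)
    assert rep.U_a == pytest.approx(3 * tendon_energy(10.0, traj.tendon_lengths[0, 0], 0.0), rel=0.05)
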