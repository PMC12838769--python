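"""Parameter-sweep classification, export and timestep scan."""

import json

import numpy as np
import pandas as pd
import pytest

from fanfold import (
    SimConfig,
    SweepGrid,
    build_wing_model,
    export_sweep,
    run_fold_sweep,
    run_unfold_sweep,
    timestep_scan,
)


@pytest.fixture(scope="module")
def small_fold_result(pattern):
    model = build_wing_model(pattern)
    grid = SweepGrid(
        k_values=(10.0,),
        l_r_values=(0.0, 9.0),
        fold_torques=(0.0, 20.0, 40.0),
        fold_duration=60.0,
    )
    return grid, run_fold_sweep(grid, model)


@pytest.fixture(scope="module")
def small_unfold_result(pattern):
    model = build_wing_model(pattern)
    grid = SweepGrid(
        k_values=(10.0, 60.0),
        l_r_values=(0.0, 9.0),
        unfold_torques=(40.0, 100.0),
        unfold_duration=60.0,
    )
    return grid, run_unfold_sweep(grid, model)


def test_grid_validation():
    with pytest.raises(ValueError):
        SweepGrid(k_values=())
    with pytest.raises(ValueError):
        SweepGrid(l_r_values=(3.0, 1.0))


def test_fold_sweep_cells_and_aggregates(small_fold_result):
    grid, res = small_fold_result
    assert len(res.cells) == len(grid.k_values) * len(grid.l_r_values)
    assert res.aggregates["n_fold_success"] == int(res.cells["fold_success"].sum())
    ok = res.cells[res.cells["fold_success"]]
    assert len(ok) >= 1  # k=10, lr=0 folds within the tested torques
    assert set(ok["min_fold_torque"]).issubset(set(grid.fold_torques))
    assert (ok["folding_time_s"] > 0).all()
    assert (ok["E_ab_J"].abs() < 5.0).all()
    assert (ok["U_a_J"] > ok["U_b_J"]).all()


def test_zero_torque_never_folds(small_fold_result):
    _, res = small_fold_result
    assert not (res.cells["min_fold_torque"] == 0.0).any()


def test_unfold_sweep_structure(small_unfold_result):
    grid, res = small_unfold_result
    cells = res.cells
    assert len(cells) == 4
    assert cells["folded_start_ok"].all()
    ok = cells[cells["unfold_success"]]
    # soft tendons with long resting length unfold; stiff short ones resist
    assert bool(ok[(ok.k == 10.0) & (ok.l_r == 9.0)].shape[0])
    stiff = cells[(cells.k == 60.0) & (cells.l_r == 0.0)]
    assert not bool(stiff["unfold_success"].iloc[0])
    assert (ok["E_bc_J"] > 0).all()


def test_export_roundtrip_and_determinism(small_fold_result, tmp_path):
    _, res = small_fold_result
    p1 = export_sweep(res, tmp_path / "a.csv", tmp_path / "a.json")
    p2 = export_sweep(res, tmp_path / "b.csv", tmp_path / "b.json")
    assert p1.read_bytes() == p2.read_bytes()
    assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
    rows = pd.read_csv(p1)
    assert len(rows) == len(res.cells)
    payload = json.loads((tmp_path / "a.json").read_text())
    assert payload["aggregates"]["n_fold_success"] == res.aggregates["n_fold_success"]
    assert isinstance(payload["feasibility_boundary"], list)


def test_sweep_deterministic(pattern):
    model = build_wing_model(pattern)
    grid = SweepGrid(
        k_values=(10.0,), l_r_values=(0.0,), fold_torques=(20.0,), fold_duration=20.0
    )
    a = run_fold_sweep(grid, model).cells
    b = run_fold_sweep(grid, model).cells
    pd.testing.assert_frame_equal(a, b)


def test_timestep_scan_single_h(standard_model):
    table = timestep_scan(
        standard_model, h_values=(0.005,), fold_duration=20.0, unfold_duration=30.0
    )
    assert len(table) == 1
    assert np.isfinite(table["t_fold_s"].iloc[0])


def test_timestep_scan_columns(standard_model):
    table = timestep_scan(
        standard_model, h_values=(0.004, 0.005), fold_duration=20.0, unfold_duration=30.0
    )
    assert list(table["h_s"]) == [0.004, 0.005]
    assert "t_fold_s_rel_spread" in table.columns
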