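"""Tensile-test analysis: strain/stress, secant modulus, sizing, fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fanfold import (
    TensileDataset,
    compute_strain_stress,
    generate_synthetic_tensile,
    hysteresis_energy,
    modulus_profile,
    read_tensile_csv,
    size_tendon,
    write_tensile_csv,
)


def test_strain_stress_unit_arithmetic():
    df = pd.DataFrame(
        {"sample_id": [1, 1], "cycle": [1, 1], "elongation_mm": [0.0, 60.0], "force_N": [0.0, 6.0]}
    )
    out = compute_strain_stress(TensileDataset(df))
    assert out["strain"].tolist() == [0.0, 1.0]  # 60 mm on l0 = 60 mm
    assert out["stress_MPa"].tolist() == [0.0, 1.0]  # 6 N on 6 mm^2


def test_zero_dimensions_rejected():
    df = pd.DataFrame({"sample_id": [1], "cycle": [1], "elongation_mm": [1.0], "force_N": [1.0]})
    with pytest.raises(ValueError):
        TensileDataset(df, l0_mm=0.0)
    with pytest.raises(ValueError):
        TensileDataset(df, a0_mm2=0.0)


def test_modulus_recovery_linear_zero_noise():
    """A linear-elastic fixture is recovered to < 1% in every strain bin."""
    data = generate_synthetic_tensile(
        e_base_mpa=10.0, stiffening=0.0, hysteresis=0.0, first_cycle_softening=0.0,
        noise_sd=0.0, seed=7,
    )
    prof = modulus_profile(data)
    assert np.all(np.abs(prof.table["E_mean_MPa"] - 10.0) / 10.0 < 0.01)


def test_modulus_recovery_with_noise():
    data = generate_synthetic_tensile(
        e_base_mpa=10.0, stiffening=0.0, hysteresis=0.0, first_cycle_softening=0.0,
        noise_sd=0.05, seed=7,
    )
    prof = modulus_profile(data)
    assert np.all(np.abs(prof.table["E_mean_MPa"] - 10.0) / 10.0 < 0.05)


def test_first_cycle_excluded():
    """Profiles are invariant to arbitrary corruption of cycle-1 data."""
    data = generate_synthetic_tensile(seed=3)
    corrupted = TensileDataset(data.data.copy(), data.l0_mm, data.a0_mm2)
    mask = corrupted.data["cycle"] == 1
    corrupted.data.loc[mask, "force_N"] = 1e6
    a = modulus_profile(data).table
    b = modulus_profile(corrupted).table
    pd.testing.assert_frame_equal(a, b)


def test_single_cycle_dataset_rejected():
    data = generate_synthetic_tensile(n_cycles=1, seed=1)
    with pytest.raises(ValueError):
        modulus_profile(data)


def test_tpu_like_modulus_bounded():
    """The default elastomer fixture stays below ~40 MPa secant modulus."""
    prof = modulus_profile(generate_synthetic_tensile(seed=11))
    assert prof.e_max_mpa <= 40.0


def test_unloading_zero_force_plateau():
    data = generate_synthetic_tensile(seed=5)
    df = compute_strain_stress(data)
    one = df[(df["sample_id"] == 1) & (df["cycle"] == 2)]
    n_load = len(one) // 2
    unload = one.iloc[n_load:]
    below = unload[unload["strain"] < 0.35 - 1e-9]
    assert np.allclose(below["force_N"], 0.0, atol=1e-12)


def test_zero_hysteresis_branches_coincide():
    data = generate_synthetic_tensile(hysteresis=0.0, noise_sd=0.0, seed=2)
    loops = hysteresis_energy(data)
    assert np.allclose(loops["loop_mJ"], 0.0, atol=1e-9)


@given(
    hyst=st.floats(0.0, 1.0),
    soft=st.floats(0.0, 0.5),
    noise=st.floats(0.0, 0.05),
    seed=st.integers(0, 2**16),
)
@settings(max_examples=25, deadline=None)
def test_hysteresis_loop_area_nonnegative(hyst, soft, noise, seed):
    data = generate_synthetic_tensile(
        hysteresis=hyst, first_cycle_softening=soft, noise_sd=noise,
        n_samples=1, n_cycles=2, n_points=60, seed=seed,
    )
    loops = hysteresis_energy(data)
    assert (loops["loop_mJ"] > -1e-6).all()


def test_generator_deterministic_per_seed():
    a = generate_synthetic_tensile(noise_sd=0.03, seed=9).data
    b = generate_synthetic_tensile(noise_sd=0.03, seed=9).data
    c = generate_synthetic_tensile(noise_sd=0.03, seed=10).data
    pd.testing.assert_frame_equal(a, b)
    assert not a["force_N"].equals(c["force_N"])


@pytest.mark.parametrize(
    "k_target, expected_mm2",
    [(10.0, 12.5), (60.0, 75.0), (4.0, 5.0)],
)
def test_tendon_sizing_proportional_to_area(k_target, expected_mm2):
    assert size_tendon(k_target, k_measured=4.0, a_measured_mm2=5.0) == pytest.approx(expected_mm2)


def test_tendon_sizing_rejects_nonpositive():
    with pytest.raises(ValueError):
        size_tendon(10.0, 0.0, 5.0)


def test_csv_roundtrip(tmp_path):
    data = generate_synthetic_tensile(n_samples=2, n_cycles=2, n_points=20, seed=4)
    path = tmp_path / "tensile.csv"
    write_tensile_csv(data, path)
    back = read_tensile_csv(path)
    pd.testing.assert_frame_equal(back.data, data.data, check_dtype=False)
    assert back.l0_mm == data.l0_mm
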