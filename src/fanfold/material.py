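"""Cyclic tensile-test analysis and physical tendon sizing.

Printed elastomer tendons (e.g. TPU) are characterised by cyclic uniaxial
tests: engineering strain eps = dl / l0, engineering stress sigma = F / A0,
and a pointwise secant Young's modulus E = sigma / eps at every measuring
point.  The first cycle is excluded (Mullins-effect softening and initial
creep make it unrepresentative), and the remaining points are binned by
strain in 10% increments to characterise the modulus distribution locally
within the loading and unloading branches.

The module also sizes a physical tendon against a simulated stiffness
target — at fixed length and modulus, axial stiffness is proportional to
the cross-sectional area — and generates synthetic cyclic datasets
emulating the features of elastomer tests: loading/unloading hysteresis,
first-cycle softening, and a zero-force plateau on unloading below a
strain threshold.

Note the two distinct cross-section fields: the tensile test specimen area
(6 mm^2) and the printed tendon area (5 mm^2); they are separate
quantities and are never merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TensileDataset",
    "ModulusProfile",
    "compute_strain_stress",
    "modulus_profile",
    "size_tendon",
    "generate_synthetic_tensile",
    "read_tensile_csv",
    "write_tensile_csv",
    "hysteresis_energy",
]

SPECIMEN_L0_MM = 60.0
SPECIMEN_A0_MM2 = 6.0
PRINTED_TENDON_A_MM2 = 5.0


@dataclass
class TensileDataset:
    """Cyclic tensile test data.

    ``data`` columns: sample_id (int), cycle (int, 1-based), elongation_mm,
    force_N; rows ordered within each (sample, cycle).  ``l0_mm`` is the
    specimen gauge length and ``a0_mm2`` the specimen cross-section (not
    the printed tendon's).
    """

    data: pd.DataFrame
    l0_mm: float = SPECIMEN_L0_MM
    a0_mm2: float = SPECIMEN_A0_MM2
    test_speed_mm_min: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"sample_id", "cycle", "elongation_mm", "force_N"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        if self.l0_mm <= 0 or self.a0_mm2 <= 0:
            raise ValueError("l0 and A0 must be positive")
        if (self.data["elongation_mm"] < -1e-9).any():
            raise ValueError("negative elongation in dataset")

    @property
    def n_samples(self) -> int:
        return self.data["sample_id"].nunique()

    @property
    def n_cycles(self) -> int:
        return int(self.data["cycle"].max())


@dataclass
class ModulusProfile:
    """Secant-modulus distribution binned by strain decile.

    ``table`` columns: bin_lo, bin_hi (strain), n, E_mean_MPa, E_median_MPa,
    E_sd_MPa.  ``points`` carries the underlying per-point (eps, sigma, E)
    values for cycles >= 2.
    """

    table: pd.DataFrame
    points: pd.DataFrame

    @property
    def e_max_mpa(self) -> float:
        return float(self.points["E_MPa"].max())


def compute_strain_stress(dataset: TensileDataset) -> pd.DataFrame:
    """Per-point engineering strain and stress.

    eps = dl / l0 (dimensionless); sigma = F / A0, in MPa for F in N and
    A0 in mm^2.
    """
    df = dataset.data.copy()
    df["strain"] = df["elongation_mm"] / dataset.l0_mm
    df["stress_MPa"] = df["force_N"] / dataset.a0_mm2
    return df


def modulus_profile(dataset: TensileDataset, bin_width: float = 0.1) -> ModulusProfile:
    """Pointwise secant modulus E = sigma/eps, binned by strain.

    The first cycle of every sample is excluded; points at zero strain are
    undefined and dropped.
    """
    if dataset.n_cycles < 2:
        raise ValueError("need at least 2 cycles per sample (first cycle is excluded)")
    df = compute_strain_stress(dataset)
    df = df[df["cycle"] >= 2]
    df = df[df["strain"] > 0].copy()
    if df.empty:
        raise ValueError("no nonzero-strain points after first-cycle exclusion")
    df["E_MPa"] = df["stress_MPa"] / df["strain"]
    edges = np.arange(0.0, df["strain"].max() + bin_width, bin_width)
    df["bin"] = np.clip(np.digitize(df["strain"], edges) - 1, 0, len(edges) - 2)
    rows = []
    for b, grp in df.groupby("bin"):
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n": len(grp),
                "E_mean_MPa": grp["E_MPa"].mean(),
                "E_median_MPa": grp["E_MPa"].median(),
                "E_sd_MPa": grp["E_MPa"].std(ddof=1) if len(grp) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows).sort_values("bin_lo").reset_index(drop=True)
    return ModulusProfile(table=table, points=df[["sample_id", "cycle", "strain", "stress_MPa", "E_MPa"]])


def size_tendon(k_target: float, k_measured: float, a_measured_mm2: float) -> float:
    """Required cross-section to reach a target axial stiffness, mm^2.

    At fixed length and modulus, k is proportional to area:
    A_required = A_measured * k_target / k_measured.
    """
    if k_measured <= 0 or a_measured_mm2 <= 0 or k_target <= 0:
        raise ValueError("stiffnesses and area must be positive")
    return a_measured_mm2 * k_target / k_measured


def hysteresis_energy(dataset: TensileDataset) -> pd.DataFrame:
    """Loop area (work dissipated per cycle) per sample and cycle, mJ.

    Computed as the closed contour integral of F dl over each cycle.
    """
    rows = []
    for (sid, cyc), grp in dataset.data.groupby(["sample_id", "cycle"]):
        dl = grp["elongation_mm"].to_numpy()
        f = grp["force_N"].to_numpy()
        dl_c = np.append(dl, dl[0])
        f_c = np.append(f, f[0])
        area = np.trapezoid(f_c, dl_c)  # N*mm = mJ; loading then unloading
        rows.append({"sample_id": sid, "cycle": cyc, "loop_mJ": area})
    return pd.DataFrame(rows)


def generate_synthetic_tensile(
    e_base_mpa: float = 15.0,
    stiffening: float = 1.5,
    hysteresis: float = 0.5,
    first_cycle_softening: float = 0.3,
    unload_zero_strain: float = 0.35,
    noise_sd: float = 0.0,
    n_samples: int = 5,
    n_cycles: int = 5,
    n_points: int = 120,
    max_strain: float = 1.0,
    l0_mm: float = SPECIMEN_L0_MM,
    a0_mm2: float = SPECIMEN_A0_MM2,
    seed: int = 0,
) -> TensileDataset:
    """Synthetic cyclic tensile fixture emulating elastomer behaviour.

    Loading branch: sigma = E(eps) * eps with a secant modulus
    ``E(eps) = e_base * (1 + stiffening * (1 - eps))`` (stiffer at low
    strain, as printed TPU shows).  Unloading branch: force returns to
    zero at ``unload_zero_strain`` and stays zero below it (the plateau
    left by creep and softening), scaled so the loop area fraction is
    controlled by ``hysteresis`` (0 = branches coincide).  The first cycle
    is stiffer by ``first_cycle_softening`` (Mullins-like; later cycles
    identical).  Multiplicative Gaussian noise of ``noise_sd`` is applied
    to forces.  Deterministic for a fixed ``seed``.
    """
    if not 0 <= hysteresis <= 1:
        raise ValueError("hysteresis must be in [0, 1]")
    if not 0 <= unload_zero_strain < max_strain:
        raise ValueError("unload_zero_strain must lie within [0, max_strain)")
    rng = np.random.default_rng(seed)
    half = n_points // 2
    # shared strain grid for both branches: the closed loading/unloading
    # contour then cancels exactly when the branches coincide
    eps_load = np.linspace(0.0, max_strain, half)
    eps_unload = eps_load[::-1]

    def secant(eps):
        return e_base_mpa * (1.0 + stiffening * (1.0 - eps))

    sigma_peak = secant(max_strain) * max_strain
    eps0 = unload_zero_strain if hysteresis > 0 else 0.0

    rows = []
    for sid in range(1, n_samples + 1):
        for cyc in range(1, n_cycles + 1):
            mult = 1.0 + (first_cycle_softening if cyc == 1 else 0.0)
            sig_l = mult * secant(eps_load) * eps_load
            if hysteresis > 0:
                x = np.clip((eps_unload - eps0) / (max_strain - eps0), 0.0, 1.0)
                # exponent > 1 keeps the unloading branch below loading
                p = 1.0 + 3.0 * hysteresis
                sig_u = mult * sigma_peak * x**p
            else:
                sig_u = mult * secant(eps_unload) * eps_unload
            if noise_sd > 0:
                sig_l = np.maximum(sig_l * (1.0 + noise_sd * rng.standard_normal(sig_l.shape)), 0.0)
                sig_u = np.maximum(sig_u * (1.0 + noise_sd * rng.standard_normal(sig_u.shape)), 0.0)
            # a passive, dissipative material never unloads above its
            # loading branch at the same strain
            sig_u = np.minimum(sig_u, sig_l[::-1])
            eps = np.concatenate([eps_load, eps_unload])
            sig = np.concatenate([sig_l, sig_u])
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "cycle": cyc,
                        "elongation_mm": eps * l0_mm,
                        "force_N": sig * a0_mm2,
                    }
                )
            )
    data = pd.concat(rows, ignore_index=True)
    return TensileDataset(
        data=data,
        l0_mm=l0_mm,
        a0_mm2=a0_mm2,
        meta={
            "synthetic": True,
            "e_base_mpa": e_base_mpa,
            "hysteresis": hysteresis,
            "unload_zero_strain": eps0,
            "seed": seed,
        },
    )


def write_tensile_csv(dataset: TensileDataset, path) -> None:
    """Write the dataset in the package CSV dialect (UTF-8, header)."""
    dataset.data.to_csv(path, index=False)


def read_tensile_csv(path, l0_mm: float = SPECIMEN_L0_MM, a0_mm2: float = SPECIMEN_A0_MM2) -> TensileDataset:
    """Read a cyclic tensile CSV with columns sample_id, cycle,
    elongation_mm, force_N."""
    return TensileDataset(data=pd.read_csv(path), l0_mm=l0_mm, a0_mm2=a0_mm2)
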