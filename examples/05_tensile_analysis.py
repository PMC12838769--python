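"""Cyclic tensile-test analysis and physical tendon sizing.

Generates a synthetic cyclic tensile dataset emulating a printed TPU
tendon (hysteresis, first-cycle softening, zero-force plateau below 35%
strain on unloading), derives the strain-binned secant-modulus profile
(first cycle excluded), and sizes the printed tendon cross-section needed
to reach simulated stiffness targets.
"""

from fanfold import (
    generate_synthetic_tensile,
    hysteresis_energy,
    modulus_profile,
    size_tendon,
)

data = generate_synthetic_tensile(seed=42)
print(f"{data.n_samples} samples x {data.n_cycles} cycles, "
      f"l0 = {data.l0_mm} mm, A0 = {data.a0_mm2} mm^2 (test specimen)")

profile = modulus_profile(data)
print(profile.table.to_string(index=False,
      formatters={c: "{:.2f}".format for c in profile.table.columns if c != "n"}))
print(f"max pointwise secant modulus: {profile.e_max_mpa:.1f} MPa "
      "(an elastomer like printed TPU, far stiffer than resilin)")

loops = hysteresis_energy(data)
print("mean dissipated energy per cycle: %.1f mJ" % loops["loop_mJ"].mean())

# sizing the printed tendon (measured ~4 N/cm at 5 mm^2) against the
# simulated stiffness range 10-60 N/cm
for k_target in (10.0, 60.0):
    area = size_tendon(k_target=k_target, k_measured=4.0, a_measured_mm2=5.0)
    print(f"target k = {k_target:>4.0f} N/cm -> required cross-section "
          f"{area:.1f} mm^2")
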