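# fanfold

Bar-and-hinge simulation of dermapteran (earwig) hindwing fan folding.

The earwig hindwing packs away under short leathery forewings with one of
the highest folding ratios among insects, and it is bistable: the radially
pleated anal fan snaps between its open and folded states without any
musculature in the wing itself.  The elasticity lives in resilin-bearing
"broadened vein patches" where the transversal *ring fold* crosses the
radial veins.  `fanfold` is a research tool for studying that mechanism at
an engineering scale — for biomechanists quantifying how finely tuned the
wing's elastic layout must be, and for engineers sizing elastic hinges for
deployable structures modelled after it.

The package provides, as an importable Python library with narrative
examples:

* **Crease patterns** — the simplified fan construction from four
  parameters (`l_proximal`, `l_distal`, `r`, `theta`, plus the unit count
  `n`), flat-foldable iff `n·θ ≤ 90°`, exported as FOLD / SVG / CSV.
* **Bar-and-hinge wing model** — mass-bearing cylindrical bars on the fold
  lines, 3-DoF proximal joints, distal hinges limited to fold to 180° and
  overbend 3° (flipped for every second strut), and tension-only
  spring-damper tendons: force `k (l − l_r)` only while `l > l_r`.
  Emittable as MuJoCo-dialect XML.
* **Dynamics** — reduced-coordinate multibody simulation with the
  semi-implicit Euler scheme `v ← v + h a`, `q ← q + h v` at `h = 0.005 s`,
  compliant joint limits, vectorised over whole parameter sweeps.
* **Energetics** — tendon potential `U_t = 10⁻²·½·k (l_t − l_r)²` J, input
  energies `E_ab`, `E_bc` from the net joint displacements between the
  flat (a), folded (b) and re-opened (c) states.
* **Parameter sweeps** — fold/unfold success maps over stiffness
  `k = 10–60 N/cm`, resting length `l_r = 0–9 cm` and torque, plus a
  timestep-sensitivity scan.
* **Material lab** — cyclic tensile-test analysis for printed elastomer
  tendons (strain/stress, first-cycle-excluded secant modulus binned by
  strain decile), physical tendon sizing, and a synthetic test-data
  generator with hysteresis, Mullins-like softening and an unloading
  zero-force plateau.

## Worked example

```python
import numpy as np
from fanfold import (FanParams, SimConfig, build_folded_geometry,
                     build_wing_model, folding_time, make_fold_schedule,
                     run_simulation, tendon_energy, theoretical_minima,
                     unfold_pattern)

pattern = unfold_pattern(build_folded_geometry(FanParams()))
model = build_wing_model(pattern, k=10.0, l_r=0.0)

l_i = model.elastic_tendons()[0].l_init
print(f"flat-state tendon length: {l_i:.2f} cm")
print(f"stored energy per tendon: {tendon_energy(10.0, l_i, 0.0):.2f} J")
print("landscape minima (0..3 joints folded):",
      [round(m) for m in theoretical_minima(model)])

traj = run_simulation(model, make_fold_schedule(20.0),
                      SimConfig(duration=30.0))
print(f"folding time at 20 N·cm: {folding_time(traj):.1f} s")
```

prints

```
flat-state tendon length: 10.97 cm
stored energy per tendon: 6.01 J
landscape minima (0..3 joints folded): [18, 12, 6, 0]
folding time at 20 N·cm: 0.9 s
```

Each taut tendon of the open wing stores about 6 J; with three tendons the
decoupled energy landscape has minima at 18/12/6/0 J for zero to three
folded joints, and the stored energy — released once the 20 N·cm proximal
torque unlocks the pleats — drives the ring fold closed.  The
`examples/` directory walks through the other capabilities: crease-pattern
export, unfolding energetics, the single-tendon bistable landscape, a
small parameter sweep, and the tensile-test analysis.

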