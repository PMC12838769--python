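"""Unfold one wing section and report its energy bookkeeping.

Builds the standard wing section with 10 N/cm tendons at 9 cm resting
length, starts from the settled folded state, unfolds it with 40 N·cm on
both joint families, and prints the detected states and the energies of
the transition (tendon potentials U_a/U_b/U_c and input energy E_bc).
"""

import numpy as np

from fanfold import (
    FanParams,
    SimConfig,
    build_energy_report,
    build_folded_geometry,
    build_wing_model,
    detect_state,
    make_unfold_schedule,
    run_fold_unfold,
    unfold_pattern,
)

pattern = unfold_pattern(build_folded_geometry(FanParams()))
model = build_wing_model(pattern, k=10.0, l_r=9.0)
print("flat-state tendon lengths [cm]:",
      np.round([t.l_init for t in model.elastic_tendons()], 2))

config = SimConfig(h=0.005, duration=100.0, record_stride=20)
traj = run_fold_unfold(
    model,
    make_unfold_schedule(M_delta=40.0, M_alpha=40.0),
    config,
    unfold_duration=100.0,
)

b = detect_state(traj, "b")
c = detect_state(traj, "c", after_t=traj.events["unfold_onset"])
print("folded state held from t = %s s" % (f"{b.t:.2f}" if b else "never"))
print("re-opened state reached at t = %s s" % (f"{c.t:.2f}" if c else "never"))

report = build_energy_report(traj, M_alpha=40.0, M_delta=40.0)
print(f"U_b = {report.U_b:.3f} J (folded: tendons slack, energy released)")
if report.U_c is not None:
    print(f"U_c = {report.U_c:.3f} J (re-opened: tendons taut again)")
if report.E_bc is not None:
    print(f"E_bc = {report.E_bc:.3f} J of input to unfold — far more than the"
          " folding input: the bistable landscape is asymmetric")
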