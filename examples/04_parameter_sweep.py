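"""Small fold-success sweep over tendon stiffness and resting length.

Runs a reduced grid (a few minutes of CPU) of the full parameter search:
for each (k, l_r) cell the proximal fold torques are tried in ascending
order and the minimum successful torque and folding time are recorded.
Use SweepGrid() defaults for the complete study design.
"""

from fanfold import (
    FanParams,
    SweepGrid,
    build_folded_geometry,
    build_wing_model,
    export_sweep,
    run_fold_sweep,
    unfold_pattern,
)

pattern = unfold_pattern(build_folded_geometry(FanParams()))
model = build_wing_model(pattern)

grid = SweepGrid(
    k_values=(10.0, 20.0),
    l_r_values=(0.0, 5.0, 9.0),
    fold_torques=(0.0, 20.0, 40.0),
    fold_duration=120.0,
)
result = run_fold_sweep(grid, model)
print(result.cells[["k", "l_r", "fold_success", "min_fold_torque", "folding_time_s", "E_ab_J"]]
      .to_string(index=False))
print("aggregates:", result.aggregates)
export_sweep(result, "fold_sweep.csv", "fold_sweep.json")
print("wrote fold_sweep.csv / fold_sweep.json")
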