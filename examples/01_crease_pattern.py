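"""Generate and export the crease pattern of one fan unit.

Builds the folded construction geometry for the standard upscaled wing
section (25 cm proximal and distal segments, 5 cm fan-centre radius, 15
degree segments, one fan unit), unfolds it into the flat crease pattern,
and exports FOLD / SVG / CSV files.
"""

import numpy as np

from fanfold import (
    FanParams,
    build_folded_geometry,
    check_flat_foldability,
    export_pattern,
    struts,
    unfold_pattern,
)

params = FanParams(l_proximal=25.0, l_distal=25.0, r=5.0, theta=15.0, n=1)
print(f"flat-foldable (n*theta = {params.n * params.theta} deg <= 90):",
      check_flat_foldability(params))

folded = build_folded_geometry(params)
print("deflection angles phi_i [deg]:", np.round(folded.phi, 3))
# phi is the acute angle at which each radial fold line crosses the ring
# fold; the distal segments of the flat pattern deviate by 180 - 2*phi.

pattern = unfold_pattern(folded)
print("computed fold lines (2n+3):", pattern.n_computed_folds)
print("fold lines kept in the model (2n+1):", pattern.n_model_folds)

for s in struts(pattern):
    print(f"  strut {s.index} ({s.kind:>20s}, {s.assignment}): "
          f"proximal {s.proximal_length:.2f} cm, distal {s.distal_length:.2f} cm, "
          f"kink {np.degrees(s.kink_angle):.2f} deg")

for fmt in ("fold", "svg", "csv"):
    path = export_pattern(pattern, f"wing_unit.{fmt}")
    print("wrote", path)
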