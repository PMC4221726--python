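"""Compare CI, SBF and TSBF responses on a single bright-field ring cell.

The signed-cosine filters (CI, SBF) measure gradient convergence; the
TSBF rectifies the cosine and weights it by gradient magnitude, so the
dark membrane ring reinforces the response at the cell center from both
of its edges and background noise is suppressed.
"""

import numpy as np

from sbfdetect import FilterParams, SceneSpec, filter_image, generate_brightfield_scene

scene = generate_brightfield_scene(SceneSpec(
    height=128, width=128, n_cells=1, radius_range=(16, 16), seed=5))
r0, c0 = scene.true_centers[0]
center = (int(round(r0)), int(round(c0)))

params = FilterParams()  # r_min 8, r_max 30, 32 lines, band 6, omega 1
for kind in ("CI", "SBF", "TSBF"):
    rm = filter_image(scene.image, params, kind=kind)
    yy, xx = np.mgrid[0:128, 0:128]
    membrane = np.abs(np.hypot(yy - r0, xx - c0) - 16) <= 1.5
    print(f"{kind:4s}: response at center {rm.values[center]:+.4f}, "
          f"mean on membrane {rm.values[membrane].mean():+.4f}, "
          f"map max {rm.values.max():+.4f}")
# TSBF peaks at the center and decays over the membrane; its scale is
# gradient-magnitude units (contrast/pixel) rather than a cosine in [-1,1].
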