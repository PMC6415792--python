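"""Intrinsic order: what alignment before averaging reveals.

Simulates a population of cells whose fiber directions are individually
well ordered but randomly oriented from cell to cell.  The plain population
average of radial orientation functions is flat (cell rotations cancel),
while rotating each correlogram so its preferred direction sits at 90
degrees before averaging reveals the order present inside each cell.
"""

import numpy as np

from cytoorder.correlation import autocorrelate, normalize_origin
from cytoorder.order_analysis import (
    average_population,
    preferred_direction,
    radial_orientation,
    rotate_correlogram,
)
from cytoorder.segmentation import segment_micrograph
from cytoorder.synthetic import generate_fibers, s2_preset

rng = np.random.default_rng(0)
rofs, aligned_rofs = [], []
for k in range(15):
    spec = s2_preset(
        seed=k + 1, n_fibers=35, length_px=80, width_px=3, image_size=(256, 256),
        orientations_deg=((float(rng.uniform(0, 180)), 1.0),),
        angle_jitter_sd_deg=6.0,
    )
    img, _, _ = generate_fibers(spec)
    corr = normalize_origin(autocorrelate(segment_micrograph(img).combined, 40))
    rof = radial_orientation(corr)
    rofs.append(rof)
    pd_deg = preferred_direction(rof)
    aligned_rofs.append(radial_orientation(rotate_correlogram(corr, 90.0 - pd_deg)))

unaligned = average_population(rofs)
aligned = average_population(aligned_rofs)

print(f"cells: {unaligned.n}, each ordered, orientations uniform over [0, 180)")
print(f"unaligned average ROF: max-min = {np.ptp(unaligned.mean):.4f}  (flat)")
print(
    f"aligned average ROF:   max-min = {np.ptp(aligned.mean):.4f}, "
    f"peak at {np.argmax(aligned.mean)} deg"
)
print(
    "Alignment removes whole-cell rotation, so the remaining 90-degree peak\n"
    "measures order within cells, not order of the population."
)
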