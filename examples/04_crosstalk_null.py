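"""Cross-correlation of two networks, with the random-pairing null.

Generates paired two-channel networks that share half their fibers (a
co-localized pair, like two stained cytoskeletons of one cell) and measures
the central peak of their cross-correlogram.  The control cross-correlates
channels from different cells within the largest circle fitting both: any
residual central peak there would be artifactual.
"""

import dataclasses

import numpy as np

from cytoorder.correlation import Correlogram
from cytoorder.crosstalk import central_peak_excess, random_pair_null, same_cell_crosstalk
from cytoorder.synthetic import FiberSpec, elliptical_cell_mask, generate_paired

spec0 = FiberSpec(
    n_fibers=40, length_px=60, width_px=3, image_size=(192, 192),
    orientations_deg=((0.0, 1.0),), angle_jitter_sd_deg=60.0,
)
support = elliptical_cell_mask((192, 192))

cellsA, cellsB = [], []
for k in range(6):
    spec = dataclasses.replace(spec0, seed=k)
    _, _, truthA, truthB = generate_paired(spec, shared_fraction=0.5,
                                           displacement_sd_px=1.0)
    cellsA.append(truthA)
    cellsB.append(truthB)

avg_same, peak_same = same_cell_crosstalk(list(zip(cellsA, cellsB)), max_lag=40)
same_excess = central_peak_excess(Correlogram(avg_same.mean, 112.0, "overlap", "cross"))

avg_null = random_pair_null(
    cellsA, cellsB, seed=0,
    supportsA=[support] * 6, supportsB=[support] * 6,
)
null_excess = central_peak_excess(Correlogram(avg_null.mean, 112.0, "overlap", "cross"))

print(f"cells: 6, channels share 50% of fibers within a cell")
print(f"same-cell peak height:    {peak_same.peak_height:.4f} over background "
      f"{peak_same.background:.4f}")
print(f"same-cell central excess: {same_excess:.4f}")
print(f"random-pair central excess: {null_excess:.4f}  (null, ~0)")
print(
    "A central peak appears only when the two networks overlap in the same\n"
    "cell; pairing channels across cells destroys it."
)
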