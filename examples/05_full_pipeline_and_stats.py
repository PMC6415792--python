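"""Full pipeline on a manifest, with condition statistics.

Builds a small two-condition experiment from synthetic images (one loosely
ordered "control" population and one strongly ordered "stretched"
population, both oriented near 90 degrees to the strain axis), writes the
micrographs and a CSV manifest to a temporary directory, and runs the
complete analysis: segmentation, correlograms, radial orientation
functions, preferred directions, and the condition comparison (two-sample
KS test and Hedges' g on the per-cell ROF value at 90 degrees).
"""

import dataclasses
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from cytoorder.pipeline import AnalysisConfig, run_analysis
from cytoorder.synthetic import generate_fibers, s2_preset

tmp = Path(tempfile.mkdtemp())
rows = []
base = s2_preset(n_fibers=35, length_px=80, width_px=3, image_size=(256, 256))
for c_idx, (cond, jitter) in enumerate([("control", 50.0), ("stretch_8h", 5.0)]):
    for i in range(5):
        spec = dataclasses.replace(
            base, seed=1000 * c_idx + i,
            orientations_deg=((90.0, 1.0),), angle_jitter_sd_deg=jitter,
        )
        img, _, _ = generate_fibers(spec)
        path = tmp / f"{cond}_{i}.tif"
        tifffile.imwrite(path, img.intensities.astype(np.float32))
        rows.append(dict(path=str(path), pixel_size_nm=112.0, channel="actin",
                         cell_id=f"{cond}_{i}", condition=cond))

manifest = tmp / "manifest.csv"
pd.DataFrame(rows).to_csv(manifest, index=False)

result = run_analysis(manifest, AnalysisConfig(output_dir=str(tmp / "out")))

print(f"processed {result.n_processed} cells, skipped {result.n_skipped}")
print("\nper-cell summary (mean by condition):")
print(result.per_cell.groupby("condition")[["rof_at_90", "intrinsic_rof_at_90"]]
      .mean().round(4))
print("\ncondition comparison (ROF at 90 deg):")
cols = ["metric", "n1", "n2", "D", "p", "g"]
print(result.comparisons[cols].round(4).to_string(index=False))
print(
    "\nNegative g means the second condition (stretch) has the larger ROF\n"
    "value at 90 degrees, i.e. stronger order perpendicular to the strain\n"
    f"axis. Full tables were written to {tmp/'out'}."
)
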