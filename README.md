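# cytoorder

Quantification of cytoskeletal order in fluorescence micrographs by
binary-mask correlation analysis.

Cells exposed to cyclic substrate strain reorganise their cytoskeletons:
stress fibers, microtubules and intermediate filaments align away from the
stretch axis and become more regularly spaced. `cytoorder` implements a
two-step, essentially parameter-free analysis of this process for
researchers working with immunofluorescence images of single cells:

1. **Segmentation.** Each micrograph is converted into a binary mask of
   fibrous structures: a global triangle (Zack) threshold on the gray-value
   histogram separates the cell from the background, a Niblack-style local
   threshold `G(i,j) > m + s/2` — with `m` and `s` the weighted mean and
   standard deviation of gray values in a circular neighbourhood of radius
   7 px — selects thin, high-local-variance structures, the two masks are
   combined by logical AND, and isolated single pixels are removed.
2. **Correlation.** From the `N × M` mask (the smallest rectangle enclosing
   the cell), the overlap-normalized autocorrelogram

   ```
   AC(i,j) = [ Σ_{k,l} I(k,l) · I(k+i, l+j) ] / ((N−|i|)(M−|j|))
   ```

   is computed by zero-padded FFT. `AC(i,j)` is the joint probability that
   two pixels separated by the lag `(i,j)` both lie on a fiber, so it decays
   slowest along the dominant fiber direction.

From the correlogram the package derives:

- the **radial orientation function (ROF)**: the mean origin-normalized
  correlation in 1°-wide angular slices of a 9–21 px annulus (1.01–2.35 µm
  at the common 112 nm pixel size) — a measure of orientational order; the
  angle of its absolute maximum is the cell's **preferred direction**;
- **translational order**: line profiles of the correlogram along the
  preferred direction, including a fiber-length estimate from the linear
  decay;
- **intrinsic order**: each correlogram is rotated so its preferred
  direction sits at 90° *before* population averaging, which separates
  order within cells from alignment of whole cells;
- **inter-network similarity**: cross-correlograms `CC(i,j)` of two
  channels of the same cell (same formula, two masks), quantified by the
  central peak height over the background, with two controls — restriction
  to the largest circle inscribed in the cell, and a random-cell-pairing
  null in which a central peak can only be artifactual;
- **statistics**: two-sample Kolmogorov–Smirnov tests and the
  bias-corrected standardized mean difference (Hedges' g,
  `g = b(⟨x₁⟩−⟨x₂⟩)/s_p`, `b = 1 − 3/(4(n₁+n₂)−9)`) on per-cell ROF values
  at 90°.

A seeded synthetic-data generator (bright rectangles over background with
PSF blur, shot noise and read noise, plus ground-truth masks) provides the
validation test bed, including paired two-channel networks with a tunable
shared-fiber fraction.

## Worked example

`examples/02_orientation_and_length.py` renders the standard validation
image — one hundred 5 × 200 px rectangles oriented at 34° to the vertical
(strain) axis with realistic intensity noise — and reads both quantities
back through the full pipeline:

```
$ python examples/02_orientation_and_length.py
generating orientation:  34.0 deg from vertical
preferred direction:     33 deg (1-degree slices)
ridge-refined direction: 34.00 deg
generating length:       200 px
recovered length:        204 px
```

The preferred direction (1° resolution) lands within the annulus slice
adjacent to the generating angle; the length estimate — the lag at which
the fitted linear decay of the along-fiber profile meets the background —
recovers the 200 px rectangle length within a few percent. The other
examples demonstrate segmentation (`01`), intrinsic order via correlogram
alignment (`03`), cross-correlation with the random-pairing null (`04`)
and the full manifest-driven pipeline with statistics (`05`).

## Command line

A thin CLI wraps the library:

```
cytoorder simulate --preset s2 --seed 1 --out-prefix /tmp/s2
cytoorder segment IMAGE.tif --pixel-size-nm 112 --out-prefix /tmp/cell
cytoorder order MASK.tif --out rof.csv
cytoorder crosstalk MASK_A.tif MASK_B.tif --region inscribed_circle
cytoorder run manifest.csv --out results/
```

`run` consumes a CSV manifest (`path, pixel_size_nm, channel, cell_id,
condition`) and writes per-cell tables, per-condition averaged ROFs with
between-cell SEM, crosstalk peak tables and pairwise condition statistics,
along with the resolved configuration for provenance.

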