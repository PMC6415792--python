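"""Two-step segmentation of fibrous cytoskeletal structures.

Step one finds the cell: a global triangle threshold on the gray-value
histogram separates the (dark) background mode from the bright tail.  Step
two finds the fibers: a Niblack-style local threshold ``G > m + s/2`` where
``m`` and ``s`` are the weighted mean and standard deviation of gray values
in a circular neighbourhood (radius 7 px by default).  Pixel weights are the
fraction of each pixel's unit area inside the circle, which suppresses the
orientation-dependent response a hard square kernel would show on a pixel
grid.  The two masks are combined with a logical AND and isolated
single-pixel regions are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from cytoorder.imaging_io import Micrograph

DEFAULT_NIBLACK_RADIUS_PX = 7
TRIANGLE_BINS = 256

MASK_PROVENANCES = ("cell", "fiber", "combined", "synthetic-truth")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean fiber/cell mask on an N x M pixel grid."""

    values: np.ndarray
    pixel_size_nm: float
    provenance: str = "combined"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=bool)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.provenance not in MASK_PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def coverage(self) -> float:
        """Fraction of set pixels (the mask's area coverage)."""
        return float(self.values.mean())


@dataclass(frozen=True)
class NiblackLocalStats:
    """Per-pixel weighted local mean and standard deviation."""

    m: np.ndarray
    s: np.ndarray
    radius_px: float


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle (Zack) threshold on a gray-value histogram.

    A line is drawn from the histogram's absolute maximum to the highest
    occupied gray level; the threshold is the gray level whose histogram
    point lies farthest (perpendicular distance) from that line.  Pixels
    strictly above the threshold level are foreground.

    Parameters
    ----------
    histogram
        Counts per gray level (bin index = gray level).

    Returns
    -------
    int
        Index of the threshold gray level.
    """
    counts = np.asarray(histogram, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must be a 1-D array of counts")
    occupied = np.nonzero(counts > 0)[0]
    if occupied.size < 2:
        raise ValueError("degenerate histogram: fewer than two occupied gray levels")
    peak = int(np.argmax(counts))  # ties break to the lowest gray value
    hi = int(occupied[-1])
    if hi == peak:
        # Peak sits at the brightest occupied level; the bright tail is the
        # other direction.  Mirror the construction toward the lowest level.
        hi = int(occupied[0])
    x0, y0 = float(peak), counts[peak]
    x1, y1 = float(hi), counts[hi]
    lo, hiidx = (peak, hi) if peak < hi else (hi, peak)
    xs = np.arange(lo, hiidx + 1, dtype=float)
    ys = counts[lo : hiidx + 1]
    # Perpendicular distance of (x, y) to the line through (x0,y0)-(x1,y1).
    dist = np.abs((y1 - y0) * xs - (x1 - x0) * ys + x1 * y0 - y1 * x0)
    return int(lo + np.argmax(dist))


def circular_weights(radius_px: float, n_quad: int = 257) -> np.ndarray:
    """Area-fraction weight kernel for a circular neighbourhood.

    The weight of each pixel equals the fraction of its unit area lying
    inside the circle of the given radius centered on the kernel center:
    1 for pixels fully inside, 0 fully outside, fractional on the rim (rim
    fractions via midpoint quadrature of the clipped circle height).
    """
    if radius_px < 1:
        raise ValueError("radius must be >= 1 px")
    r = float(radius_px)
    half = int(np.ceil(r + 0.5))
    coords = np.arange(-half, half + 1, dtype=float)
    cc, rr = np.meshgrid(coords, coords)
    # distance from kernel center to nearest / farthest corner of each pixel
    near = np.hypot(np.maximum(np.abs(rr) - 0.5, 0), np.maximum(np.abs(cc) - 0.5, 0))
    far = np.hypot(np.abs(rr) + 0.5, np.abs(cc) + 0.5)
    w = np.zeros_like(rr)
    w[far <= r] = 1.0
    rim = (near < r) & (far > r)
    xs_unit = (np.arange(n_quad) + 0.5) / n_quad  # midpoint nodes in (0, 1)
    for i, j in zip(*np.nonzero(rim)):
        x0, x1 = cc[i, j] - 0.5, cc[i, j] + 0.5
        y0, y1 = rr[i, j] - 0.5, rr[i, j] + 0.5
        x = x0 + xs_unit * (x1 - x0)
        inside = np.abs(x) < r
        h = np.zeros(n_quad)
        half_chord = np.sqrt(np.maximum(r * r - x[inside] ** 2, 0.0))
        top = np.minimum(y1, half_chord)
        bot = np.maximum(y0, -half_chord)
        h[inside] = np.maximum(top - bot, 0.0)
        w[i, j] = h.mean() * (x1 - x0)
    return (w + w.T) / 2.0  # enforce the exact dihedral symmetry of the disc


def niblack_local_stats(
    img: Micrograph | np.ndarray, radius_px: float = DEFAULT_NIBLACK_RADIUS_PX
) -> NiblackLocalStats:
    """Weighted local mean and population standard deviation per pixel.

    At image borders the kernel is truncated to in-image pixels and the
    weight sum renormalized, so border statistics are unbiased by padding.
    """
    g = img.intensities if isinstance(img, Micrograph) else np.asarray(img, float)
    w = circular_weights(radius_px)
    wsum = ndimage.convolve(np.ones_like(g), w, mode="constant", cval=0.0)
    m = ndimage.convolve(g, w, mode="constant", cval=0.0) / wsum
    ex2 = ndimage.convolve(g * g, w, mode="constant", cval=0.0) / wsum
    s = np.sqrt(np.maximum(ex2 - m * m, 0.0))
    return NiblackLocalStats(m=m, s=s, radius_px=float(radius_px))


def niblack_mask(
    img: Micrograph, radius_px: float = DEFAULT_NIBLACK_RADIUS_PX
) -> BinaryMask:
    """Variance-based fiber mask: pixel set iff ``G > m + s/2``.

    Thin fibrous structures carry high local gray-value variance in at least
    one direction, so this local criterion selects them while rejecting
    smooth background and out-of-focus haze.  Constant regions yield no
    foreground (the inequality is strict).
    """
    if radius_px < 1:
        raise ValueError("radius must be >= 1 px")
    stats = niblack_local_stats(img, radius_px)
    g = img.intensities
    # strict inequality up to float round-off, so constant regions (G == m,
    # s == 0 in exact arithmetic) are never foreground
    eps = 1e-9 * (1.0 + np.abs(g))
    values = g > stats.m + stats.s / 2.0 + eps
    return BinaryMask(values=values, pixel_size_nm=img.pixel_size_nm, provenance="fiber")


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def remove_isolated_pixels(mask: BinaryMask) -> BinaryMask:
    """Clear set pixels that have no set 8-neighbor (single-pixel specks).

    A lone diagonal neighbor keeps a pixel: 1-px-wide diagonal fibers must
    survive.
    """
    v = mask.values
    neighbors = ndimage.convolve(
        v.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant", cval=0
    )
    return replace(mask, values=v & (neighbors > 0))


def _intensity_histogram(g: np.ndarray, bins: int = TRIANGLE_BINS):
    lo, hi = float(g.min()), float(g.max())
    if hi == lo:
        raise ValueError("degenerate histogram: constant image")
    counts, edges = np.histogram(g, bins=bins, range=(lo, hi))
    return counts, edges


def cell_mask_triangle(img: Micrograph, bins: int = TRIANGLE_BINS) -> BinaryMask:
    """Cell mask from the triangle threshold on the full-image histogram."""
    counts, edges = _intensity_histogram(img.intensities, bins)
    t = triangle_threshold(counts)
    # foreground strictly above the threshold level = above its bin's upper edge
    thr = edges[t + 1]
    values = img.intensities > thr
    return BinaryMask(values=values, pixel_size_nm=img.pixel_size_nm, provenance="cell")


def bounding_box(mask: BinaryMask) -> tuple[int, int, int, int]:
    """Smallest rectangle enclosing set pixels: (row0, row1, col0, col1), half-open."""
    rows = np.nonzero(mask.values.any(axis=1))[0]
    cols = np.nonzero(mask.values.any(axis=0))[0]
    if rows.size == 0:
        raise ValueError("no cell detected: mask is empty")
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


@dataclass(frozen=True)
class SegmentationResult:
    cell_mask: BinaryMask
    fiber_mask: BinaryMask
    combined: BinaryMask
    bbox: tuple[int, int, int, int]
    micrograph: Micrograph  # cropped to bbox


def segment_micrograph(
    img: Micrograph, radius_px: float = DEFAULT_NIBLACK_RADIUS_PX
) -> SegmentationResult:
    """Full two-step segmentation of one micrograph.

    Returns the triangle cell mask, the Niblack fiber mask, their AND with
    single-pixel specks removed, and the bounding box of the cell mask; all
    masks and the micrograph are cropped to that box, which is the analysis
    region for correlograms.
    """
    cell = cell_mask_triangle(img)
    if not cell.values.any():
        raise ValueError("no cell detected: empty cell mask")
    fiber = niblack_mask(img, radius_px)
    combined = BinaryMask(
        values=cell.values & fiber.values,
        pixel_size_nm=img.pixel_size_nm,
        provenance="combined",
    )
    combined = remove_isolated_pixels(combined)
    r0, r1, c0, c1 = bounding_box(cell)
    crop = np.s_[r0:r1, c0:c1]
    cropped_img = replace(img, intensities=img.intensities[crop])
    return SegmentationResult(
        cell_mask=replace(cell, values=cell.values[crop]),
        fiber_mask=replace(fiber, values=fiber.values[crop]),
        combined=replace(combined, values=combined.values[crop]),
        bbox=(r0, r1, c0, c1),
        micrograph=cropped_img,
    )
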