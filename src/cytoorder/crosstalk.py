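"""Similarity between two cytoskeletal networks via cross-correlation peaks.

Cross-correlograms of two binary masks from the same cell show a central
peak over a smooth background; the peak height above background measures how
much the two networks overlap in space.  Two controls guard the
interpretation: analysis can be restricted to the largest circle inscribed
in the cell (removing shape- and periphery-driven contributions), and a
random-pairing null cross-correlates networks from *different* cells, where
no biologically meaningful short-range resemblance can exist — any residual
peak there is artifactual.

Circular regions are still correlated on their square bounding grids with
the rectangle overlap normalization (N-|i|)(M-|j|), which imprints a faint
cross-shaped artifact on the background; the corrected normalization by the
overlap area of two shifted discs is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from cytoorder.correlation import Correlogram, correlate_fft
from cytoorder.order_analysis import PopulationAverage, average_population
from cytoorder.segmentation import BinaryMask

logger = logging.getLogger(__name__)

DEFAULT_PEAK_WINDOW_PX = 9
DEFAULT_BG_RING_PX = (27, 36)


@dataclass(frozen=True)
class InscribedCircle:
    """Largest circle that fits inside a mask's set region."""

    center: tuple[int, int]
    radius_px: int


@dataclass(frozen=True)
class PeakMeasurement:
    """Central peak of a cross-correlogram, measured from the background."""

    peak_height: float
    background: float
    peak_lag: tuple[int, int]


def largest_inscribed_circle(mask: BinaryMask) -> InscribedCircle:
    """Largest inscribed circle via the Euclidean distance transform.

    The center is the distance transform's maximum (ties break to the first
    in row-major order) and the radius is that maximum distance floored to
    whole pixels; the image boundary counts as background.
    """
    v = mask.values
    if not v.any():
        raise ValueError("empty mask has no inscribed circle")
    padded = np.pad(v, 1)  # treat outside the grid as background
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    center_flat = int(np.argmax(dist))
    center = np.unravel_index(center_flat, dist.shape)
    # a disc of radius r fits iff r < distance to the nearest background pixel
    radius = max(int(np.ceil(dist[center]) - 1), 0)
    return InscribedCircle(center=(int(center[0]), int(center[1])), radius_px=radius)


def clip_to_circle(mask: BinaryMask, circle: InscribedCircle) -> BinaryMask:
    """Restrict a mask to a disc; all other data are ignored.

    Returns the (2r+1) x (2r+1) square bounding the disc, false outside the
    closed disc.
    """
    r = circle.radius_px
    if r < 1:
        raise ValueError("inscribed circle smaller than one pixel")
    cr, cc = circle.center
    n, m = mask.shape
    if cr - r < 0 or cc - r < 0 or cr + r >= n or cc + r >= m:
        raise ValueError("circle does not fit within the mask grid")
    sq = mask.values[cr - r : cr + r + 1, cc - r : cc + r + 1]
    yy, xx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    disc = (yy * yy + xx * xx) <= r * r
    return replace(mask, values=sq & disc)


def disc_overlap_normalization(c: Correlogram, radius_px: int) -> Correlogram:
    """Renormalize a disc-region correlogram by the true disc overlap area.

    Replaces the rectangle factor (N-|i|)(M-|j|) by the overlap area of two
    discs of the given radius shifted by the lag vector, which removes the
    cross-shaped background artifact of the square-grid normalization.
    """
    L = c.max_lag
    n = m = 2 * radius_px + 1
    lags = np.arange(-L, L + 1, dtype=float)
    di, dj = np.meshgrid(lags, lags, indexing="ij")
    rect = np.outer(n - np.abs(lags), m - np.abs(lags)).astype(float)
    d = np.hypot(di, dj)
    r = float(radius_px)
    with np.errstate(invalid="ignore"):
        lens = 2.0 * r * r * np.arccos(np.clip(d / (2 * r), -1, 1)) - (
            d / 2.0
        ) * np.sqrt(np.maximum(4 * r * r - d * d, 0.0))
    lens = np.where(d >= 2 * r, 0.0, lens)
    vals = np.where(lens > 0, c.values * rect / lens, np.nan)
    return replace(c, values=vals)


def peak_and_background(
    c: Correlogram,
    peak_window_px: int = DEFAULT_PEAK_WINDOW_PX,
    bg_ring_px: tuple[int, int] = DEFAULT_BG_RING_PX,
) -> PeakMeasurement:
    """Quantify the central peak of a correlogram over its background.

    The background is the median of correlogram values in the annulus
    ``bg_ring_px`` (robust to residual central structure); the peak height is
    the maximum within the centered square window of the given half-width,
    minus that background.
    """
    L = c.max_lag
    bg_in, bg_out = bg_ring_px
    if bg_out > L:
        raise ValueError(f"background ring outer radius {bg_out} exceeds extent {L}")
    if peak_window_px > L:
        raise ValueError(f"peak window {peak_window_px} exceeds extent {L}")
    lags = np.arange(-L, L + 1, dtype=float)
    di, dj = np.meshgrid(lags, lags, indexing="ij")
    r = np.hypot(di, dj)
    ring = (r >= bg_in) & (r <= bg_out) & np.isfinite(c.values)
    background = float(np.median(c.values[ring]))
    w = peak_window_px
    window = c.values[L - w : L + w + 1, L - w : L + w + 1]
    flat = np.nanargmax(window)
    pi, pj = np.unravel_index(flat, window.shape)
    peak_val = float(window[pi, pj])
    return PeakMeasurement(
        peak_height=peak_val - background,
        background=background,
        peak_lag=(int(pi - w), int(pj - w)),
    )


def central_peak_excess(
    c: Correlogram,
    peak_window_px: int = DEFAULT_PEAK_WINDOW_PX,
    control_offsets: tuple | None = None,
) -> float:
    """Central-window maximum minus the mean of off-center window maxima.

    A window maximum is positively biased on a noisy field, so a raw
    peak-over-background height never averages to zero even without a true
    peak.  Subtracting the mean of identically sized control windows placed
    away from the center gives a statistic that is unbiased under the
    no-peak null and large when the networks genuinely overlap.
    """
    L = c.max_lag
    w = peak_window_px
    if control_offsets is None:
        d = L - w
        e = int(d / np.sqrt(2.0))
        control_offsets = (
            (d, 0), (-d, 0), (0, d), (0, -d), (e, e), (e, -e), (-e, e), (-e, -e),
        )
    def wmax(ci: int, cj: int) -> float:
        return float(np.nanmax(
            c.values[L + ci - w : L + ci + w + 1, L + cj - w : L + cj + w + 1]
        ))

    for ci, cj in control_offsets:
        if abs(ci) + w > L or abs(cj) + w > L:
            raise ValueError("control window exceeds correlogram extent")
    central = wmax(0, 0)
    controls = [wmax(ci, cj) for ci, cj in control_offsets]
    return central - float(np.mean(controls))


def _common_max_lag(shapes, requested: int) -> int:
    feasible = min(min(s) - 1 for s in shapes)
    return min(requested, feasible)


def same_cell_crosstalk(
    cells: list,
    region: str = "full",
    max_lag: int = 40,
    peak_window_px: int = DEFAULT_PEAK_WINDOW_PX,
    bg_ring_px: tuple[int, int] = DEFAULT_BG_RING_PX,
    normalization: str = "rectangle",
) -> tuple[PopulationAverage, PeakMeasurement]:
    """Average cross-correlogram of two networks of the same cells.

    ``cells`` is a list of ``(maskA, maskB)`` or ``(maskA, maskB, cell_mask)``
    tuples with pixel-registered channels.  With ``region='inscribed_circle'``
    both channels are clipped identically to the largest circle fitting the
    cell mask (the union of both networks when no cell mask is given).
    Cells that fail clipping are skipped with a logged warning.  Returns the
    unweighted average correlogram and the peak measurement of that average.
    """
    if region not in ("full", "inscribed_circle"):
        raise ValueError(f"unknown region {region!r}")
    if normalization not in ("rectangle", "disc_overlap"):
        raise ValueError(f"unknown normalization {normalization!r}")
    prepared = []
    radii = []
    for idx, cell in enumerate(cells):
        ma, mb = cell[0], cell[1]
        support = cell[2] if len(cell) > 2 else None
        if ma.shape != mb.shape:
            raise ValueError(f"cell {idx}: channel dimensions differ")
        try:
            if region == "inscribed_circle":
                if support is None:
                    union = replace(ma, values=ma.values | mb.values)
                    support = replace(
                        union, values=ndimage.binary_fill_holes(union.values)
                    )
                circle = largest_inscribed_circle(support)
                ma = clip_to_circle(ma, circle)
                mb = clip_to_circle(mb, circle)
                radii.append(circle.radius_px)
            prepared.append((ma, mb))
        except ValueError as exc:
            logger.warning("cell %d skipped: %s", idx, exc)
    if not prepared:
        raise ValueError("no analyzable cells")
    lag = _common_max_lag([p[0].shape for p in prepared], max_lag)
    corrs = []
    for k, (ma, mb) in enumerate(prepared):
        c = correlate_fft(ma, mb, lag)
        if normalization == "disc_overlap" and region == "inscribed_circle":
            c = disc_overlap_normalization(c, radii[k])
        corrs.append(c)
    avg = average_population(corrs)
    mean_c = replace(corrs[0], values=avg.mean, source="cross")
    bg = (min(bg_ring_px[0], lag - 1), min(bg_ring_px[1], lag))
    peak = peak_and_background(mean_c, min(peak_window_px, lag), bg)
    return avg, peak


def _random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation with no fixed point (rejection sampling)."""
    if n < 2:
        raise ValueError("a derangement needs at least 2 elements")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def random_pair_null(
    cellsA: list[BinaryMask],
    cellsB: list[BinaryMask],
    seed: int,
    max_lag: int = 40,
    normalization: str = "rectangle",
    supportsA: list[BinaryMask] | None = None,
    supportsB: list[BinaryMask] | None = None,
) -> PopulationAverage:
    """Random-cell-pairing null for cross-correlation peaks.

    Each channel-1 mask is paired with the channel-2 mask of a *different*,
    randomly chosen cell (a seeded uniform derangement).  For each pair the
    analysis is limited to the largest circle that fits into both cells: the
    radius is the smaller of the two inscribed radii and each mask is clipped
    to a disc of that radius centered on its own circle center, so the discs
    are registered center-to-center.  The clipped discs are cross-correlated
    and the correlograms averaged unweighted.  Networks from different cells
    cannot resemble each other on short length scales, so a central peak in
    this average would be artifactual.

    ``supportsA``/``supportsB`` optionally give the cell-shaped region each
    network lives in; the inscribed circle is then fitted to the cell rather
    than to the (sparse) network mask itself.
    """
    if len(cellsA) != len(cellsB):
        raise ValueError("cellsA and cellsB must have the same length")
    n = len(cellsA)
    rng = np.random.default_rng(seed)
    perm = _random_derangement(n, rng)
    pairs = []
    for i in range(n):
        j = int(perm[i])
        ma, mb = cellsA[i], cellsB[j]
        ca = largest_inscribed_circle(supportsA[i] if supportsA else ma)
        cb = largest_inscribed_circle(supportsB[j] if supportsB else mb)
        r = min(ca.radius_px, cb.radius_px)
        if r < 1:
            logger.warning("pair %d skipped: inscribed radius < 1 px", i)
            continue
        da = clip_to_circle(ma, InscribedCircle(ca.center, r))
        db = clip_to_circle(mb, InscribedCircle(cb.center, r))
        pairs.append((da, db, r))
    if not pairs:
        raise ValueError("no analyzable pairs")
    lag = _common_max_lag([p[0].shape for p in pairs], max_lag)
    corrs = []
    for da, db, r in pairs:
        c = correlate_fft(da, db, lag)
        if normalization == "disc_overlap":
            c = disc_overlap_normalization(c, r)
        corrs.append(c)
    return average_population(corrs)
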