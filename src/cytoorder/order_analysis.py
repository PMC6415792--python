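"""Orientational, translational and intrinsic order from correlograms.

Orientational order is measured by the *radial orientation function* (ROF):
the mean origin-normalized auto-correlation in 1-degree-wide angular slices
of a fixed annulus around zero lag (default radii 9-21 px, i.e. 1.01-2.35 um
at the common 112 nm pixel size — just beyond the Niblack kernel).  The
annulus angle is measured from the vertical (strain) axis, counterclockwise,
and because auto-correlograms are point symmetric the two half circles are
pooled into [0, 180) degrees.  The angle of the ROF's absolute maximum is a
cell's *preferred direction*.

Translational order is the decay of the correlogram along the preferred
direction (a line profile).  *Intrinsic* order removes whole-cell rotation:
each cell's correlogram is rotated so its preferred direction sits at 90
degrees before the population is averaged, so any remaining order reflects
structure within cells rather than alignment between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from cytoorder.correlation import Correlogram

logger = logging.getLogger(__name__)

DEFAULT_R_INNER_PX = 9.0
DEFAULT_R_OUTER_PX = 21.0
N_SLICES = 180
FLATNESS_EPS = 1e-6


@dataclass(frozen=True)
class RadialOrientationFunction:
    """Mean correlation per 1-degree slice of an annulus, over [0, 180)."""

    values: np.ndarray
    r_inner_px: float = DEFAULT_R_INNER_PX
    r_outer_px: float = DEFAULT_R_OUTER_PX
    offset_subtracted: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (N_SLICES,):
            raise ValueError(f"ROF must have exactly {N_SLICES} slices")
        if not self.r_inner_px < self.r_outer_px:
            raise ValueError("r_inner_px must be < r_outer_px")
        object.__setattr__(self, "values", arr)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(N_SLICES, dtype=float)

    def at_angle(self, angle_deg: float) -> float:
        """Value of the slice containing the given angle."""
        return float(self.values[int(np.floor(angle_deg)) % N_SLICES])


@dataclass(frozen=True)
class LineProfile:
    """Correlation sampled along a fixed direction from zero lag."""

    lags_px: np.ndarray
    values: np.ndarray
    direction_deg: float
    pixel_size_nm: float

    @property
    def lags_um(self) -> np.ndarray:
        return self.lags_px * self.pixel_size_nm / 1000.0


@dataclass(frozen=True)
class PopulationAverage:
    """Unweighted elementwise mean with between-cell SEM."""

    mean: np.ndarray
    sem: np.ndarray | None
    n: int


def _lag_angles_deg(max_lag: int) -> np.ndarray:
    """Angle of each lag pixel from the vertical axis, CCW, in [0, 180)."""
    lags = np.arange(-max_lag, max_lag + 1, dtype=float)
    di, dj = np.meshgrid(lags, lags, indexing="ij")
    # vertical (row) axis = 0 deg; CCW positive; point symmetry folds mod 180
    theta = np.degrees(np.arctan2(-dj, -di))  # angle of (row,col)=(cos,sin) dirs
    return np.mod(theta, 180.0)


def radial_orientation(
    c: Correlogram,
    r_inner_px: float = DEFAULT_R_INNER_PX,
    r_outer_px: float = DEFAULT_R_OUTER_PX,
) -> RadialOrientationFunction:
    """Radial orientation function of an origin-normalized auto-correlogram.

    Each annulus pixel (center distance in [r_inner, r_outer], inclusive) is
    assigned to the 1-degree slice containing its angle; antipodal slices are
    pooled; the slice value is the mean of its pixels.  Slices left empty by
    the pixel grid are filled by circular linear interpolation between the
    nearest occupied slices (logged).
    """
    if c.normalization != "origin":
        raise ValueError("radial_orientation requires an origin-normalized correlogram")
    L = c.max_lag
    if L < r_outer_px:
        raise ValueError(
            f"correlogram extent {L} px is smaller than the outer radius {r_outer_px} px"
        )
    lags = np.arange(-L, L + 1, dtype=float)
    di, dj = np.meshgrid(lags, lags, indexing="ij")
    r = np.hypot(di, dj)
    in_ring = (r >= r_inner_px) & (r <= r_outer_px)
    theta = np.mod(np.degrees(np.arctan2(-dj, -di)), 180.0)
    slices = np.floor(theta[in_ring]).astype(int) % N_SLICES
    vals = c.values[in_ring]
    finite = np.isfinite(vals)
    slices, vals = slices[finite], vals[finite]
    sums = np.bincount(slices, weights=vals, minlength=N_SLICES)
    counts = np.bincount(slices, minlength=N_SLICES)
    out = np.full(N_SLICES, np.nan)
    occ = counts > 0
    out[occ] = sums[occ] / counts[occ]
    n_empty = int((~occ).sum())
    if n_empty:
        logger.info(
            "radial_orientation: %d of %d slices empty; filled by circular "
            "linear interpolation",
            n_empty,
            N_SLICES,
        )
        out = _fill_circular(out)
    return RadialOrientationFunction(
        values=out, r_inner_px=float(r_inner_px), r_outer_px=float(r_outer_px)
    )


def _fill_circular(values: np.ndarray) -> np.ndarray:
    """Fill NaN entries by linear interpolation on a circular index axis."""
    n = values.size
    good = np.isfinite(values)
    if not good.any():
        raise ValueError("all slices empty")
    idx = np.arange(n)
    # unwrap by tripling the axis, then interpolate over the middle copy
    xg = np.concatenate([idx[good] - n, idx[good], idx[good] + n])
    yg = np.tile(values[good], 3)
    out = values.copy()
    out[~good] = np.interp(idx[~good], xg, yg)
    return out


def subtract_offset(rof: RadialOrientationFunction) -> RadialOrientationFunction:
    """Subtract the 0-degree slice value from every slice (for reporting)."""
    if rof.offset_subtracted:
        raise ValueError("offset already subtracted")
    return replace(rof, values=rof.values - rof.values[0], offset_subtracted=True)


def preferred_direction(rof: RadialOrientationFunction) -> float:
    """Angle (deg) of the ROF's absolute maximum, in [0, 180).

    Ties break to the smallest angle; a flat ROF returns 0 with a logged
    degeneracy warning.
    """
    v = rof.values
    if float(v.max() - v.min()) < FLATNESS_EPS:
        logger.warning("preferred_direction: ROF is flat; returning 0 deg")
        return 0.0
    return float(np.argmax(v))


def direction_vector(direction_deg: float) -> tuple[float, float]:
    """Unit lag-space (row, col) vector of a direction given in degrees CCW
    from the vertical axis."""
    t = np.radians(direction_deg)
    return float(np.cos(t)), float(np.sin(t))


def line_profile(
    c: Correlogram, direction_deg: float, max_lag_px: int | None = None
) -> LineProfile:
    """Sample a correlogram at unit-lag steps along one direction.

    Bilinear interpolation between grid points; typically applied along the
    preferred direction of an origin-normalized auto-correlogram, where the
    decay measures translational order.
    """
    direction_deg = float(np.mod(direction_deg, 360.0))
    L = c.max_lag
    if max_lag_px is None:
        max_lag_px = L
    if max_lag_px > L:
        raise ValueError(f"max_lag_px {max_lag_px} exceeds correlogram extent {L}")
    dr, dc = direction_vector(direction_deg)
    u = np.arange(max_lag_px + 1, dtype=float)
    rows = c.center[0] + u * dr
    cols = c.center[1] + u * dc
    vals = ndimage.map_coordinates(c.values, [rows, cols], order=1, mode="nearest")
    return LineProfile(
        lags_px=u,
        values=vals,
        direction_deg=direction_deg,
        pixel_size_nm=c.pixel_size_nm,
    )


def rotate_correlogram(c: Correlogram, by_deg: float) -> Correlogram:
    """Rotate a correlogram about zero lag so features at angle a move to
    a + by_deg.

    Bilinear interpolation; samples falling outside the source grid become
    NaN and are excluded from downstream averages.
    """
    L = c.max_lag
    lags = np.arange(-L, L + 1, dtype=float)
    di, dj = np.meshgrid(lags, lags, indexing="ij")
    t = np.radians(by_deg)
    # inverse rotation of the output lag vector into source coordinates
    src_r = np.cos(t) * di + np.sin(t) * dj
    src_c = -np.sin(t) * di + np.cos(t) * dj
    vals = ndimage.map_coordinates(
        c.values, [src_r + L, src_c + L], order=1, mode="constant", cval=np.nan
    )
    return replace(c, values=vals)


def align_to_90(c: Correlogram) -> tuple[Correlogram, float]:
    """Rotate a correlogram so its preferred direction sits at 90 degrees."""
    pd = preferred_direction(radial_orientation(c))
    return rotate_correlogram(c, 90.0 - pd), pd


def average_population(items: list, align: bool = False) -> PopulationAverage:
    """Unweighted elementwise mean and between-cell SEM of a population.

    ``items`` are same-shape :class:`RadialOrientationFunction`,
    :class:`LineProfile` or :class:`Correlogram` objects.  No per-cell weight
    factors are applied; the uncertainty of the average is estimated from the
    variance between cells (SEM = sd / sqrt(n)).  With ``align=True`` each
    item must be an origin-normalized correlogram and is rotated to put its
    preferred direction at 90 degrees before averaging (intrinsic order);
    rotation-clipped corners are excluded via per-element valid counts.
    """
    if len(items) == 0:
        raise ValueError("need at least one item")
    if align:
        if not all(isinstance(it, Correlogram) for it in items):
            raise ValueError("align=True requires Correlogram items")
        items = [align_to_90(it)[0] for it in items]
    arrays = [np.asarray(it.values, dtype=float) for it in items]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among items: {sorted(shapes)}")
    stack = np.stack(arrays)
    valid = np.isfinite(stack)
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_valid > 0, np.nansum(stack, axis=0) / n_valid, np.nan)
        if len(items) >= 2:
            dev2 = np.nansum((stack - mean) ** 2, axis=0)
            sd = np.sqrt(np.where(n_valid > 1, dev2 / np.maximum(n_valid - 1, 1), np.nan))
            sem = sd / np.sqrt(n_valid)
        else:
            sem = None
    return PopulationAverage(mean=mean, sem=sem, n=len(items))


def find_orientation_modes(rof: RadialOrientationFunction, n_modes: int) -> np.ndarray:
    """Angles (deg) of the ``n_modes`` most prominent ROF peaks.

    Peaks are detected on the circularly extended 180-degree axis and ranked
    by prominence, so multimodal orientation distributions (several fiber
    families at distinct angles) are resolved into one angle per family.
    """
    from scipy.signal import find_peaks

    v = rof.values
    ext = np.concatenate([v, v, v])  # circular extension
    peaks, props = find_peaks(ext, prominence=0.0)
    in_mid = (peaks >= N_SLICES) & (peaks < 2 * N_SLICES)
    peaks, prom = peaks[in_mid] - N_SLICES, props["prominences"][in_mid]
    if peaks.size < n_modes:
        raise ValueError(f"only {peaks.size} peaks found, {n_modes} requested")
    order = np.argsort(prom)[::-1][:n_modes]
    return np.sort(peaks[order].astype(float))


def refine_direction(
    c: Correlogram,
    coarse_deg: float,
    half_width_deg: float = 1.5,
    step_deg: float = 0.25,
    lag_window: tuple[int, int] = (40, 160),
) -> float:
    """Sub-degree ridge alignment of a direction estimate.

    The radial orientation function locates the correlation ridge at
    1-degree resolution; over long lags even a fraction of a degree of
    misalignment walks the sampled line off the ridge.  This scans a fine
    angle grid around the coarse estimate and returns the angle maximising
    the mean profile value over a mid-range lag window.
    """
    lo, hi = lag_window
    hi = min(hi, c.max_lag)
    lo = min(lo, hi // 2)
    best_angle, best_val = coarse_deg, -np.inf
    for a in np.arange(coarse_deg - half_width_deg, coarse_deg + half_width_deg + 1e-9,
                       step_deg):
        vals = line_profile(c, a, hi).values[lo : hi + 1]
        score = float(np.nanmean(vals))
        if score > best_val:
            best_angle, best_val = float(a), score
    return float(np.mod(best_angle, 180.0))


def estimate_decay_length(
    profile: LineProfile,
    min_lag_px: float = 15.0,
    min_length_px: float = 40.0,
    background_order: int = 2,
) -> float:
    """Feature length from the linear decay of an along-fiber line profile.

    The along-fiber auto-correlation of straight fibers of length L decays
    linearly and meets the background at lag L.  The profile is modelled as
    a triangle over a smooth background,

        v(u) = A (1 - u/L)_+  +  (b0 + b1 u + ... ),

    the kink position L is grid-searched at 1 px resolution with the
    remaining coefficients solved by least squares, and the L of the
    best-fitting model (with positive triangle amplitude A) is returned.
    The polynomial background absorbs the slowly decaying contribution of
    distinct, near-collinear fibers; lags below ``min_lag_px`` are excluded
    because segmentation speckle and the filter halo distort the profile
    near the origin.
    """
    u = profile.lags_px
    v = profile.values
    sel = (u >= min_lag_px) & np.isfinite(v)
    uu, vv = u[sel], v[sel]
    if uu.size < 10:
        raise ValueError("profile too short for a decay fit")
    u_hi = float(uu.max()) - 20.0
    if u_hi <= min_length_px:
        raise ValueError("profile extent too small relative to min_length_px")
    bg_basis = [uu**k for k in range(background_order + 1)]
    Xbg = np.column_stack(bg_basis)
    coef_bg, *_ = np.linalg.lstsq(Xbg, vv, rcond=None)
    sse_bg = float(((Xbg @ coef_bg - vv) ** 2).sum())
    best: tuple[float, float] | None = None
    for L in np.arange(min_length_px, u_hi, 1.0):
        X = np.column_stack([np.maximum(1.0 - uu / L, 0.0), *bg_basis])
        coef, *_ = np.linalg.lstsq(X, vv, rcond=None)
        if coef[0] <= 0:
            continue
        sse = float(((X @ coef - vv) ** 2).sum())
        if best is None or sse < best[1]:
            best = (float(L), sse)
    # the triangle must actually explain variance beyond the background alone
    if best is None or not best[1] < 0.99 * sse_bg:
        raise ValueError("profile has no decaying triangle component")
    return best[0]
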