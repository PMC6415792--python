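"""Ground-truthed synthetic fluorescence micrographs of fibrous networks.

Fibers are bright rotated rectangles at uniformly random positions over a
dark background; the rendered image is blurred with a Gaussian PSF and
corrupted with signal-dependent shot noise plus additive Gaussian read
noise, emulating a confocal fluorescence micrograph of a stained
cytoskeleton.  The un-blurred, un-noised fiber occupancy is returned as the
ground-truth mask, and the per-fiber angles as ground-truth orientations.

The ``s2`` preset renders the validation image used throughout the test
suite: one hundred 5 x 200 px rectangles all oriented at 34 degrees to the
vertical axis with realistic intensity noise.  Bimodal and trimodal presets
provide multi-peaked orientation distributions, and paired generation
produces two-channel networks with a tunable shared-fiber fraction for
cross-correlation experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cytoorder.imaging_io import COMMON_PIXEL_SIZE_NM, Micrograph
from cytoorder.segmentation import BinaryMask


@dataclass(frozen=True)
class FiberSpec:
    """Parameters of one synthetic fibrous network.

    ``orientations_deg`` is a list of ``(angle_deg, weight)`` modes; each
    fiber draws its mode by weight and adds Gaussian angular jitter of
    ``angle_jitter_sd_deg``.  ``photon_scale`` sets the shot-noise strength
    (expected photons per intensity unit; ``0`` disables shot noise);
    ``psf_sigma_px`` the Gaussian blur; ``read_noise_sd`` the additive noise.
    The seed fixes the full realization.
    """

    n_fibers: int = 100
    length_px: float = 200.0
    width_px: float = 5.0
    orientations_deg: tuple = ((34.0, 1.0),)
    angle_jitter_sd_deg: float = 0.0
    image_size: tuple[int, int] = (600, 600)
    intensity: float = 100.0
    psf_sigma_px: float = 1.5
    photon_scale: float = 1.0
    read_noise_sd: float = 5.0
    background_level: float = 10.0
    pixel_size_nm: float = COMMON_PIXEL_SIZE_NM
    clip_at_borders: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if min(self.image_size) < 8:
            raise ValueError("image too small")
        if self.length_px <= 0 or self.width_px <= 0:
            raise ValueError("fiber dimensions must be positive")
        w = sum(wt for _, wt in self.orientations_deg)
        if not np.isclose(w, 1.0):
            raise ValueError(f"orientation mode weights must sum to 1, got {w}")


def _draw_angles(spec: FiberSpec, rng: np.random.Generator) -> np.ndarray:
    modes = np.array([a for a, _ in spec.orientations_deg], dtype=float)
    weights = np.array([w for _, w in spec.orientations_deg], dtype=float)
    which = rng.choice(modes.size, size=spec.n_fibers, p=weights)
    angles = modes[which]
    if spec.angle_jitter_sd_deg > 0:
        angles = angles + rng.normal(0.0, spec.angle_jitter_sd_deg, spec.n_fibers)
    return np.mod(angles, 180.0)


def _draw_centers(
    spec: FiberSpec, rng: np.random.Generator, support: BinaryMask | None
) -> np.ndarray:
    n, m = spec.image_size
    if support is None:
        # By default whole fibers are kept inside the frame so that the
        # rendered rectangles have their nominal length; clip_at_borders
        # instead spreads centers over the full frame and truncates.
        margin = 0.0
        if not spec.clip_at_borders:
            margin = float(np.hypot(spec.length_px / 2.0, spec.width_px / 2.0))
            if 2 * margin >= min(n, m):
                raise ValueError("fibers do not fit inside the frame")
        rows = rng.uniform(margin, n - margin, spec.n_fibers)
        cols = rng.uniform(margin, m - margin, spec.n_fibers)
        return np.column_stack([rows, cols])
    set_rc = np.argwhere(support.values)
    if set_rc.size == 0:
        raise ValueError("support mask is empty")
    picks = set_rc[rng.integers(0, len(set_rc), spec.n_fibers)].astype(float)
    return picks + rng.uniform(-0.5, 0.5, picks.shape)


def _rasterize_fibers(
    spec: FiberSpec, centers: np.ndarray, angles: np.ndarray
) -> np.ndarray:
    """Count of fibers covering each pixel (fluorescence adds on overlap)."""
    n, m = spec.image_size
    count = np.zeros((n, m), dtype=float)
    hl, hw = spec.length_px / 2.0, spec.width_px / 2.0
    reach = int(np.ceil(np.hypot(hl, hw))) + 1
    for (cr, cc), ang in zip(centers, angles):
        t = np.radians(ang)
        dr, dc = np.cos(t), np.sin(t)  # fiber axis in (row, col)
        r0, r1 = max(int(cr) - reach, 0), min(int(cr) + reach + 1, n)
        c0, c1 = max(int(cc) - reach, 0), min(int(cc) + reach + 1, m)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc_ = np.meshgrid(
            np.arange(r0, r1, dtype=float), np.arange(c0, c1, dtype=float),
            indexing="ij",
        )
        u = (rr - cr) * dr + (cc_ - cc) * dc
        v = -(rr - cr) * dc + (cc_ - cc) * dr
        count[r0:r1, c0:c1] += (np.abs(u) <= hl) & (np.abs(v) <= hw)
    return count


def _render(
    spec: FiberSpec, count: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    signal = spec.background_level + spec.intensity * count
    if spec.psf_sigma_px > 0:
        signal = ndimage.gaussian_filter(signal, spec.psf_sigma_px)
    img = signal
    if spec.photon_scale > 0:
        img = rng.poisson(np.maximum(signal, 0.0) * spec.photon_scale) / spec.photon_scale
    if spec.read_noise_sd > 0:
        img = img + rng.normal(0.0, spec.read_noise_sd, img.shape)
    return np.clip(img, 0.0, None)


def generate_fibers(
    spec: FiberSpec, support: BinaryMask | None = None
) -> tuple[Micrograph, BinaryMask, np.ndarray]:
    """Render one synthetic network.

    Returns the noisy micrograph, the ground-truth occupancy mask and the
    per-fiber angles (degrees from vertical, CCW).  ``support`` optionally
    restricts fiber centers to a cell-shaped region.
    """
    rng = np.random.default_rng(spec.seed)
    angles = _draw_angles(spec, rng)
    centers = _draw_centers(spec, rng, support)
    count = _rasterize_fibers(spec, centers, angles)
    img = _render(spec, count, rng)
    truth = BinaryMask(
        values=count > 0,
        pixel_size_nm=spec.pixel_size_nm,
        provenance="synthetic-truth",
    )
    micro = Micrograph(
        intensities=img,
        pixel_size_nm=spec.pixel_size_nm,
        channel="other",
        cell_id=f"synthetic-{spec.seed}",
        condition="synthetic",
    )
    return micro, truth, angles


def generate_multimodal(
    spec: FiberSpec, support: BinaryMask | None = None
) -> tuple[Micrograph, BinaryMask, np.ndarray]:
    """Render a network whose orientation distribution has 2-3 modes.

    Identical to :func:`generate_fibers` (to which a single-mode spec
    reduces) but validates that the modes are separated by at least 20
    degrees so the downstream orientation function can resolve them.
    """
    n_modes = len(spec.orientations_deg)
    if n_modes > 1:
        modes = sorted(a for a, _ in spec.orientations_deg)
        gaps = [
            min((b - a) % 180.0, (a - b) % 180.0)
            for a, b in zip(modes, modes[1:] + [modes[0]])
        ]
        if min(gaps) < 20.0:
            raise ValueError(
                f"orientation modes closer than 20 deg ({min(gaps):.1f} deg) "
                "cannot be resolved by the annulus analysis"
            )
    return generate_fibers(spec, support)


def generate_paired(
    spec: FiberSpec,
    shared_fraction: float,
    displacement_sd_px: float = 0.0,
    support: BinaryMask | None = None,
) -> tuple[Micrograph, Micrograph, BinaryMask, BinaryMask]:
    """Two-channel network pair with a tunable co-localized fiber fraction.

    Channel A follows ``spec``.  Channel B keeps ``shared_fraction`` of A's
    fibers (each jittered in position by ``displacement_sd_px``) and replaces
    the rest with fresh independent fibers; both channels are rendered with
    independent noise.  Returns (imgA, imgB, truthA, truthB).
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    angles_a = _draw_angles(spec, rng)
    centers_a = _draw_centers(spec, rng, support)
    n_shared = int(round(spec.n_fibers * shared_fraction))
    shared_idx = rng.choice(spec.n_fibers, size=n_shared, replace=False)
    centers_b = _draw_centers(spec, rng, support)
    angles_b = _draw_angles(spec, rng)
    centers_b[: n_shared] = centers_a[shared_idx]
    angles_b[: n_shared] = angles_a[shared_idx]
    if displacement_sd_px > 0 and n_shared:
        centers_b[:n_shared] += rng.normal(0.0, displacement_sd_px, (n_shared, 2))
    count_a = _rasterize_fibers(spec, centers_a, angles_a)
    count_b = _rasterize_fibers(spec, centers_b, angles_b)
    img_a = _render(spec, count_a, rng)
    img_b = _render(spec, count_b, rng)
    truth_a = BinaryMask(count_a > 0, spec.pixel_size_nm, "synthetic-truth")
    truth_b = BinaryMask(count_b > 0, spec.pixel_size_nm, "synthetic-truth")
    ma = Micrograph(img_a, spec.pixel_size_nm, "other", f"pairA-{spec.seed}", "synthetic")
    mb = Micrograph(img_b, spec.pixel_size_nm, "other", f"pairB-{spec.seed}", "synthetic")
    return ma, mb, truth_a, truth_b


def elliptical_cell_mask(
    image_size: tuple[int, int],
    semi_axes: tuple[float, float] | None = None,
    center: tuple[float, float] | None = None,
    pixel_size_nm: float = COMMON_PIXEL_SIZE_NM,
) -> BinaryMask:
    """Elliptical cell support mask (for exercising inscribed-circle logic)."""
    n, m = image_size
    if center is None:
        center = ((n - 1) / 2.0, (m - 1) / 2.0)
    if semi_axes is None:
        semi_axes = (0.45 * n, 0.35 * m)
    rr, cc = np.meshgrid(np.arange(n, dtype=float), np.arange(m, dtype=float),
                         indexing="ij")
    inside = ((rr - center[0]) / semi_axes[0]) ** 2 + (
        (cc - center[1]) / semi_axes[1]
    ) ** 2 <= 1.0
    return BinaryMask(inside, pixel_size_nm, "cell")


def load_preset(name: str, seed: int = 0) -> tuple[FiberSpec, dict]:
    """Load a named preset from the bundled presets.yaml.

    Returns the :class:`FiberSpec` plus a dict of any extra options the
    preset carries (e.g. pairing parameters).
    """
    import importlib.resources

    import yaml

    text = (
        importlib.resources.files("cytoorder").joinpath("presets.yaml").read_text()
    )
    presets = yaml.safe_load(text)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    raw = dict(presets[name])
    extras = {
        k: raw.pop(k) for k in ("shared_fraction", "displacement_sd_px") if k in raw
    }
    if "orientations_deg" in raw:
        raw["orientations_deg"] = tuple(tuple(m) for m in raw["orientations_deg"])
    if "image_size" in raw:
        raw["image_size"] = tuple(raw["image_size"])
    return FiberSpec(seed=seed, **raw), extras


def s2_preset(seed: int = 0, **overrides) -> FiberSpec:
    """The validation preset: 100 rectangles of 5 x 200 px at 34 degrees to
    the vertical axis, with realistic intensity noise."""
    return dataclasses.replace(FiberSpec(seed=seed), **overrides)


def bimodal_preset(seed: int = 0, modes=(30.0, 120.0), **overrides) -> FiberSpec:
    """Two equally weighted orientation modes (bimodal filament order)."""
    base = FiberSpec(
        orientations_deg=tuple((m, 1.0 / len(modes)) for m in modes), seed=seed
    )
    return dataclasses.replace(base, **overrides)


def trimodal_preset(seed: int = 0, modes=(0.0, 60.0, 120.0), **overrides) -> FiberSpec:
    """Three equally weighted orientation modes (trimodal filament order)."""
    return bimodal_preset(seed=seed, modes=modes, **overrides)
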