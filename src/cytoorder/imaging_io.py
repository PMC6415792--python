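"""Micrograph container, TIFF reading and resampling to a common pixel grid.

Coordinate conventions used throughout the package: row index increases
downward, column index rightward, 0-based, pixel centers at integer
coordinates.  The image vertical (row) axis is the strain axis and defines
angle 0; angles increase counterclockwise and are reported in [0, 180)
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage

#: Common physical pixel size (nm) that all micrographs are resampled to
#: before analysis.
COMMON_PIXEL_SIZE_NM = 112.0

VALID_CHANNELS = ("actin", "microtubule", "vimentin", "other")


@dataclass(frozen=True)
class Micrograph:
    """A single-channel fluorescence micrograph of one cell.

    Parameters
    ----------
    intensities
        N x M grid of nonnegative gray values (arbitrary fluorescence units).
    pixel_size_nm
        Physical edge length of one pixel in nanometres.
    channel
        Stained cytoskeletal system: ``actin``, ``microtubule``, ``vimentin``
        or ``other``.
    cell_id
        Opaque identifier of the cell.
    condition
        Free-text experimental condition, e.g. a strain duration.
    """

    intensities: np.ndarray
    pixel_size_nm: float
    channel: str = "other"
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("intensities must be a non-empty 2-D grid")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if arr.min() < 0:
            raise ValueError("intensities must be nonnegative")
        if not (self.pixel_size_nm > 0):
            raise ValueError("pixel_size_nm must be positive")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(
                f"channel must be one of {VALID_CHANNELS}, got {self.channel!r}"
            )
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


def read_micrograph(
    path,
    pixel_size_nm: float,
    channel: str = "other",
    cell_id: str = "",
    condition: str = "",
    channel_index: int | None = None,
) -> Micrograph:
    """Read a grayscale TIFF into a :class:`Micrograph`.

    Intensities are taken as stored (8- or 16-bit), without rescaling.  A
    multi-channel plane requires an explicit ``channel_index``.
    """
    if not (pixel_size_nm > 0):
        raise ValueError("pixel_size_nm must be positive")
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"could not read TIFF {path!r}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 3:
        if channel_index is None:
            raise ValueError(
                f"{path!r} holds a multi-channel plane of shape {data.shape}; "
                "pass channel_index to select one channel"
            )
        axis = int(np.argmin(data.shape))  # channel axis is the short one
        data = np.take(data, channel_index, axis=axis)
    if data.ndim != 2:
        raise ValueError(f"{path!r} is not a single-plane image (shape {data.shape})")
    return Micrograph(
        intensities=data.astype(float),
        pixel_size_nm=float(pixel_size_nm),
        channel=channel,
        cell_id=cell_id or str(path),
        condition=condition,
    )


def write_micrograph(path, img: Micrograph, dtype=np.float32) -> None:
    """Write a micrograph's intensity grid as a single-plane TIFF."""
    tifffile.imwrite(path, img.intensities.astype(dtype))


def resample_to_common_grid(
    img: Micrograph, target_pixel_size_nm: float = COMMON_PIXEL_SIZE_NM
) -> Micrograph:
    """Interpolate a micrograph to the common physical pixel size.

    Bilinear interpolation; output dimensions are
    ``round(dim * pixel_size / target)``.  A micrograph already on the target
    grid is returned unchanged.
    """
    if not (target_pixel_size_nm > 0):
        raise ValueError("target pixel size must be positive")
    if img.pixel_size_nm == target_pixel_size_nm:
        return img
    scale = img.pixel_size_nm / target_pixel_size_nm
    n, m = img.shape
    out_n = int(round(n * scale))
    out_m = int(round(m * scale))
    if out_n < 8 or out_m < 8:
        raise ValueError(
            f"resampling {n}x{m} at {img.pixel_size_nm} nm to "
            f"{target_pixel_size_nm} nm gives {out_n}x{out_m}: too small to analyze"
        )
    # Map output pixel centers to source coordinates with aligned pixel edges:
    # source position = (out_index + 0.5) / scale_eff - 0.5.
    rows = (np.arange(out_n) + 0.5) * (n / out_n) - 0.5
    cols = (np.arange(out_m) + 0.5) * (m / out_m) - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(
        img.intensities, [rr, cc], order=1, mode="nearest"
    )
    out = np.clip(out, 0.0, None)
    return replace(img, intensities=out, pixel_size_nm=float(target_pixel_size_nm))


@dataclass
class ManifestRow:
    path: str
    pixel_size_nm: float
    channel: str
    cell_id: str
    condition: str
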