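"""Overlap-normalized auto- and cross-correlograms of binary masks.

The correlogram value at lag ``(i, j)`` is

    C(i, j) = [ sum_{k,l} A(k, l) * B(k+i, l+j) ] / ((N-|i|) (M-|j|))

i.e. the number of coincident set-pixel pairs at that shift divided by the
number of overlapping pixel positions of the two N x M grids.  For boolean
masks this is the joint probability that two positions separated by the lag
vector are both set, so it decays slowest along fiber directions.  Signed
lags are computed; auto-correlograms are point symmetric about zero lag and
their zero-lag value equals the mask's area-coverage fraction.

Two implementations share one contract: a direct-summation path (the test
oracle) and an FFT path with ample zero padding to avoid wrap-around.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as spfft

from cytoorder.segmentation import BinaryMask

DEFAULT_MAX_LAG = 40


@dataclass(frozen=True)
class Correlogram:
    """Zero-lag-centered grid of correlation values.

    ``values`` has shape (2L+1, 2L+1) for maximum lag L; element
    ``values[L + i, L + j]`` is the correlation at lag (i, j).
    ``normalization`` is ``overlap`` (per-lag division by the rectangle
    overlap area) or ``origin`` (further divided by the zero-lag value).
    """

    values: np.ndarray
    pixel_size_nm: float
    normalization: str = "overlap"
    source: str = "auto"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] % 2 == 0 or arr.shape[1] % 2 == 0:
            raise ValueError("correlogram must be 2-D with odd dimensions")
        if self.normalization not in ("overlap", "origin"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.source not in ("auto", "cross"):
            raise ValueError(f"unknown source {self.source!r}")
        object.__setattr__(self, "values", arr)

    @property
    def max_lag(self) -> int:
        return self.values.shape[0] // 2

    @property
    def center(self) -> tuple[int, int]:
        return self.values.shape[0] // 2, self.values.shape[1] // 2

    @property
    def zero_lag(self) -> float:
        return float(self.values[self.center])

    def at_lag(self, i: int, j: int) -> float:
        return float(self.values[self.center[0] + i, self.center[1] + j])


def _check_inputs(maskA: BinaryMask, maskB: BinaryMask, max_lag: int) -> None:
    if maskA.shape != maskB.shape:
        raise ValueError(f"mask dimensions differ: {maskA.shape} vs {maskB.shape}")
    n, m = maskA.shape
    if not (0 <= max_lag < min(n, m)):
        raise ValueError(f"max_lag {max_lag} must be < min(N, M) = {min(n, m)}")


def _overlap_norm(n: int, m: int, max_lag: int) -> np.ndarray:
    lags = np.arange(-max_lag, max_lag + 1)
    return np.outer(n - np.abs(lags), m - np.abs(lags)).astype(float)


def correlate_direct(
    maskA: BinaryMask, maskB: BinaryMask, max_lag: int = DEFAULT_MAX_LAG
) -> Correlogram:
    """Correlogram by direct summation over shifted overlaps (test oracle)."""
    _check_inputs(maskA, maskB, max_lag)
    a = maskA.values.astype(float)
    b = maskB.values.astype(float)
    n, m = a.shape
    out = np.zeros((2 * max_lag + 1, 2 * max_lag + 1))
    for i in range(-max_lag, max_lag + 1):
        a_r = slice(max(0, -i), n - max(0, i))
        b_r = slice(max(0, i), n - max(0, -i))
        for j in range(-max_lag, max_lag + 1):
            a_c = slice(max(0, -j), m - max(0, j))
            b_c = slice(max(0, j), m - max(0, -j))
            out[max_lag + i, max_lag + j] = np.sum(a[a_r, a_c] * b[b_r, b_c])
    out /= _overlap_norm(n, m, max_lag)
    return Correlogram(
        values=out,
        pixel_size_nm=maskA.pixel_size_nm,
        normalization="overlap",
        source="auto" if maskA.values is maskB.values else "cross",
    )


def correlate_fft(
    maskA: BinaryMask, maskB: BinaryMask, max_lag: int = DEFAULT_MAX_LAG
) -> Correlogram:
    """Correlogram via zero-padded FFT; identical contract to the direct path.

    Padding to at least (2N-1) x (2M-1) removes wrap-around; the padded size
    is rounded up to a fast transform length, which does not change values.
    Tiny negative round-off values are clamped to zero (correlations of
    boolean inputs are nonnegative).
    """
    _check_inputs(maskA, maskB, max_lag)
    a = maskA.values.astype(float)
    b = maskB.values.astype(float)
    n, m = a.shape
    pn = spfft.next_fast_len(2 * n - 1)
    pm = spfft.next_fast_len(2 * m - 1)
    fa = spfft.rfft2(a, s=(pn, pm))
    fb = spfft.rfft2(b, s=(pn, pm))
    # raw[i mod pn, j mod pm] = sum_{k,l} A(k,l) B(k+i, l+j)
    raw = spfft.irfft2(np.conj(fa) * fb, s=(pn, pm))
    idx_r = np.arange(-max_lag, max_lag + 1) % pn
    idx_c = np.arange(-max_lag, max_lag + 1) % pm
    out = raw[np.ix_(idx_r, idx_c)]
    out = np.maximum(out, 0.0)
    out /= _overlap_norm(n, m, max_lag)
    return Correlogram(
        values=out,
        pixel_size_nm=maskA.pixel_size_nm,
        normalization="overlap",
        source="auto" if maskA.values is maskB.values else "cross",
    )


def autocorrelate(mask: BinaryMask, max_lag: int = DEFAULT_MAX_LAG) -> Correlogram:
    """FFT auto-correlogram of a mask (zero lag = area coverage)."""
    c = correlate_fft(mask, mask, max_lag)
    return replace(c, source="auto")


def normalize_origin(c: Correlogram) -> Correlogram:
    """Divide a correlogram by its zero-lag value.

    For an auto-correlogram the zero-lag value is the area coverage, so this
    is the coverage normalization applied before orientational analysis.
    """
    z = c.zero_lag
    if z <= 0:
        raise ValueError("cannot normalize: zero-lag value is 0 (empty mask)")
    return replace(c, values=c.values / z, normalization="origin")
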