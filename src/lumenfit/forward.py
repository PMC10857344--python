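"""Image-formation model for lumen cross-sections.

The acquired intensity of a cross-section pixel at world position
``(i*delta_s, j*delta_s)`` is modeled as

    I(i, j) = a + b * F(i*delta_s, j*delta_s)

where ``F`` is the unit-intensity lumen indicator (1 inside the contour, 0
outside) convolved with an isotropic Gaussian point-spread function of
standard deviation ``w`` (mm), and ``a``, ``b`` are the background intensity
and the lumen intensity step in normalized units.  No closed form exists for
the convolution over an arbitrary B-spline region, so it is evaluated
numerically on a supersampled scanline grid: exactly along x (the 1-D
Gaussian integral over each inside-interval is a difference of normal CDFs),
by discrete quadrature across scanlines, then integrated over each detector
pixel's footprint.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .geometry import ContourSpline, evaluate_contour, rasterize_polygon

__all__ = [
    "ImageFormationParams",
    "CrossSectionImage",
    "TruncatedContourWarning",
    "psf_profile",
    "rasterize_indicator",
    "render",
    "save_image_npz",
    "load_image_npz",
    "save_image_png",
    "load_image_png",
]

DEFAULT_SUPERSAMPLE = 8
_CONTOUR_SAMPLES = 512  # dense polygon used for rasterization


class TruncatedContourWarning(UserWarning):
    """The contour extends beyond the image extent and was clipped."""


@dataclass(frozen=True)
class ImageFormationParams:
    """Full parameterization of a model cross-section image.

    ``a``: background intensity, ``b``: lumen intensity step (both in
    normalized units), ``w``: Gaussian PSF standard deviation in mm,
    ``delta_s``: sampling interval in mm, ``N``: half-size (image side is
    ``2N+1``), ``spline``: the lumen contour.  The default PSF width follows
    ``w/delta_s = 0.65``.
    """

    spline: ContourSpline
    a: float = 0.1
    b: float = 0.25
    w: float | None = None
    delta_s: float = 1.0
    N: int = 7

    def __post_init__(self) -> None:
        if self.w is None:
            object.__setattr__(self, "w", 0.65 * self.delta_s)
        if self.w <= 0 or self.delta_s <= 0:
            raise ValueError("w and delta_s must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")


@dataclass
class CrossSectionImage:
    """Square, odd-sided intensity grid with pixel centers at (i*delta_s, j*delta_s).

    ``intensities[j_row, i_col]`` holds the sample whose world position is
    ``x = i*delta_s`` (rightward) and ``y = j*delta_s`` (upward), with
    ``i, j in {-N, ..., N}``; row 0 is ``j = -N``.
    """

    intensities: np.ndarray
    delta_s: float
    valid_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] % 2 == 0:
            raise ValueError("cross-section image must be square with odd side length")
        if not np.all(np.isfinite(arr)):
            raise ValueError("cross-section image contains non-finite intensities")
        self.intensities = arr

    @property
    def N(self) -> int:
        return (self.intensities.shape[0] - 1) // 2

    @property
    def side(self) -> int:
        return self.intensities.shape[0]

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates (mm) of pixel columns (x) and rows (y)."""
        idx = np.arange(-self.N, self.N + 1, dtype=float)
        return idx * self.delta_s, idx * self.delta_s


def psf_profile(w: float, x_offsets: np.ndarray, y_offsets: np.ndarray | None = None) -> np.ndarray:
    """Discrete isotropic Gaussian PSF kernel, normalized to unit sum.

    ``x_offsets``/``y_offsets`` are spatial offsets in mm; offsets farther
    than ``4*w`` from the center carry (and are assigned) zero weight.
    """
    if w <= 0:
        raise ValueError("w must be positive")
    x = np.asarray(x_offsets, dtype=float)
    y = x if y_offsets is None else np.asarray(y_offsets, dtype=float)
    r2 = x[None, :] ** 2 + y[:, None] ** 2
    kernel = np.exp(-r2 / (2.0 * w**2))
    kernel[r2 > (4.0 * w) ** 2] = 0.0
    return kernel / kernel.sum()


def _fine_grid(N: int, delta_s: float, supersample: int) -> np.ndarray:
    """Centers of the supersampled cells covering the image extent (one axis)."""
    L = (2 * N + 1) * supersample
    return (np.arange(L) + 0.5) / supersample * delta_s - (N + 0.5) * delta_s


def rasterize_indicator(
    spline: ContourSpline,
    supersample: int = DEFAULT_SUPERSAMPLE,
    N: int = 7,
    delta_s: float = 1.0,
    num_contour_points: int = _CONTOUR_SAMPLES,
) -> np.ndarray:
    """Even-odd fill of the lumen region on a supersampled grid.

    Returns a ``((2N+1)*supersample,)**2`` uint8 grid covering the image
    extent ``[-(N+0.5)*delta_s, (N+0.5)*delta_s]``; parts of the contour
    outside the extent are clipped with :class:`TruncatedContourWarning`.
    """
    if supersample < 4:
        raise ValueError("supersample must be >= 4")
    if np.all(spline.d == 0.0):
        side = (2 * N + 1) * supersample
        return np.zeros((side, side), dtype=np.uint8)
    poly = evaluate_contour(spline, num_contour_points)
    coords = _fine_grid(N, delta_s, supersample)
    half_extent = (N + 0.5) * delta_s
    if np.any(np.abs(poly) > half_extent):
        warnings.warn("contour extends beyond the image extent; clipped",
                      TruncatedContourWarning, stacklevel=2)
    return rasterize_polygon(poly, coords, coords)


def _scanline_intervals(polygon: np.ndarray, y_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Even-odd inside-intervals of a polygon along horizontal scanlines.

    Returns two ``(n_rows, m)`` arrays of interval left/right x endpoints,
    padded with empty (l == r == 0) intervals where a row has fewer crossings.
    """
    x1, y1 = polygon[:, 0], polygon[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    keep = ~((x1 == x2) & (y1 == y2))
    x1, y1, x2, y2 = x1[keep], y1[keep], x2[keep], y2[keep]
    py = y_rows[:, None]
    crosses = (y1 <= py) != (y2 <= py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = np.where(crosses, x1 + (py - y1) * (x2 - x1) / (y2 - y1), np.inf)
    xint.sort(axis=1)
    n_cross = crosses.sum(axis=1)
    max_pairs = int(np.max(n_cross, initial=0)) // 2
    if max_pairs == 0:
        return np.zeros((y_rows.size, 1)), np.zeros((y_rows.size, 1))
    left = xint[:, 0:2 * max_pairs:2].copy()
    right = xint[:, 1:2 * max_pairs:2].copy()
    empty = ~np.isfinite(left) | ~np.isfinite(right)
    left[empty] = 0.0
    right[empty] = 0.0
    return left, right


def render(
    params: ImageFormationParams,
    supersample: int = DEFAULT_SUPERSAMPLE,
) -> CrossSectionImage:
    """Numerically evaluate the forward model ``I = a + b * (f ⊛ h)``.

    The convolution of the lumen indicator with the Gaussian PSF is computed
    semi-analytically: on each of ``supersample`` scanlines per pixel row the
    polygon's inside-intervals are convolved with the 1-D Gaussian exactly
    (differences of normal CDFs), the second 1-D convolution across scanlines
    is evaluated by discrete quadrature, and the result is averaged over each
    pixel's footprint.  The scheme is smooth in the contour parameters below
    the subpixel scale, which the least-squares identification relies on;
    ``0 <= F <= 1`` pointwise.  Lumen parts beyond the image extent are
    clipped, consistent with :func:`rasterize_indicator`.
    """
    if supersample < 4:
        warnings.warn("supersample < 4 degrades rendering accuracy", stacklevel=2)
    side = 2 * params.N + 1
    spline = params.spline
    if np.all(spline.d == 0.0):
        return CrossSectionImage(np.full((side, side), params.a), params.delta_s)
    poly = evaluate_contour(spline, _CONTOUR_SAMPLES)
    coords = _fine_grid(params.N, params.delta_s, supersample)
    half_extent = (params.N + 0.5) * params.delta_s
    left, right = _scanline_intervals(poly, coords)
    np.clip(left, -half_extent, half_extent, out=left)
    np.clip(right, -half_extent, half_extent, out=right)
    # exact 1-D convolution along x: sum of CDF differences per interval
    from scipy.special import ndtr

    arg = coords[None, :, None]  # (rows=1, x, m=1) broadcast target
    inv_w = 1.0 / params.w
    profile = ndtr((arg - left[:, None, :]) * inv_w) - ndtr((arg - right[:, None, :]) * inv_w)
    A = profile.sum(axis=2)  # (rows, x)
    # discrete quadrature of the y-convolution, then pixel-footprint average
    sigma_rows = params.w * supersample / params.delta_s
    blurred = gaussian_filter1d(A, sigma_rows, axis=0, mode="constant", cval=0.0, truncate=4.0)
    F = blurred.reshape(side, supersample, side, supersample).mean(axis=(1, 3))
    np.clip(F, 0.0, 1.0, out=F)
    return CrossSectionImage(params.a + params.b * F, params.delta_s)


# --- I/O ------------------------------------------------------------------

def save_image_npz(path, image: CrossSectionImage) -> None:
    np.savez(path, intensities=image.intensities, delta_s=image.delta_s, N=image.N)


def load_image_npz(path) -> CrossSectionImage:
    with np.load(path) as data:
        return CrossSectionImage(data["intensities"], float(data["delta_s"]))


def save_image_png(path, image: CrossSectionImage) -> None:
    """16-bit PNG with a JSON sidecar recording the intensity scale and pixel size."""
    from PIL import Image

    lo = float(image.intensities.min())
    hi = float(image.intensities.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    arr = np.round((image.intensities - lo) * scale).astype(np.uint16)
    Image.fromarray(arr, mode="I;16").save(path)
    sidecar = {"lo": lo, "hi": hi, "delta_s": image.delta_s}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_image_png(path) -> CrossSectionImage:
    from PIL import Image

    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    arr = np.asarray(Image.open(path), dtype=float)
    lo, hi = sidecar["lo"], sidecar["hi"]
    if hi > lo:
        arr = arr / 65535.0 * (hi - lo) + lo
    else:
        arr = np.full_like(arr, lo)
    return CrossSectionImage(arr, float(sidecar["delta_s"]))
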