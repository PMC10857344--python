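"""Centerline frames and oblique cross-section extraction from 3D volumes.

An externally produced vessel centerline (an ordered list of 3D world-mm
points) is approximated by a smoothing spline, resampled at a regular
arc-length step, and equipped with rotation-minimizing frames: orthonormal
(tangent, normal, binormal) triads propagated by the double-reflection
method, which avoids the spurious twist of Frenet frames around the tangent.
Cross-section images are then sampled from the volume by trilinear
interpolation on the plane spanned by each frame's normal and binormal,
centered on the centerline point — the geometry on which the lumen contour
model operates.

Upstream centerline discovery (vesselness filtering, thresholding, thinning,
skeleton parsing) is out of scope; published third-party implementations of
those steps produce the point lists this module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import splev, splprep
from scipy.ndimage import map_coordinates

from .forward import CrossSectionImage

__all__ = [
    "Centerline",
    "FrameSequence",
    "Volume3D",
    "smooth_centerline",
    "rotation_minimizing_frames",
    "frenet_frames",
    "extract_cross_section",
    "extract_sections",
    "normalize_ct",
    "load_volume",
    "load_centerline_csv",
    "save_centerline_csv",
]

DEFAULT_SPACING_MM = 0.5
HU_CLIP = (-300.0, 800.0)


@dataclass
class Centerline:
    """Ordered 3D world-coordinate points (mm) with unit tangents."""

    points: np.ndarray  # (K, 3)
    tangents: np.ndarray  # (K, 3), unit norm
    spacing: float = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        if self.points.shape != self.tangents.shape or self.points.shape[1] != 3:
            raise ValueError("points and tangents must both be (K, 3)")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0.0):
            raise ValueError("consecutive centerline points must be distinct")
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("tangents must be unit vectors")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class FrameSequence:
    """Per-point right-handed orthonormal triads (tangent, normal, binormal)."""

    tangents: np.ndarray
    normals: np.ndarray
    binormals: np.ndarray

    def __len__(self) -> int:
        return self.tangents.shape[0]

    def twist(self) -> np.ndarray:
        """Per-step rotation (radians) of the normal about the tangent."""
        angles = np.empty(len(self) - 1)
        for k in range(len(self) - 1):
            # transport normal k to frame k+1 by minimal rotation, then compare
            transported = _rotate_between(self.tangents[k], self.tangents[k + 1],
                                          self.normals[k])
            cosang = np.clip(np.dot(transported, self.normals[k + 1]), -1.0, 1.0)
            angles[k] = np.arccos(cosang)
        return angles


@dataclass
class Volume3D:
    """3D intensity grid with world geometry (all lengths in mm).

    ``data`` is indexed ``[z, y, x]`` (the layout volume readers produce);
    ``spacing``, ``origin`` and the direction-cosine matrix are given in
    world (x, y, z) order, so world = origin + direction @ (index * spacing).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray | None = None
    units: str = "normalized"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacings must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        if self.direction is None:
            self.direction = np.eye(3)
        else:
            self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (x, y, z) voxel indices of world-mm points."""
        rel = np.atleast_2d(points) - self.origin
        local = rel @ np.linalg.inv(self.direction).T
        return local / self.spacing


def _rotate_between(t0: np.ndarray, t1: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate v by the minimal rotation taking unit vector t0 onto t1."""
    c = float(np.dot(t0, t1))
    axis = np.cross(t0, t1)
    s2 = float(np.dot(axis, axis))
    if s2 < 1e-24:
        return v if c > 0 else -v
    # Rodrigues with sin/cos expressed via the cross product terms
    return v * c + np.cross(axis, v) + axis * np.dot(axis, v) * (1.0 - c) / s2


def smooth_centerline(raw_points: np.ndarray, smoothing: float = 0.0,
                      spacing: float = DEFAULT_SPACING_MM) -> Centerline:
    """Approximate noisy skeleton points by a differentiable 3D curve.

    A smoothing spline is fitted per coordinate against the chord-length
    parameter (``smoothing`` is the spline residual budget; 0 interpolates)
    and resampled at the requested arc-length step, with tangents evaluated
    analytically from the spline derivative.
    """
    pts = np.asarray(raw_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("need at least 4 ordered 3D points")
    tck, _ = splprep(pts.T, s=smoothing, k=3)
    # dense arc-length table, then uniform-arc resampling
    u_dense = np.linspace(0.0, 1.0, 20 * pts.shape[0])
    dense = np.stack(splev(u_dense, tck), axis=1)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n_out = max(2, int(np.floor(total / spacing)) + 1)
    targets = np.linspace(0.0, total, n_out)
    u_out = np.interp(targets, arc, u_dense)
    points = np.stack(splev(u_out, tck), axis=1)
    deriv = np.stack(splev(u_out, tck, der=1), axis=1)
    norms = np.linalg.norm(deriv, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("degenerate centerline: zero-length tangent")
    return Centerline(points=points, tangents=deriv / norms, spacing=spacing)


def rotation_minimizing_frames(centerline: Centerline,
                               initial_normal: np.ndarray | None = None) -> FrameSequence:
    """Propagate an initial normal along the curve by double reflection.

    Each step applies two reflections (in the chord's bisecting plane, then
    in the new tangent's bisecting plane), which transports the frame with
    the minimal possible rotation about the tangent; successive frames stay
    orthonormal and right-handed to machine precision.
    """
    pts = centerline.points
    tangents = centerline.tangents
    K = len(centerline)
    if initial_normal is None:
        # world axis least aligned with the first tangent, projected
        axis = np.zeros(3)
        axis[np.argmin(np.abs(tangents[0]))] = 1.0
        initial_normal = axis
    r = np.asarray(initial_normal, dtype=float)
    r = r - np.dot(r, tangents[0]) * tangents[0]
    norm = np.linalg.norm(r)
    if norm < 1e-12:
        raise ValueError("initial normal is parallel to the first tangent")
    r = r / norm
    normals = np.empty((K, 3))
    normals[0] = r
    for k in range(K - 1):
        v1 = pts[k + 1] - pts[k]
        c1 = float(np.dot(v1, v1))
        if c1 == 0.0:
            raise ValueError("zero-length centerline step")
        rL = normals[k] - (2.0 / c1) * np.dot(v1, normals[k]) * v1
        tL = tangents[k] - (2.0 / c1) * np.dot(v1, tangents[k]) * v1
        v2 = tangents[k + 1] - tL
        c2 = float(np.dot(v2, v2))
        if c2 > 0.0:
            normals[k + 1] = rL - (2.0 / c2) * np.dot(v2, rL) * v2
        else:
            normals[k + 1] = rL
        # guard against drift out of the tangent-orthogonal plane
        n = normals[k + 1] - np.dot(normals[k + 1], tangents[k + 1]) * tangents[k + 1]
        normals[k + 1] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)
    return FrameSequence(tangents=tangents.copy(), normals=normals, binormals=binormals)


def frenet_frames(centerline: Centerline) -> FrameSequence:
    """Discrete Frenet frames (normal from tangent differences); twist-prone.

    Provided as the classical reference the rotation-minimizing frames are
    compared against; falls back to parallel transport where the curve is
    locally straight and the Frenet normal is undefined.
    """
    tangents = centerline.tangents
    K = len(centerline)
    normals = np.empty((K, 3))
    prev = None
    for k in range(K):
        if k == 0:
            dt = tangents[1] - tangents[0]
        elif k == K - 1:
            dt = tangents[-1] - tangents[-2]
        else:
            dt = tangents[k + 1] - tangents[k - 1]
        n = dt - np.dot(dt, tangents[k]) * tangents[k]
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            n = prev if prev is not None else _any_orthogonal(tangents[k])
            n = n - np.dot(n, tangents[k]) * tangents[k]
            norm = np.linalg.norm(n)
        normals[k] = n / norm
        prev = normals[k]
    return FrameSequence(tangents=tangents.copy(), normals=normals,
                         binormals=np.cross(tangents, normals))


def _any_orthogonal(t: np.ndarray) -> np.ndarray:
    axis = np.zeros(3)
    axis[np.argmin(np.abs(t))] = 1.0
    return axis - np.dot(axis, t) * t


def extract_cross_section(
    volume: Volume3D,
    point: np.ndarray,
    normal: np.ndarray,
    binormal: np.ndarray,
    N: int = 7,
    delta_s: float = 1.0,
    fill_value: float = 0.0,
) -> CrossSectionImage:
    """Trilinear plane resampling of the volume at a centerline point.

    Samples the ``(2N+1)**2`` world positions ``point + i*delta_s*normal +
    j*delta_s*binormal`` for ``i, j in {-N..N}``; out-of-volume samples take
    ``fill_value`` and are recorded in the image's validity mask.
    """
    point = np.asarray(point, dtype=float).reshape(3)
    idx = np.arange(-N, N + 1, dtype=float) * delta_s
    grid = (point[None, None, :]
            + idx[None, :, None] * np.asarray(normal, dtype=float)
            + idx[:, None, None] * np.asarray(binormal, dtype=float))
    indices = volume.world_to_index(grid.reshape(-1, 3))  # (n, 3) in (x, y, z)
    coords_zyx = indices[:, ::-1].T
    dims = np.asarray(volume.data.shape, dtype=float)  # (z, y, x)
    inside = np.all((coords_zyx.T >= 0) & (coords_zyx.T <= dims - 1), axis=1)
    if not np.any(inside):
        raise ValueError("cross-section plane lies entirely outside the volume")
    values = map_coordinates(volume.data, coords_zyx, order=1,
                             mode="constant", cval=fill_value)
    side = 2 * N + 1
    return CrossSectionImage(values.reshape(side, side), delta_s,
                             valid_mask=inside.reshape(side, side))


def extract_sections(volume: Volume3D, centerline: Centerline,
                     frames: FrameSequence | None = None,
                     N: int = 7, delta_s: float = 1.0) -> list[CrossSectionImage]:
    """Cross-sections at every centerline point using its RMF frame."""
    if frames is None:
        frames = rotation_minimizing_frames(centerline)
    return [
        extract_cross_section(volume, centerline.points[k], frames.normals[k],
                              frames.binormals[k], N=N, delta_s=delta_s)
        for k in range(len(centerline))
    ]


def normalize_ct(volume: Volume3D, lo: float = HU_CLIP[0],
                 hi: float = HU_CLIP[1]) -> Volume3D:
    """Clip CT intensities to [lo, hi] HU and map affinely onto [0, 1]."""
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    data = (np.clip(volume.data, lo, hi) - lo) / (hi - lo)
    return Volume3D(data=data, spacing=volume.spacing.copy(),
                    origin=volume.origin.copy(), direction=volume.direction.copy(),
                    units="normalized")


# --- I/O ------------------------------------------------------------------

def load_volume(path) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) volume."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    return Volume3D(
        data=data,
        spacing=np.asarray(img.GetSpacing()),
        origin=np.asarray(img.GetOrigin()),
        direction=np.asarray(img.GetDirection()).reshape(3, 3),
        units="HU" if data.min() < 0 else "raw",
    )


def load_centerline_csv(path) -> np.ndarray:
    data = np.genfromtxt(path, delimiter=",", skip_header=1, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError(f"{path}: expected three columns x_mm,y_mm,z_mm")
    return data


def save_centerline_csv(path, points: np.ndarray) -> None:
    pts = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("x_mm,y_mm,z_mm\n")
        for x, y, z in pts:
            fh.write(f"{x:.9g},{y:.9g},{z:.9g}\n")
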