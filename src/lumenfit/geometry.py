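"""Closed periodic cubic B-spline lumen contours.

A lumen cross-section boundary is modeled as a closed cubic B-spline whose
control points lie on ``D`` radial lines through the section center, at angles
``phi_i = 2*pi*i/D``.  The distance of control point ``C_i`` from the center is
``R * d_i * delta_s`` where ``d = (d_0, ..., d_{D-1})`` is the dimensionless
shape-parameter vector, ``R`` a fixed scale factor and ``delta_s`` the pixel
size in mm.  A negative ``d_i`` places the control point on the opposite
radial line (angle ``phi_i + pi``), which lets the contour model concave,
near-center boundaries.

Closure is obtained by cyclically wrapping the first ``degree`` control points
(``C_D = C_0, C_{D+1} = C_1, C_{D+2} = C_2`` for cubics) on a uniform integer
knot vector, so the curve is C^2-continuous everywhere including the seam and
has exactly ``D`` free shape parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "ContourSpline",
    "basis",
    "control_points",
    "evaluate_contour",
    "polygon_area",
    "point_in_contour",
    "points_in_polygon",
    "rasterize_polygon",
    "save_spline_json",
    "load_spline_json",
    "save_polygon_csv",
    "load_polygon_csv",
]


class DegenerateContourWarning(UserWarning):
    """Raised (as a warning) when a contour collapses to its center point."""


@dataclass(frozen=True)
class ContourSpline:
    """Closed cubic B-spline contour with radial control points.

    Parameters
    ----------
    d : array-like of shape (D,)
        Dimensionless radial control distances, typically in [-0.3, 1.0].
    R : float
        Dimensionless scale factor (fixed per image configuration).
    delta_s : float
        Sampling interval (pixel size), mm.
    center : (2,) array-like
        Offset of the radial origin in mm, default (0, 0).
    """

    d: np.ndarray
    R: float = 11.0
    delta_s: float = 1.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    degree: int = 3

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if d.ndim != 1 or d.size < 4:
            raise ValueError(f"d must be a vector with D >= 4 entries, got shape {d.shape}")
        if self.degree != 3:
            raise ValueError("only cubic (degree 3) contours are supported")
        if self.delta_s <= 0:
            raise ValueError("delta_s must be positive")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(2))

    @property
    def D(self) -> int:
        """Number of free radial control distances."""
        return self.d.size

    @property
    def knots(self) -> np.ndarray:
        """Uniform integer knot vector for the wrapped control polygon."""
        # D + degree wrapped control points need D + 2*degree + 1 knots.
        return np.arange(self.D + 2 * self.degree + 1, dtype=float)

    @property
    def domain(self) -> tuple[float, float]:
        """Parameter interval on which the closed curve is traversed once."""
        return float(self.degree), float(self.degree + self.D)

    def with_d(self, d: np.ndarray) -> "ContourSpline":
        return replace(self, d=np.asarray(d, dtype=float))


def basis(i: int, j: int, t: float, knots: np.ndarray) -> float:
    """B-spline basis function ``B_{i,j}(t)`` by the de Boor recursion.

    Degree-0 bases are indicators of the half-open knot span
    ``t_i <= t < t_{i+1}``; 0/0 terms in the recursion are taken as 0.
    """
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) < 0):
        raise ValueError("knot sequence must be nondecreasing")
    if j < 0:
        raise ValueError("degree must be nonnegative")
    if i < 0 or i + j + 1 >= knots.size:
        raise ValueError(f"knot sequence too short for basis index ({i}, {j})")
    if j == 0:
        return 1.0 if knots[i] <= t < knots[i + 1] else 0.0
    left_den = knots[i + j] - knots[i]
    right_den = knots[i + j + 1] - knots[i + 1]
    left = 0.0 if left_den == 0.0 else (t - knots[i]) / left_den * basis(i, j - 1, t, knots)
    right = (
        0.0
        if right_den == 0.0
        else (knots[i + j + 1] - t) / right_den * basis(i + 1, j - 1, t, knots)
    )
    return left + right


def control_points(
    d: np.ndarray,
    R: float,
    delta_s: float,
    center: np.ndarray = (0.0, 0.0),
) -> np.ndarray:
    """Control-point coordinates (mm) on radial lines at angles ``2*pi*i/D``.

    ``C_i = R * d_i * delta_s * (cos phi_i, sin phi_i) + center``; a negative
    ``d_i`` automatically lands on the opposite radial line ``phi_i + pi``.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    if d.size < 4:
        raise ValueError("need D >= 4 control distances")
    phi = 2.0 * np.pi * np.arange(d.size) / d.size
    pts = (R * d * delta_s)[:, None] * np.stack([np.cos(phi), np.sin(phi)], axis=1)
    return pts + np.asarray(center, dtype=float)


def _wrapped_control_points(spline: ContourSpline) -> np.ndarray:
    cp = control_points(spline.d, spline.R, spline.delta_s, spline.center)
    return np.vstack([cp, cp[: spline.degree]])


def evaluate_contour(spline: ContourSpline, num_points: int = 100) -> np.ndarray:
    """Sample the closed contour at uniform parameter steps.

    Returns an ``(num_points, 2)`` array in mm whose first and last points
    coincide (closed polygon).  A fully degenerate contour (all ``d_i = 0``)
    returns the center repeated and emits :class:`DegenerateContourWarning`.
    """
    if num_points < spline.D:
        raise ValueError("num_points must be at least D")
    if np.all(spline.d == 0.0):
        warnings.warn("all control distances are zero; contour degenerates to the center",
                      DegenerateContourWarning, stacklevel=2)
        return np.tile(spline.center, (num_points, 1))
    cp = _wrapped_control_points(spline)
    bspl = BSpline(spline.knots, cp, spline.degree, extrapolate=False)
    t0, t1 = spline.domain
    t = np.linspace(t0, t1, num_points)
    pts = bspl(t)
    pts[-1] = pts[0]  # closure is exact analytically; pin the float endpoint
    return pts


def polygon_area(polygon: np.ndarray) -> float:
    """Absolute shoelace area (mm^2) of a closed polygon.

    Orientation independent.  For self-intersecting polygons this is the
    magnitude of the signed sum; callers may detect that case separately.
    """
    p = np.asarray(polygon, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise ValueError("polygon must be an (n>=3, 2) array")
    x, y = p[:, 0], p[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def points_in_polygon(polygon: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (crossing number) membership test.

    Boundary points are a measure-zero set and may resolve either way here;
    :func:`point_in_contour` adds an explicit boundary check.
    """
    poly = np.asarray(polygon, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    px = pts[:, 0][:, None]
    py = pts[:, 1][:, None]
    crosses = (y1 <= py) != (y2 <= py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    inside = np.sum(crosses & (px < xint), axis=1) % 2 == 1
    return inside


def _on_boundary(polygon: np.ndarray, p: np.ndarray, tol: float = 1e-12) -> bool:
    a = np.asarray(polygon, dtype=float)
    b = np.roll(a, -1, axis=0)
    ab = b - a
    ap = p[None, :] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.clip(np.where(denom > 0, np.einsum("ij,ij->i", ap, ab) / denom, 0.0), 0.0, 1.0)
    closest = a + s[:, None] * ab
    return bool(np.min(np.linalg.norm(p[None, :] - closest, axis=1)) <= tol)


def point_in_contour(polygon: np.ndarray, p: np.ndarray) -> bool:
    """Even-odd membership of a single point; boundary points count as inside."""
    p = np.asarray(p, dtype=float).reshape(2)
    if _on_boundary(polygon, p):
        return True
    return bool(points_in_polygon(polygon, p[None, :])[0])


def rasterize_polygon(
    polygon: np.ndarray,
    x_coords: np.ndarray,
    y_coords: np.ndarray,
) -> np.ndarray:
    """Even-odd scanline fill of a polygon on a rectilinear grid.

    Parameters give the x coordinates of the grid columns and y coordinates of
    the grid rows; the result has shape ``(len(y_coords), len(x_coords))`` with
    1 inside the polygon and 0 outside (even-odd rule, robust to
    self-intersection).
    """
    poly = np.asarray(polygon, dtype=float)
    x_coords = np.asarray(x_coords, dtype=float)
    y_coords = np.asarray(y_coords, dtype=float)
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    keep = ~((x1 == x2) & (y1 == y2))
    x1, y1, x2, y2 = x1[keep], y1[keep], x2[keep], y2[keep]
    mask = np.zeros((y_coords.size, x_coords.size), dtype=np.uint8)
    py = y_coords[:, None]
    crosses = (y1 <= py) != (y2 <= py)  # (rows, edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    for r in range(y_coords.size):
        xs = np.sort(xint[r, crosses[r]])
        if xs.size == 0:
            continue
        # even-odd: columns with an odd number of crossings to their right
        counts = xs.size - np.searchsorted(xs, x_coords, side="right")
        mask[r] = (counts % 2).astype(np.uint8)
    return mask


# --- I/O ------------------------------------------------------------------

def save_spline_json(path, spline: ContourSpline) -> None:
    obj = {
        "d": spline.d.tolist(),
        "R": spline.R,
        "delta_s": spline.delta_s,
        "D": spline.D,
        "degree": spline.degree,
        "center": spline.center.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_spline_json(path) -> ContourSpline:
    with open(path) as fh:
        obj = json.load(fh)
    return ContourSpline(
        d=np.asarray(obj["d"], dtype=float),
        R=float(obj["R"]),
        delta_s=float(obj["delta_s"]),
        center=np.asarray(obj.get("center", (0.0, 0.0)), dtype=float),
        degree=int(obj.get("degree", 3)),
    )


def save_polygon_csv(path, polygon: np.ndarray) -> None:
    p = np.asarray(polygon, dtype=float)
    with open(path, "w") as fh:
        fh.write("x_mm,y_mm\n")
        for x, y in p:
            fh.write(f"{x:.9g},{y:.9g}\n")


def load_polygon_csv(path) -> np.ndarray:
    data = np.genfromtxt(path, delimiter=",", skip_header=1, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns x_mm,y_mm")
    return data
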