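"""Reference least-squares identification of the lumen model.

Given an acquired cross-section image and the fixed configuration constants
(scale factor ``R``, PSF width ``w``, pixel size ``delta_s``, control count
``D``), the ``P = D + 2`` adjustable parameters ``p = (a, b, d)`` are found
by bounded minimization of the sum of squared differences between acquired
and modeled pixel intensities.  This is a nonlinear local search: the result
is the best local optimum reached from the initialization, not a guaranteed
global one, which is precisely why the CNN regressor exists as the fast and
robust alternative.

The module also fits a B-spline contour directly to an observer-marked
polygon by minimizing the mean contour distance over ``d`` — the step that
converts expert annotations into network training targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .forward import CrossSectionImage, ImageFormationParams, render
from .geometry import ContourSpline, evaluate_contour, polygon_area
from .metrics import mdist, resample_contour

__all__ = [
    "FitBounds",
    "FitResult",
    "fit_image",
    "fit_spline_to_polygon",
    "fit_directory",
]


@dataclass(frozen=True)
class FitBounds:
    """Search box and initialization range for the LS fit."""

    a_bounds: tuple[float, float] = (0.0, 0.3)
    b_bounds: tuple[float, float] = (0.1, 0.5)
    d_bounds: tuple[float, float] = (-0.3, 1.0)
    d_init_range: tuple[float, float] = (0.2, 0.4)

    def __post_init__(self) -> None:
        for lo, hi in (self.a_bounds, self.b_bounds, self.d_bounds, self.d_init_range):
            if not lo < hi:
                raise ValueError("each bounds pair must satisfy lower < upper")


@dataclass
class FitResult:
    a_hat: float
    b_hat: float
    d_hat: np.ndarray
    objective: float
    converged: bool
    n_evaluations: int
    message: str = field(default="", repr=False)

    @property
    def p_hat(self) -> np.ndarray:
        return np.concatenate([[self.a_hat, self.b_hat], self.d_hat])


def _objective_factory(image: CrossSectionImage, R: float, w: float,
                       delta_s: float, N: int, supersample: int):
    target = image.intensities

    def objective(p: np.ndarray) -> float:
        a, b = p[0], p[1]
        spline = ContourSpline(d=p[2:], R=R, delta_s=delta_s)
        params = ImageFormationParams(spline=spline, a=a, b=b, w=w,
                                      delta_s=delta_s, N=N)
        model = render(params, supersample).intensities
        resid = target - model
        return float(np.sum(resid * resid))

    return objective


def fit_image(
    image: CrossSectionImage,
    R: float = 11.0,
    w: float | None = None,
    delta_s: float | None = None,
    D: int = 10,
    bounds: FitBounds = FitBounds(),
    init: np.ndarray | None = None,
    supersample: int = 8,
    maxiter: int = 300,
    ftol: float = 1e-12,
    n_restarts: int = 2,
    restart_objective: float = 1e-8,
    restart_seed: int = 0,
) -> FitResult:
    """Bounded least-squares fit of ``(a, b, d)`` to an acquired image.

    ``R``, ``w`` and ``delta_s`` are treated as known constants (``w``
    defaults to ``0.65 * delta_s``).  The default start point puts ``a`` and
    ``b`` at their bound midpoints and every ``d_i`` at the midpoint of the
    initialization range.  The search is local and can stall in a poor
    minimum; when the achieved objective exceeds ``restart_objective``, up
    to ``n_restarts`` further attempts are made from start points drawn
    uniformly from the initialization range (deterministic via
    ``restart_seed``), keeping the best result.  Optimizer non-convergence
    is reported through ``converged`` rather than raised.
    """
    if not np.all(np.isfinite(image.intensities)):
        raise ValueError("image contains NaN or infinite pixels")
    delta_s = image.delta_s if delta_s is None else delta_s
    if w is None:
        w = 0.65 * delta_s
    N = image.N
    if init is None:
        init = np.concatenate([
            [np.mean(bounds.a_bounds), np.mean(bounds.b_bounds)],
            np.full(D, np.mean(bounds.d_init_range)),
        ])
    init = np.asarray(init, dtype=float)
    if init.size != D + 2:
        raise ValueError(f"initial point must have {D + 2} entries (a, b, d)")
    box = [bounds.a_bounds, bounds.b_bounds] + [bounds.d_bounds] * D
    objective = _objective_factory(image, R, w, delta_s, N, supersample)
    restart_rng = np.random.default_rng(restart_seed)
    result = None
    nfev = 0
    for attempt in range(1 + max(0, n_restarts)):
        start = init if attempt == 0 else np.concatenate([
            [restart_rng.uniform(*bounds.a_bounds),
             restart_rng.uniform(*bounds.b_bounds)],
            restart_rng.uniform(*bounds.d_init_range, size=D),
        ])
        trial = minimize(objective, start, method="SLSQP", bounds=box,
                         options={"maxiter": maxiter, "ftol": ftol})
        nfev += int(trial.nfev)
        if trial.fun > restart_objective and D % 2 == 0 and np.sum(trial.x[2:]) < 0:
            # the optimizer slid into the mirrored parameter branch
            # (d ~ -roll(d, D/2) traces the same curve) where the asymmetric
            # d-bounds pin it at the lower edge; re-polish from the
            # equivalent positive-branch representation
            alt = trial.x.copy()
            alt[2:] = np.clip(-np.roll(trial.x[2:], D // 2), *bounds.d_bounds)
            trial2 = minimize(objective, alt, method="SLSQP", bounds=box,
                              options={"maxiter": maxiter, "ftol": ftol})
            nfev += int(trial2.nfev)
            if trial2.fun < trial.fun:
                trial = trial2
        if result is None or trial.fun < result.fun:
            result = trial
        if result.fun <= restart_objective:
            break
    p = np.clip(result.x, [b[0] for b in box], [b[1] for b in box])
    # For even D the parameterization has an exact two-fold symmetry:
    # d and -roll(d, D/2) trace the identical curve (a control point at
    # distance -x on ray i sits at distance x on ray i + D/2).  Report the
    # representative with nonnegative total, provided it stays in bounds.
    if D % 2 == 0 and np.sum(p[2:]) < 0.0:
        alt = -np.roll(p[2:], D // 2)
        if np.all(alt >= bounds.d_bounds[0]) and np.all(alt <= bounds.d_bounds[1]):
            p = np.concatenate([p[:2], alt])
    return FitResult(
        a_hat=float(p[0]),
        b_hat=float(p[1]),
        d_hat=p[2:].copy(),
        objective=objective(p),
        converged=bool(result.success),
        n_evaluations=nfev,
        message=str(result.message),
    )


def _radial_profile_init(polygon: np.ndarray, D: int, R: float, delta_s: float,
                         center: np.ndarray) -> np.ndarray:
    """Initialize d from the polygon's radius at each control angle."""
    dense = resample_contour(polygon, 500) - center
    angles = np.arctan2(dense[:, 1], dense[:, 0])
    radii = np.linalg.norm(dense, axis=1)
    phi = 2.0 * np.pi * np.arange(D) / D
    d0 = np.empty(D)
    for i in range(D):
        diff = np.angle(np.exp(1j * (angles - phi[i])))
        d0[i] = radii[np.argmin(np.abs(diff))] / (R * delta_s)
    return d0


def fit_spline_to_polygon(
    polygon: np.ndarray,
    D: int = 10,
    R: float = 10.0,
    delta_s: float = 0.45,
    center: np.ndarray = (0.0, 0.0),
    init: np.ndarray | None = None,
    maxiter: int = 400,
) -> tuple[np.ndarray, float]:
    """Fit contour shape parameters ``d`` to an observed polygon.

    Minimizes the mean contour distance between the fixed polygon and the
    evaluated B-spline over ``d`` (derivative-free Powell search, smooth in
    ``d`` thanks to the uniform resampling inside the metric).  Returns the
    optimal ``d`` and the achieved mDist in mm.
    """
    polygon = np.asarray(polygon, dtype=float)
    if polygon.shape[0] < D:
        raise ValueError(f"polygon must have at least D={D} points")
    if polygon_area(polygon) < 1e-12:
        raise ValueError("degenerate polygon with (near) zero area")
    center = np.asarray(center, dtype=float).reshape(2)
    if init is None:
        init = _radial_profile_init(polygon, D, R, delta_s, center)

    def objective(d: np.ndarray) -> float:
        spline = ContourSpline(d=d, R=R, delta_s=delta_s, center=center)
        return mdist(polygon, evaluate_contour(spline, 200))

    result = minimize(objective, np.asarray(init, dtype=float), method="Powell",
                      options={"maxiter": maxiter, "xtol": 1e-6, "ftol": 1e-8})
    return result.x.copy(), float(result.fun)


def fit_directory(images: dict[str, CrossSectionImage], out_dir,
                  **fit_kwargs) -> pd.DataFrame:
    """Fit every image, write per-image JSON results and a combined CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, image in sorted(images.items()):
        res = fit_image(image, **fit_kwargs)
        record = {
            "id": name, "a_hat": res.a_hat, "b_hat": res.b_hat,
            **{f"d{j}": res.d_hat[j] for j in range(res.d_hat.size)},
            "objective": res.objective, "converged": res.converged,
        }
        rows.append(record)
        with open(out_dir / f"{name}.json", "w") as fh:
            json.dump({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in record.items()}, fh, indent=1)
    frame = pd.DataFrame(rows)
    frame.to_csv(out_dir / "fits.csv", index=False)
    return frame
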