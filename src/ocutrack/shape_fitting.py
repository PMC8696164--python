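"""Occlusion filtering and ellipse/circle parameterization of contour points.

The occlusion filter implements the 1-standard-deviation rule: compute the
mean point of the contour set, each point's Euclidean distance to that
mean, and the standard deviation of those distances; points whose distance
deviates from the mean distance by more than one SD are discarded.  The
deviation is two-sided by default (the only reading that keeps a clean
ellipse contour intact, since ellipse points are not equidistant from
their center); a one-sided variant that only discards far outliers is
available via ``mode="one_sided"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ContourPointSet, PupilModel
from .errors import FitError, InsufficientPointsError

__all__ = ["FilterReport", "filter_contour", "fit_ellipse", "fit_circle"]

MIN_POINTS_ELLIPSE = 5
MIN_POINTS_CIRCLE = 3

#: Discard cutoff in standard deviations of the point-to-mean distance
#: distribution.  Ties at exactly the cutoff are kept, so an equidistant
#: point set (SD = 0) is never trimmed.
SD_CUTOFF = 1.0


@dataclass(frozen=True)
class FilterReport:
    """Diagnostics of one occlusion-filter pass."""

    mean_point: tuple[float, float]
    distances: np.ndarray
    sd: float
    kept_mask: np.ndarray


def filter_contour(
    points: ContourPointSet, mode: str = "two_sided"
) -> tuple[ContourPointSet, FilterReport]:
    """Apply the 1-SD occlusion filter in a single pass.

    Returns a new point set with the ``kept`` flags assigned, plus a
    report.  Never discards when the distance SD is zero.
    """
    if mode not in ("two_sided", "one_sided"):
        raise ValueError("mode must be 'two_sided' or 'one_sided'")
    pts = points.points
    if len(pts) < MIN_POINTS_CIRCLE:
        raise InsufficientPointsError(f"occlusion filter needs >= 3 points, got {len(pts)}")
    mean_point = pts.mean(axis=0)
    d = np.hypot(pts[:, 0] - mean_point[0], pts[:, 1] - mean_point[1])
    sd = float(d.std())
    # Tolerance keeps exact ties (and the SD == 0 equidistant case) immune
    # to floating-point rounding of the distance computation.
    tol = 1e-9 * (1.0 + float(d.mean()))
    if mode == "two_sided":
        kept = np.abs(d - d.mean()) <= SD_CUTOFF * sd + tol
    else:
        kept = d - d.mean() <= SD_CUTOFF * sd + tol
    out = ContourPointSet(points=pts.copy(), ray_ids=points.ray_ids.copy(), kept=kept)
    report = FilterReport(
        mean_point=(float(mean_point[0]), float(mean_point[1])),
        distances=d,
        sd=sd,
        kept_mask=kept,
    )
    return out, report


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return pts


def fit_ellipse(points) -> PupilModel:
    """Direct least-squares conic fit constrained to an ellipse.

    Numerically stable formulation of the ellipse-specific constrained fit
    (the quadratic and linear parts of the scatter matrix are separated and
    only a 3x3 eigenproblem is solved).  Points are centered on their
    centroid first for conditioning.
    """
    pts = _as_points(points)
    if len(pts) < MIN_POINTS_ELLIPSE:
        raise InsufficientPointsError(f"ellipse fit needs >= 5 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    x = pts[:, 0] - centroid[0]
    y = pts[:, 1] - centroid[1]

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate point configuration") from exc
    M = S1 + S2 @ T
    # Apply the inverse ellipse-constraint matrix C = [[0,0,2],[0,-1,0],[2,0,0]].
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    # The ellipse solution is the eigenvector with 4AC - B^2 > 0.
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.flatnonzero(np.isreal(eigval) & (cond > 0))
    if len(ok) == 0:
        raise FitError("no elliptical solution for these points")
    a1 = np.real(eigvec[:, ok[0]])
    conic = np.concatenate([a1, T @ a1])  # A, B, C, D, E, F in centered coords
    model = _conic_to_model(conic)
    return PupilModel(
        cx=model.cx + centroid[0],
        cy=model.cy + centroid[1],
        a=model.a,
        b=model.b,
        theta=model.theta,
        shape="ellipse",
    )


def _conic_to_model(conic: np.ndarray) -> PupilModel:
    A, B, C, D, E, F = (float(v) for v in conic)
    disc = B * B - 4 * A * C
    if disc >= 0:
        raise FitError("fitted conic is not an ellipse")
    cx = (2 * C * D - B * E) / disc
    cy = (2 * A * E - B * D) / disc
    # Value of the quadratic form at the center sets the axis scale.
    F0 = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    Q = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(Q)
    scale = -F0
    if scale == 0 or np.any(lam * scale <= 0):
        raise FitError("degenerate ellipse (zero or imaginary axes)")
    axes = np.sqrt(scale / lam)
    order = np.argsort(axes)[::-1]  # conic sign is arbitrary; sort explicitly
    a, b = float(axes[order[0]]), float(axes[order[1]])
    major = vec[:, order[0]]
    theta = math.atan2(major[1], major[0]) % math.pi
    return PupilModel(cx=cx, cy=cy, a=a, b=b, theta=theta, shape="ellipse")


def fit_circle(points) -> PupilModel:
    """Algebraic least-squares circle (Kasa fit); returns a == b, theta = 0."""
    pts = _as_points(points)
    if len(pts) < MIN_POINTS_CIRCLE:
        raise InsufficientPointsError(f"circle fit needs >= 3 points, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or sv[-1] < 1e-9 * sv[0]:
        raise FitError("collinear points admit no circle fit")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise FitError("degenerate circle (nonpositive radius)")
    r = math.sqrt(r2)
    return PupilModel(cx=float(cx), cy=float(cy), a=r, b=r, theta=0.0, shape="circle")


def algebraic_residual(model: PupilModel, points) -> float:
    """Sum of squared algebraic residuals of points against a fitted model.

    Uses the normalized implicit ellipse equation
    ``((x')/a)^2 + ((y')/b)^2 - 1`` in the model's principal frame, so
    circle and ellipse fits are comparable on the same points.
    """
    pts = _as_points(points)
    ct, st = math.cos(model.theta), math.sin(model.theta)
    dx = pts[:, 0] - model.cx
    dy = pts[:, 1] - model.cy
    u = (dx * ct + dy * st) / model.a
    v = (-dx * st + dy * ct) / model.b
    return float(np.sum((u * u + v * v - 1.0) ** 2))
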