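"""Circle and box primitives for AP-radiograph measurements.

Everything downstream — edge refinement, RANSAC, wear computation — works on
circles expressed either in pixel coordinates (x rightward, y downward,
continuous sub-pixel centers) or in a resolution-independent normalized form
where the center is a fraction of the image width/height and the radius is a
fraction of the mean image dimension (W+H)/2.  The normalized form is what the
``cls x y r`` annotation files store.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Circle",
    "NormalizedCircle",
    "NormalizedBox",
    "ImageDims",
    "DegenerateGeometryError",
    "CLS_FEMORAL",
    "CLS_CUP",
    "normalize_circle",
    "denormalize_circle",
    "circle_to_normbox",
    "circle_from_three_points",
    "fit_circle_least_squares",
]

#: class ids used throughout: 0 = femoral head, 1 = acetabular cup
CLS_FEMORAL = 0
CLS_CUP = 1


class DegenerateGeometryError(ValueError):
    """Raised when points are collinear/coincident or a shape has no area."""


@dataclass(frozen=True)
class Circle:
    """Pixel-space circle: center (cx, cy) and radius, all in pixels."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cx) and math.isfinite(self.cy)):
            raise ValueError("circle center must be finite")
        if not (math.isfinite(self.r) and self.r >= 0):
            raise ValueError(f"radius must be finite and >= 0, got {self.r}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)


@dataclass(frozen=True)
class NormalizedCircle:
    """Resolution-independent circle annotation (``cls x y r``).

    ``x``/``y`` are fractions of image width/height; ``r`` is a fraction of
    the mean dimension (W+H)/2.  cls 0 = femoral head, 1 = acetabular cup.
    """

    cls: int
    x: float
    y: float
    r: float

    def __post_init__(self) -> None:
        if self.cls not in (CLS_FEMORAL, CLS_CUP):
            raise ValueError(f"cls must be 0 or 1, got {self.cls}")
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise ValueError(f"normalized center outside [0,1]: ({self.x}, {self.y})")
        if self.r < 0:
            raise ValueError(f"normalized radius must be >= 0, got {self.r}")


@dataclass(frozen=True)
class NormalizedBox:
    """Normalized box label (``cls x_center y_center width height``)."""

    cls: int
    x_box: float
    y_box: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_box <= 1.0 and 0.0 <= self.y_box <= 1.0):
            raise ValueError("normalized box center outside [0,1]")
        if self.w < 0 or self.h < 0:
            raise ValueError("box width/height must be >= 0")


@dataclass(frozen=True)
class ImageDims:
    """Integer image dimensions in pixels."""

    W: int
    H: int

    def __post_init__(self) -> None:
        if int(self.W) != self.W or int(self.H) != self.H:
            raise ValueError("dimensions must be integers")
        if self.W < 1 or self.H < 1:
            raise ValueError(f"dimensions must be >= 1, got {self.W}x{self.H}")

    @property
    def mean_dim(self) -> float:
        """(W+H)/2 — the radius-normalization denominator."""
        return (self.W + self.H) / 2.0


def normalize_circle(c: Circle, dims: ImageDims, cls: int) -> NormalizedCircle:
    """Convert a pixel circle to the normalized ``cls x y r`` form.

    x = cx/W, y = cy/H, r = r_px / ((W+H)/2).
    """
    return NormalizedCircle(
        cls=cls, x=c.cx / dims.W, y=c.cy / dims.H, r=c.r / dims.mean_dim
    )


def denormalize_circle(nc: NormalizedCircle, dims: ImageDims) -> Circle:
    """Inverse of :func:`normalize_circle` (exact up to float rounding)."""
    return Circle(cx=nc.x * dims.W, cy=nc.y * dims.H, r=nc.r * dims.mean_dim)


def circle_to_normbox(nc: NormalizedCircle, dims: ImageDims) -> NormalizedBox:
    """Normalized bounding box that exactly circumscribes the circle.

    In pixel space the box side is 2*r_px in both axes; in normalized units
    that becomes w = r(1 + H/W) and h = r(1 + W/H), with the center unchanged.
    """
    w = nc.r * (1.0 + dims.H / dims.W)
    h = nc.r * (1.0 + dims.W / dims.H)
    return NormalizedBox(cls=nc.cls, x_box=nc.x, y_box=nc.y, w=w, h=h)


def circle_from_three_points(
    p1: Sequence[float], p2: Sequence[float], p3: Sequence[float]
) -> Circle:
    """Circumscribed circle through three non-collinear points.

    Solves the perpendicular-bisector intersection in closed form.

    Raises
    ------
    DegenerateGeometryError
        If the points are (nearly) collinear or coincident.
    """
    (x1, y1), (x2, y2), (x3, y3) = (tuple(map(float, p)) for p in (p1, p2, p3))
    # 2 * signed triangle area
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    spread = max(
        (x1 - x2) ** 2 + (y1 - y2) ** 2,
        (x2 - x3) ** 2 + (y2 - y3) ** 2,
        (x3 - x1) ** 2 + (y3 - y1) ** 2,
    )
    if abs(d) <= 1e-9 * max(spread, 1e-300):
        raise DegenerateGeometryError("points are collinear or coincident")
    s1 = x1 * x1 + y1 * y1
    s2 = x2 * x2 + y2 * y2
    s3 = x3 * x3 + y3 * y3
    ux = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d
    uy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d
    r = math.hypot(x1 - ux, y1 - uy)
    return Circle(cx=ux, cy=uy, r=r)


def fit_circle_least_squares(points: Sequence[Sequence[float]]) -> Circle:
    """Algebraic (Kasa) least-squares circle fit.

    Minimizes sum((x-cx)^2 + (y-cy)^2 - r^2)^2, which is linear in
    (2cx, 2cy, r^2 - cx^2 - cy^2) and therefore closed-form.  Exact when the
    points lie on a circle; a good polish step on RANSAC inliers.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, or points (nearly) collinear.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x * x + y * y
    # rank deficiency <=> collinear points (the design matrix loses a column)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise DegenerateGeometryError("points are collinear; circle undetermined")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0 or not np.isfinite(r2):
        raise DegenerateGeometryError("degenerate least-squares circle")
    return Circle(cx=float(cx), cy=float(cy), r=float(math.sqrt(r2)))
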