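"""Medial, superior, and resultant 2D wear from PRE/POST circle pairs.

Polyethylene wear lets the prosthetic femoral head migrate inside the
acetabular cup.  On serial AP radiographs this shows up as (a) a change in
the head-to-cup center distance ("medial" component, d) and (b) a change in
the vertical gap between the superior points of the two circles ("superior"
component, g).  Because the physical head radius never changes, the ratio of
the femoral-head radii measured on the two films,

    sf = r_fem_PRE / r_fem_POST,

cancels any magnification difference between acquisitions: multiplying all
POST geometry by a constant leaves sf * d_POST and sf * g_POST unchanged.
The signed components and the resultant are

    delta_d = d_POST * sf - d_PRE
    delta_g = g_POST * sf - g_PRE
    delta_total = sqrt(delta_d^2 + delta_g^2)

all in PRE-image pixels; dividing by a known pixel-per-mm magnification M
converts to millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .geometry import Circle

__all__ = [
    "TimepointGeometry",
    "WearReport",
    "center_distance",
    "superior_gap",
    "wear_from_measurements",
    "compute_wear_report",
    "write_wear_report",
    "read_wear_report",
]


@dataclass(frozen=True)
class TimepointGeometry:
    """Femoral-head and cup circles measured on one radiograph."""

    femoral: Circle
    cup: Circle
    label: Literal["PRE", "POST"] = "PRE"

    def __post_init__(self) -> None:
        if not self.cup.r > self.femoral.r:
            raise ValueError(
                f"cup radius ({self.cup.r}) must exceed femoral radius "
                f"({self.femoral.r})"
            )


@dataclass(frozen=True)
class WearReport:
    """All quantities of the standardized per-patient wear report (pixels)."""

    r_fem_pre: float
    r_fem_post: float
    sf: float
    d_pre: float
    d_post: float
    d_post_scaled: float
    g_pre: float
    g_post: float
    g_post_scaled: float
    delta_d: float
    delta_g: float
    delta_total: float
    magnification: float | None = None
    wear_mm: float | None = None


def center_distance(t: TimepointGeometry) -> float:
    """Euclidean head-center to cup-center distance (pixels)."""
    return math.hypot(t.cup.cx - t.femoral.cx, t.cup.cy - t.femoral.cy)


def superior_gap(t: TimepointGeometry) -> float:
    """Vertical distance between the superior (top) points of the two circles.

    With y pointing down, the top of a circle is y_top = cy - r.  The gap is
    taken as an absolute value so the result does not depend on which circle
    tops out higher.
    """
    y_top_fem = t.femoral.cy - t.femoral.r
    y_top_cup = t.cup.cy - t.cup.r
    return abs(y_top_cup - y_top_fem)


def wear_from_measurements(
    r_fem_pre: float,
    r_fem_post: float,
    d_pre: float,
    d_post: float,
    g_pre: float,
    g_post: float,
    magnification: float | None = None,
) -> WearReport:
    """Wear report from scalar measurements (radii, center distances, gaps).

    This is the computational core; :func:`compute_wear_report` derives the
    scalars from circle pairs and delegates here.
    """
    if r_fem_post <= 0:
        raise ValueError("POST femoral radius must be positive")
    if r_fem_pre <= 0:
        raise ValueError("PRE femoral radius must be positive")
    sf = r_fem_pre / r_fem_post
    d_post_scaled = d_post * sf
    g_post_scaled = g_post * sf
    delta_d = d_post_scaled - d_pre
    delta_g = g_post_scaled - g_pre
    delta_total = math.hypot(delta_d, delta_g)
    wear_mm = None
    if magnification is not None:
        if magnification <= 0:
            raise ValueError("magnification must be positive")
        wear_mm = delta_total / magnification
    return WearReport(
        r_fem_pre=r_fem_pre,
        r_fem_post=r_fem_post,
        sf=sf,
        d_pre=d_pre,
        d_post=d_post,
        d_post_scaled=d_post_scaled,
        g_pre=g_pre,
        g_post=g_post,
        g_post_scaled=g_post_scaled,
        delta_d=delta_d,
        delta_g=delta_g,
        delta_total=delta_total,
        magnification=magnification,
        wear_mm=wear_mm,
    )


def compute_wear_report(
    pre: TimepointGeometry,
    post: TimepointGeometry,
    magnification: float | None = None,
) -> WearReport:
    """Full wear report for a PRE/POST pair of fitted circle geometries."""
    return wear_from_measurements(
        r_fem_pre=pre.femoral.r,
        r_fem_post=post.femoral.r,
        d_pre=center_distance(pre),
        d_post=center_distance(post),
        g_pre=superior_gap(pre),
        g_post=superior_gap(post),
        magnification=magnification,
    )


_FIELD_ORDER = (
    "r_fem_pre",
    "r_fem_post",
    "sf",
    "d_pre",
    "d_post",
    "d_post_scaled",
    "g_pre",
    "g_post",
    "g_post_scaled",
    "delta_d",
    "delta_g",
    "delta_total",
    "magnification",
    "wear_mm",
)


def write_wear_report(report: WearReport, path: str | Path) -> None:
    """Write the labeled key-value text report (6-decimal fixed point).

    Lines for magnification / wear_mm are present only when a magnification
    factor was supplied.  :func:`read_wear_report` round-trips the file.
    """
    lines = []
    for name in _FIELD_ORDER:
        value = getattr(report, name)
        if value is None:
            continue
        lines.append(f"{name} {value:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_wear_report(path: str | Path) -> WearReport:
    """Parse a report written by :func:`write_wear_report`."""
    values: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 2 or fields[0] not in _FIELD_ORDER:
            raise ValueError(f"{path}:{lineno}: malformed report line")
        values[fields[0]] = float(fields[1])
    return WearReport(
        **{name: values.get(name) for name in _FIELD_ORDER}  # type: ignore[arg-type]
    )
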