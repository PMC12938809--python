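"""Hybrid circle refinement: Edge-Snap, RANSAC, Hough fallback, cup search.

Given a coarse ROI-derived circle proposal, the femoral head is refined by
(1) Edge-Snap — radial profiles of the combined edge signal are sampled over
many angles inside a narrow annulus and the per-angle peak radii are pooled
by a response-weighted median — and (2) RANSAC over high-response edge points
harvested in a thin ring around the snapped radius, polished by a
least-squares fit.

The acetabular cup rim is often partially occluded, so it gets a candidate
search instead: a deterministic grid of center shifts and radius scales
around the proposal, each candidate snapped (and optionally RANSAC-refined),
then scored by a six-component composite (edge support, angular coverage,
longest supported arc, gradient/normal alignment, center proximity to the
ROI, fraction of support outside the femoral circle) and screened by
anatomical constraints: cup radius strictly larger than the head radius, a
positive joint-space gap, cup center inside the ROI, and minimum Canny edge
density along both rims.  When every candidate scores poorly, a circular
Hough transform with gradient-direction voting is run over the same region
and its candidates are scored and screened identically, replacing the
incumbent only if strictly better.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import (
    Circle,
    DegenerateGeometryError,
    circle_from_three_points,
    fit_circle_least_squares,
)
from .preprocess import EdgeMap, EnhanceConfig, build_edge_map
from .roi import RoiBox, box_to_circle_proposal, crop_roi

__all__ = [
    "EdgeSnapConfig",
    "RansacConfig",
    "CupSearchConfig",
    "RefineConfig",
    "CandidateScore",
    "ProsthesisFit",
    "InsufficientDataError",
    "NoValidFitError",
    "edge_snap",
    "harvest_ring_points",
    "ransac_circle",
    "hough_circles",
    "generate_cup_candidates",
    "score_cup_candidate",
    "anatomical_filter",
    "fit_prosthesis",
]


class InsufficientDataError(ValueError):
    """Fewer points than a circle fit requires."""


class NoValidFitError(RuntimeError):
    """No candidate passed the anatomical filter; carries diagnostics."""

    def __init__(self, message: str, diagnostics: list[str] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class OutOfBoundsError(ValueError):
    """Circle (with its search annulus) lies fully outside the edge map."""


@dataclass(frozen=True)
class EdgeSnapConfig:
    n_angles: int = 360
    annulus_frac: float = 0.2     # half-width of the radial band, rel. to r
    min_support_frac: float = 0.1
    noise_floor: float = 0.2      # combined-response level counted as signal
    r_step: float = 0.5           # radial sampling step, px

    def __post_init__(self) -> None:
        if self.n_angles < 8:
            raise ValueError("n_angles must be >= 8")
        if not 0.0 < self.annulus_frac < 1.0:
            raise ValueError("annulus_frac must be in (0, 1)")


@dataclass(frozen=True)
class RansacConfig:
    n_iter: int = 500
    inlier_tol: float = 2.0       # px distance-to-circle for inliers
    ring_frac: float = 0.15       # harvest ring half-width, rel. to r
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.inlier_tol <= 0:
            raise ValueError("inlier_tol must be > 0")


@dataclass(frozen=True)
class CupSearchConfig:
    n_shifts: int = 3             # center-offset grid points per axis
    shift_frac: float = 0.08      # max |offset| rel. to proposal radius
    scale_range: tuple[float, float] = (0.9, 1.15)
    n_scales: int = 5
    snap_annulus_frac: float = 0.1
    use_ransac: bool = True       # RANSAC polish after per-candidate snap
    score_weights: tuple[float, ...] = (1.0,) * 6
    support_threshold: float = 0.25   # response counted as a supporting point
    fallback_threshold: float = 0.35  # best total below this triggers Hough
    min_coverage: float = 0.5         # angular coverage below this also triggers


@dataclass(frozen=True)
class RefineConfig:
    """Everything :func:`fit_prosthesis` needs, with pipeline defaults."""

    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    canny_sigma: float = 0.33
    edge_weights: tuple[float, float] = (0.5, 0.5)
    margin_frac: float = 0.15
    edge_snap: EdgeSnapConfig = field(default_factory=EdgeSnapConfig)
    ransac: RansacConfig = field(default_factory=RansacConfig)
    cup: CupSearchConfig = field(default_factory=CupSearchConfig)
    min_gap: float = 1.0          # px joint-space gap (liner thickness floor)
    min_edge_density: float = 0.02
    hough_r_step: float = 1.0
    hough_n_peaks: int = 5
    hough_vote_floor: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class CandidateScore:
    """Composite cup-quality score and its six components."""

    edge_support: float
    angular_coverage: float
    longest_arc: float            # radians, [0, 2*pi]
    gradient_alignment: float
    center_proximity: float
    outside_fraction: float
    total: float


@dataclass(frozen=True)
class ProsthesisFit:
    femoral: Circle
    cup: Circle
    femoral_score: CandidateScore
    cup_score: CandidateScore
    method: str                   # "ransac" | "hough_fallback"
    diagnostics: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# sampling helpers


def _sample(em_field: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bilinear sample of a field at continuous (x, y); outside -> 0."""
    return map_coordinates(
        em_field, np.vstack([ys.ravel(), xs.ravel()]), order=1, mode="constant"
    ).reshape(xs.shape)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median; ties resolve to the lower value."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    total = w.sum()
    if total <= 0:
        return float(np.median(values))
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(v[min(idx, len(v) - 1)])


def edge_snap(
    em: EdgeMap, c0: Circle, cfg: EdgeSnapConfig | None = None
) -> tuple[Circle, float]:
    """Radial Edge-Snap: re-align the radius to the locus of peak edge response.

    The center is left unchanged (center refinement is RANSAC's job).  Per
    angle, the combined response is sampled along radii in the annulus
    ``[r0*(1-annulus_frac), r0*(1+annulus_frac)]``; the argmax radii are
    pooled by a response-weighted median.  ``support`` is the fraction of
    angles whose peak response exceeds the noise floor; below
    ``min_support_frac`` the input radius is kept.
    """
    cfg = cfg or EdgeSnapConfig()
    H, W = em.shape
    r_lo = max(1.0, c0.r * (1.0 - cfg.annulus_frac))
    r_hi = c0.r * (1.0 + cfg.annulus_frac)
    if (
        c0.cx + r_hi < 0
        or c0.cy + r_hi < 0
        or c0.cx - r_hi > W - 1
        or c0.cy - r_hi > H - 1
    ):
        raise OutOfBoundsError("circle annulus lies outside the edge map")
    if r_hi <= r_lo:
        return c0, 0.0
    radii = np.arange(r_lo, r_hi + cfg.r_step / 2, cfg.r_step)
    angles = np.linspace(0.0, 2.0 * np.pi, cfg.n_angles, endpoint=False)
    xs = c0.cx + radii[None, :] * np.cos(angles)[:, None]
    ys = c0.cy + radii[None, :] * np.sin(angles)[:, None]
    resp = _sample(em.combined, xs, ys)          # (n_angles, n_radii)
    peak_idx = np.argmax(resp, axis=1)
    peak_val = resp[np.arange(len(angles)), peak_idx]
    support = float(np.mean(peak_val > cfg.noise_floor))
    if support < cfg.min_support_frac:
        return c0, support
    r_new = _weighted_median(radii[peak_idx], peak_val)
    return Circle(cx=c0.cx, cy=c0.cy, r=r_new), support


def harvest_ring_points(
    em: EdgeMap,
    c: Circle,
    ring_frac: float = 0.15,
    response_quantile: float = 0.7,
) -> np.ndarray:
    """High-response pixels in a thin ring around ``c`` as (x, y) points.

    Pixels whose radial distance from the center deviates from the radius by
    at most ``ring_frac * r`` and whose combined response is at or above the
    given quantile of the positive responses inside that ring.  May be empty.
    """
    H, W = em.shape
    yy, xx = np.mgrid[0:H, 0:W]
    dist = np.hypot(xx - c.cx, yy - c.cy)
    in_ring = np.abs(dist - c.r) <= ring_frac * c.r
    resp = em.combined[in_ring]
    positive = resp[resp > 0]
    if positive.size == 0:
        return np.empty((0, 2))
    thresh = float(np.quantile(positive, response_quantile))
    keep = in_ring & (em.combined >= thresh) & (em.combined > 0)
    pts = np.column_stack([xx[keep], yy[keep]]).astype(float)
    return pts


def ransac_circle(
    points: Sequence[Sequence[float]] | np.ndarray,
    cfg: RansacConfig | None = None,
) -> tuple[Circle, int, float]:
    """RANSAC circle fit from random (or exhaustive) point triplets.

    Inliers of a hypothesis are points with |distance-to-center - r| <=
    ``inlier_tol``.  The best hypothesis (most inliers; ties broken by lower
    mean inlier residual) is polished by a least-squares fit on its inliers.
    When the number of triplets C(n,3) does not exceed ``n_iter``, all
    triplets are enumerated deterministically; otherwise ``n_iter`` random
    triplets are drawn from the seeded generator.
    """
    cfg = cfg or RansacConfig()
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise InsufficientDataError("RANSAC needs at least 3 points")
    n = pts.shape[0]
    n_triplets = n * (n - 1) * (n - 2) // 6
    if n_triplets <= cfg.n_iter:
        triplets = itertools.combinations(range(n), 3)
    else:
        rng = np.random.default_rng(cfg.seed)
        triplets = (
            tuple(rng.choice(n, size=3, replace=False)) for _ in range(cfg.n_iter)
        )

    best: tuple[int, float, Circle, np.ndarray] | None = None
    any_valid = False
    for i, j, k in triplets:
        try:
            hyp = circle_from_three_points(pts[i], pts[j], pts[k])
        except DegenerateGeometryError:
            continue
        any_valid = True
        resid = np.abs(np.hypot(pts[:, 0] - hyp.cx, pts[:, 1] - hyp.cy) - hyp.r)
        mask = resid <= cfg.inlier_tol
        count = int(mask.sum())
        mean_resid = float(resid[mask].mean()) if count else math.inf
        if best is None or count > best[0] or (count == best[0] and mean_resid < best[1]):
            best = (count, mean_resid, hyp, mask)
    if not any_valid or best is None:
        raise DegenerateGeometryError("all sampled triplets were degenerate")
    count, _, hyp, mask = best
    try:
        final = fit_circle_least_squares(pts[mask]) if count >= 3 else hyp
    except DegenerateGeometryError:
        final = hyp
    return final, count, count / n


def hough_circles(
    em: EdgeMap,
    r_min: float,
    r_max: float,
    r_step: float = 1.0,
    n_peaks: int = 5,
    vote_floor: float = 0.05,
    nms_center: int = 5,
    nms_radius_bins: int = 2,
    vote_mask: np.ndarray | None = None,
) -> list[tuple[Circle, float]]:
    """Circular Hough transform with gradient-direction voting.

    Every pixel whose combined response exceeds ``vote_floor`` casts two
    votes per radius bin, at the two candidate centers along its gradient
    direction (the rim center lies along the normal).  Votes are weighted by
    the combined response.  Peaks are extracted by greedy non-maximum
    suppression over a spatial window and a radius-bin window, and returned
    sorted by accumulator score descending.  ``vote_mask`` optionally limits
    which pixels may vote (True = allowed).
    """
    if not r_min < r_max:
        raise ValueError("require r_min < r_max")
    H, W = em.shape
    radii = np.arange(float(r_min), float(r_max) + r_step / 2, r_step)
    allowed = em.combined > vote_floor
    if vote_mask is not None:
        allowed &= vote_mask
    ys, xs = np.nonzero(allowed)
    if len(xs) == 0:
        return []
    w = em.combined[ys, xs]
    theta = em.grad_dir[ys, xs]
    acc = np.zeros((len(radii), H, W))
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    for ri, r in enumerate(radii):
        for sign in (1.0, -1.0):
            cx = np.rint(xs + sign * r * cos_t).astype(int)
            cy = np.rint(ys + sign * r * sin_t).astype(int)
            ok = (cx >= 0) & (cx < W) & (cy >= 0) & (cy < H)
            np.add.at(acc[ri], (cy[ok], cx[ok]), w[ok])

    peaks: list[tuple[Circle, float]] = []
    acc_work = acc.copy()
    for _ in range(n_peaks):
        idx = np.unravel_index(np.argmax(acc_work), acc_work.shape)
        score = float(acc_work[idx])
        if score <= 0:
            break
        ri, cy, cx = (int(v) for v in idx)
        peaks.append((Circle(cx=float(cx), cy=float(cy), r=float(radii[ri])), score))
        r0, r1 = max(0, ri - nms_radius_bins), ri + nms_radius_bins + 1
        y0, y1 = max(0, cy - nms_center), cy + nms_center + 1
        x0, x1 = max(0, cx - nms_center), cx + nms_center + 1
        acc_work[r0:r1, y0:y1, x0:x1] = 0.0
    return peaks


def generate_cup_candidates(
    c0: Circle,
    n_shifts: int = 3,
    shift_frac: float = 0.08,
    scale_range: tuple[float, float] = (0.9, 1.15),
    n_scales: int = 5,
) -> list[Circle]:
    """Deterministic grid of center shifts x radius scales around ``c0``.

    Center offsets span ``[-shift_frac*r, +shift_frac*r]`` per axis with
    ``n_shifts`` points; radii span ``scale_range`` with ``n_scales`` points
    (a single scale collapses to 1.0).  ``c0`` itself is always included.
    """
    lo, hi = scale_range
    if not (0 < lo < hi) and n_scales > 1:
        raise ValueError("scale_range must satisfy 0 < low < high")
    offsets = (
        np.array([0.0])
        if n_shifts == 1
        else np.linspace(-shift_frac * c0.r, shift_frac * c0.r, n_shifts)
    )
    scales = np.array([1.0]) if n_scales == 1 else np.linspace(lo, hi, n_scales)
    candidates = [
        Circle(cx=c0.cx + dx, cy=c0.cy + dy, r=c0.r * s)
        for dx in offsets
        for dy in offsets
        for s in scales
    ]
    if not any(c == c0 for c in candidates):
        candidates.insert(0, c0)
    return candidates


def _ring_samples(
    em: EdgeMap, cand: Circle, n_angles: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-angle peak response within +-tol of the radius.

    Returns (angles, peak response, peak radius, grad_dir at peak).
    """
    angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    radii = np.linspace(max(1.0, cand.r - tol), cand.r + tol, 7)
    xs = cand.cx + radii[None, :] * np.cos(angles)[:, None]
    ys = cand.cy + radii[None, :] * np.sin(angles)[:, None]
    resp = _sample(em.combined, xs, ys)
    peak_idx = np.argmax(resp, axis=1)
    rows = np.arange(n_angles)
    peak_resp = resp[rows, peak_idx]
    peak_r = radii[peak_idx]
    gdir = _sample(em.grad_dir, xs[rows, peak_idx], ys[rows, peak_idx])
    return angles, peak_resp, peak_r, gdir


def _longest_true_run_circular(mask: np.ndarray) -> int:
    if mask.all():
        return len(mask)
    if not mask.any():
        return 0
    # rotate so the sequence starts at a False, then count runs linearly
    first_false = int(np.argmin(mask))
    rolled = np.roll(mask, -first_false)
    best = run = 0
    for m in rolled:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def score_cup_candidate(
    cand: Circle,
    em: EdgeMap,
    femoral: Circle | None,
    roi_center: tuple[float, float],
    weights: Sequence[float] = (1.0,) * 6,
    n_angles: int = 360,
    support_threshold: float = 0.25,
) -> CandidateScore:
    """Six-component composite quality score of a circle candidate.

    Components (all in [0, 1]; longest arc reported in radians and
    normalized by 2*pi inside the composite):

    - edge_support: of the high-response pixels in a surrounding annulus,
      the fraction radially within a narrow tolerance of the candidate radius;
    - angular_coverage: fraction of angular bins whose peak response along
      the ring exceeds the support threshold;
    - longest_arc: longest contiguous supported arc;
    - gradient_alignment: mean |cos| between local gradient direction and the
      radial direction over supported bins (polarity-insensitive);
    - center_proximity: 1 - d/(r/2) clamped to [0,1], d = distance from the
      candidate center to the ROI center;
    - outside_fraction: fraction of supporting peak points outside the
      femoral circle (1.0 when no femoral circle is given).
    """
    w = np.asarray(weights, dtype=float)
    if w.min() < 0 or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    tol = max(2.0, 0.03 * cand.r)

    angles, peak_resp, peak_r, gdir = _ring_samples(em, cand, n_angles, tol)
    supported = peak_resp >= support_threshold
    angular_coverage = float(np.mean(supported))
    bin_width = 2.0 * np.pi / n_angles
    longest_arc = _longest_true_run_circular(supported) * bin_width

    if supported.any():
        align = np.abs(np.cos(gdir[supported] - angles[supported]))
        gradient_alignment = float(np.mean(align))
        px = cand.cx + peak_r[supported] * np.cos(angles[supported])
        py = cand.cy + peak_r[supported] * np.sin(angles[supported])
        if femoral is None:
            outside_fraction = 1.0
        else:
            d_fem = np.hypot(px - femoral.cx, py - femoral.cy)
            outside_fraction = float(np.mean(d_fem > femoral.r))
    else:
        gradient_alignment = 0.0
        outside_fraction = 0.0

    # pixel-based radial support: high-response pixels in a wider annulus
    H, W = em.shape
    band = 3.0 * tol
    y0 = max(0, int(cand.cy - cand.r - band))
    y1 = min(H, int(cand.cy + cand.r + band) + 1)
    x0 = max(0, int(cand.cx - cand.r - band))
    x1 = min(W, int(cand.cx + cand.r + band) + 1)
    edge_support = 0.0
    if y1 > y0 and x1 > x0:
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - cand.cx, yy - cand.cy)
        near = np.abs(dist - cand.r) <= band
        strong = near & (em.combined[y0:y1, x0:x1] >= support_threshold)
        n_strong = int(strong.sum())
        if n_strong:
            within = strong & (np.abs(dist - cand.r) <= tol)
            edge_support = float(within.sum() / n_strong)

    d_roi = math.hypot(cand.cx - roi_center[0], cand.cy - roi_center[1])
    center_proximity = float(np.clip(1.0 - d_roi / (0.5 * max(cand.r, 1.0)), 0.0, 1.0))

    components = np.array(
        [
            edge_support,
            angular_coverage,
            longest_arc / (2.0 * np.pi),
            gradient_alignment,
            center_proximity,
            outside_fraction,
        ]
    )
    total = float(np.dot(w / w.sum(), components))
    return CandidateScore(
        edge_support=edge_support,
        angular_coverage=angular_coverage,
        longest_arc=longest_arc,
        gradient_alignment=gradient_alignment,
        center_proximity=center_proximity,
        outside_fraction=outside_fraction,
        total=total,
    )


def _ring_edge_density(
    em: EdgeMap, c: Circle, band: float = 2.0, response_floor: float = 0.1
) -> float:
    """Fraction of ring-band pixels carrying edge evidence.

    A pixel counts when Canny fired there or its combined response clears
    ``response_floor`` — so a rim whose contrast falls just below the Canny
    hysteresis floor but still produces coherent gradients is not scored as
    empty (that regime is exactly where the Hough fallback must operate).
    """
    H, W = em.shape
    y0 = max(0, int(c.cy - c.r - band))
    y1 = min(H, int(c.cy + c.r + band) + 1)
    x0 = max(0, int(c.cx - c.r - band))
    x1 = min(W, int(c.cx + c.r + band) + 1)
    if y1 <= y0 or x1 <= x0:
        return 0.0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - c.cx, yy - c.cy)
    in_band = np.abs(dist - c.r) <= band
    n = int(in_band.sum())
    if n == 0:
        return 0.0
    evidence = em.edges[y0:y1, x0:x1] | (em.combined[y0:y1, x0:x1] >= response_floor)
    return float(evidence[in_band].sum() / n)


def anatomical_filter(
    femoral: Circle,
    cup: Circle,
    em: EdgeMap,
    min_gap: float = 1.0,
    min_edge_density: float = 0.02,
    roi: RoiBox | None = None,
) -> tuple[bool, list[str]]:
    """Anatomical plausibility screen for a head/cup circle pair.

    Pass requires all of: cup radius strictly larger than head radius; the
    head strictly inside the cup with at least ``min_gap`` pixels of
    joint-space clearance; cup center inside the ROI (when given); Canny edge
    density along each rim band at least ``min_edge_density``.  ``reasons``
    lists every violated rule.
    """
    reasons: list[str] = []
    if not cup.r > femoral.r:
        reasons.append("radius ordering: cup radius must exceed femoral radius")
    center_dist = math.hypot(cup.cx - femoral.cx, cup.cy - femoral.cy)
    if cup.r - femoral.r - center_dist < min_gap:
        reasons.append("joint-space gap: head not inside cup with minimum gap")
    if roi is not None and not (
        roi.x0 <= cup.cx <= roi.x1 and roi.y0 <= cup.cy <= roi.y1
    ):
        reasons.append("cup center outside ROI")
    for name, circ in (("femoral", femoral), ("cup", cup)):
        if _ring_edge_density(em, circ) < min_edge_density:
            reasons.append(f"edge density below minimum ({name})")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# orchestrator


def _shift(c: Circle, dx: float, dy: float) -> Circle:
    return Circle(cx=c.cx + dx, cy=c.cy + dy, r=c.r)


def _split_rois(rois: Sequence[RoiBox]) -> tuple[Circle, Circle, RoiBox]:
    """Initial femoral/cup proposals + the enclosing working ROI."""
    fem_boxes = [b for b in rois if b.cls == 0]
    cup_boxes = [b for b in rois if b.cls == 1]
    if fem_boxes and cup_boxes:
        fb = max(fem_boxes, key=lambda b: b.confidence)
        cb = max(cup_boxes, key=lambda b: b.confidence)
        fem0 = box_to_circle_proposal(fb)
        cup0 = box_to_circle_proposal(cb)
        work = RoiBox(
            x0=min(fb.x0, cb.x0),
            y0=min(fb.y0, cb.y0),
            x1=max(fb.x1, cb.x1),
            y1=max(fb.y1, cb.y1),
            confidence=min(fb.confidence, cb.confidence),
            cls=1,
        )
        return fem0, cup0, work
    # single implant-level ROI: the cup spans the box, the head sits inside
    box = max(rois, key=lambda b: b.confidence)
    cup0 = box_to_circle_proposal(box)
    fem0 = Circle(cx=cup0.cx, cy=cup0.cy, r=0.6 * cup0.r)
    return fem0, cup0, box


def fit_prosthesis(
    image: np.ndarray,
    rois: Sequence[RoiBox],
    config: RefineConfig | None = None,
) -> ProsthesisFit:
    """End-to-end circle refinement inside detector-provided ROIs.

    Femoral head: Edge-Snap, then RANSAC on harvested ring points.  Cup:
    candidate grid, per-candidate Edge-Snap (+ optional RANSAC), composite
    scoring, anatomical filtering, argmax; Hough fallback when the best
    composite score is below the fallback threshold.  Raises
    :class:`NoValidFitError` when nothing passes the anatomical filter.
    """
    config = config or RefineConfig()
    if not rois:
        raise ValueError("at least one ROI is required")
    diagnostics: list[str] = []
    fem0, cup0, work_box = _split_rois(rois)

    crop, (ox, oy) = crop_roi(image, work_box, config.margin_frac)
    em = build_edge_map(
        crop, config.enhance, canny_sigma=config.canny_sigma,
        weights=config.edge_weights,
    )
    fem_local = _shift(fem0, -ox, -oy)
    cup_local = _shift(cup0, -ox, -oy)
    roi_center_local = (
        work_box.center[0] - ox,
        work_box.center[1] - oy,
    )
    cup_roi_local = RoiBox(
        x0=work_box.x0 - ox, y0=work_box.y0 - oy,
        x1=work_box.x1 - ox, y1=work_box.y1 - oy,
        confidence=work_box.confidence, cls=work_box.cls,
    )

    # --- femoral head: edge-snap, harvest, RANSAC
    fem_snap, fem_support = edge_snap(em, fem_local, config.edge_snap)
    diagnostics.append(f"femoral edge-snap support={fem_support:.3f}")
    fem_pts = harvest_ring_points(em, fem_snap, config.ransac.ring_frac)
    femoral = fem_snap
    if len(fem_pts) >= 3:
        try:
            femoral, n_in, frac_in = ransac_circle(fem_pts, config.ransac)
            diagnostics.append(
                f"femoral RANSAC inliers={n_in}/{len(fem_pts)} ({frac_in:.2f})"
            )
        except DegenerateGeometryError:
            diagnostics.append("femoral RANSAC degenerate; kept snapped circle")
    else:
        diagnostics.append("femoral ring harvest too sparse; kept snapped circle")

    fem_score = score_cup_candidate(
        femoral, em, None, roi_center_local,
        weights=config.cup.score_weights,
        support_threshold=config.cup.support_threshold,
    )

    # --- cup: candidate grid -> snap (+ransac) -> score -> filter
    cup_cfg = config.cup
    snap_cfg = replace(config.edge_snap, annulus_frac=cup_cfg.snap_annulus_frac)
    candidates = generate_cup_candidates(
        cup_local, cup_cfg.n_shifts, cup_cfg.shift_frac,
        cup_cfg.scale_range, cup_cfg.n_scales,
    )
    refined: dict[tuple[float, float, float], Circle] = {}
    for cand in candidates:
        try:
            snapped, _ = edge_snap(em, cand, snap_cfg)
        except OutOfBoundsError:
            continue
        circ = snapped
        if cup_cfg.use_ransac:
            pts = harvest_ring_points(em, snapped, ring_frac=0.08)
            if len(pts) >= 3:
                try:
                    circ, _, _ = ransac_circle(pts, config.ransac)
                except DegenerateGeometryError:
                    pass
        key = (round(circ.cx * 2) / 2, round(circ.cy * 2) / 2, round(circ.r * 2) / 2)
        refined.setdefault(key, circ)

    def evaluate(circ: Circle) -> tuple[CandidateScore, bool, list[str]]:
        score = score_cup_candidate(
            circ, em, femoral, roi_center_local,
            weights=cup_cfg.score_weights,
            support_threshold=cup_cfg.support_threshold,
        )
        ok, reasons = anatomical_filter(
            femoral, circ, em, config.min_gap, config.min_edge_density,
            roi=cup_roi_local,
        )
        return score, ok, reasons

    best_cup: Circle | None = None
    best_score: CandidateScore | None = None
    for circ in refined.values():
        score, ok, _ = evaluate(circ)
        if ok and (best_score is None or score.total > best_score.total):
            best_cup, best_score = circ, score
    diagnostics.append(
        f"cup grid: {len(refined)} refined candidates, best total="
        + (f"{best_score.total:.3f}" if best_score else "none passed filter")
    )

    # --- Hough fallback: low composite score or weak angular coverage both
    # signal insufficient edge support for the grid's winner
    method = "ransac"
    if (
        best_score is None
        or best_score.total < cup_cfg.fallback_threshold
        or best_score.angular_coverage < cup_cfg.min_coverage
    ):
        diagnostics.append("fallback triggered: weak composite/coverage")
        # the cup rim must lie outside the fitted femoral circle, so exclude
        # the (strong) femoral edge from both the radius range and the votes
        # wider radius range than the candidate grid: a triggered fallback
        # means the ROI-derived radius itself is suspect
        r_lo = max(0.6 * cup_local.r, femoral.r + config.min_gap + 1.0)
        r_hi = max(1.35 * cup_local.r, r_lo + 3.0 * config.hough_r_step)
        yy, xx = np.mgrid[0 : em.shape[0], 0 : em.shape[1]]
        outside_head = (
            np.hypot(xx - femoral.cx, yy - femoral.cy)
            > femoral.r + config.min_gap
        )
        for hough_c, hough_score in hough_circles(
            em, r_lo, r_hi, config.hough_r_step, config.hough_n_peaks,
            vote_floor=config.hough_vote_floor, vote_mask=outside_head,
        ):
            try:
                snapped, _ = edge_snap(em, hough_c, snap_cfg)
            except OutOfBoundsError:
                continue
            score, ok, _ = evaluate(snapped)
            if ok and (best_score is None or score.total > best_score.total):
                best_cup, best_score = snapped, score
                method = "hough_fallback"
                diagnostics.append(
                    f"hough candidate adopted (votes={hough_score:.1f}, "
                    f"total={score.total:.3f})"
                )

    if best_cup is None or best_score is None:
        raise NoValidFitError(
            "no cup candidate passed the anatomical filter", diagnostics
        )
    if best_score.angular_coverage < cup_cfg.min_coverage:
        diagnostics.append(
            f"best candidate coverage {best_score.angular_coverage:.3f} "
            f"< {cup_cfg.min_coverage}"
        )
        raise NoValidFitError(
            "no candidate with sufficient angular edge coverage", diagnostics
        )

    return ProsthesisFit(
        femoral=_shift(femoral, ox, oy),
        cup=_shift(best_cup, ox, oy),
        femoral_score=fem_score,
        cup_score=best_score,
        method=method,
        diagnostics=tuple(diagnostics),
    )
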