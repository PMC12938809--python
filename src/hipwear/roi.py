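"""ROI acquisition and box-to-circle plumbing.

The detector that localizes the implant is pluggable: anything implementing
:class:`RoiProvider` can supply boxes.  Two providers ship here — a text-file
ingester for externally produced detections ("cls conf x y w h", normalized)
and :class:`OracleRoiProvider`, which jitters ground-truth circumscribing
boxes and stands in for a detector in tests and phantom studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .geometry import (
    Circle,
    ImageDims,
    NormalizedCircle,
    circle_to_normbox,
    denormalize_circle,
)

__all__ = [
    "RoiBox",
    "RoiProvider",
    "OracleRoiProvider",
    "box_to_circle_proposal",
    "crop_roi",
    "oracle_roi_provider",
    "read_detector_boxes",
    "normbox_to_roibox",
]


class OutOfBoundsError(ValueError):
    """Raised when a box lies fully outside the image."""


@dataclass(frozen=True)
class RoiBox:
    """Half-open pixel box [x0, x1) x [y0, y1) with a detector confidence."""

    x0: float
    y0: float
    x1: float
    y1: float
    confidence: float = 1.0
    cls: int = 0

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("box must have positive extent")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height


class RoiProvider(Protocol):
    """Source of ROI boxes for an image (detector adapter contract)."""

    def provide(self, image: np.ndarray) -> list[RoiBox]: ...


def box_to_circle_proposal(box: RoiBox) -> Circle:
    """Initial circle proposal from a detection box.

    Center = box center; radius = the average of the half-width and
    half-height, so the circumscribing box of a circle maps back to that
    circle exactly.
    """
    cx, cy = box.center
    r = (box.width + box.height) / 4.0
    if r <= 0:
        raise ValueError("degenerate box")
    return Circle(cx=cx, cy=cy, r=r)


def crop_roi(
    image: np.ndarray, box: RoiBox, margin_frac: float = 0.15
) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop ``box`` expanded by ``margin_frac`` per side, clipped to the image.

    Returns ``(subimage, (ox, oy))`` where adding the offset to subimage
    coordinates recovers full-image coordinates exactly.
    """
    if margin_frac < 0:
        raise ValueError("margin_frac must be >= 0")
    H, W = image.shape[:2]
    mx = margin_frac * box.width
    my = margin_frac * box.height
    x0 = int(np.floor(box.x0 - mx))
    y0 = int(np.floor(box.y0 - my))
    x1 = int(np.ceil(box.x1 + mx))
    y1 = int(np.ceil(box.y1 + my))
    x0c, y0c = max(0, x0), max(0, y0)
    x1c, y1c = min(W, x1), min(H, y1)
    if x0c >= x1c or y0c >= y1c:
        raise OutOfBoundsError("ROI box lies outside the image")
    return image[y0c:y1c, x0c:x1c], (x0c, y0c)


def oracle_roi_provider(
    truth: Sequence[NormalizedCircle],
    dims: ImageDims,
    jitter: float = 0.0,
    seed: int = 0,
) -> list[RoiBox]:
    """Ground-truth-derived boxes with uniform relative jitter.

    Each truth circle is converted to its exact circumscribing box; the box
    center is then perturbed by U(-jitter, jitter) times the box extent and
    the size by a factor 1 + U(-jitter, jitter).  jitter=0 reproduces the
    exact boxes; a fixed seed reproduces the draw.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    boxes: list[RoiBox] = []
    for nc in truth:
        c = denormalize_circle(nc, dims)
        nb = circle_to_normbox(nc, dims)
        w_px = nb.w * dims.W
        h_px = nb.h * dims.H
        dx = rng.uniform(-jitter, jitter) * w_px
        dy = rng.uniform(-jitter, jitter) * h_px
        sw = 1.0 + rng.uniform(-jitter, jitter)
        sh = 1.0 + rng.uniform(-jitter, jitter)
        cx, cy = c.cx + dx, c.cy + dy
        hw, hh = w_px * sw / 2.0, h_px * sh / 2.0
        x0 = max(0.0, cx - hw)
        y0 = max(0.0, cy - hh)
        x1 = min(float(dims.W), cx + hw)
        y1 = min(float(dims.H), cy + hh)
        boxes.append(RoiBox(x0=x0, y0=y0, x1=x1, y1=y1, confidence=1.0, cls=nc.cls))
    return boxes


@dataclass(frozen=True)
class OracleRoiProvider:
    """RoiProvider wrapper around :func:`oracle_roi_provider`."""

    truth: tuple[NormalizedCircle, ...]
    dims: ImageDims
    jitter: float = 0.0
    seed: int = 0

    def provide(self, image: np.ndarray) -> list[RoiBox]:
        return oracle_roi_provider(self.truth, self.dims, self.jitter, self.seed)


def normbox_to_roibox(
    cls: int, conf: float, x: float, y: float, w: float, h: float, dims: ImageDims
) -> RoiBox:
    """Pixel-space box from a normalized detector record, clipped to the image."""
    cx, cy = x * dims.W, y * dims.H
    hw, hh = w * dims.W / 2.0, h * dims.H / 2.0
    return RoiBox(
        x0=max(0.0, cx - hw),
        y0=max(0.0, cy - hh),
        x1=min(float(dims.W), cx + hw),
        y1=min(float(dims.H), cy + hh),
        confidence=conf,
        cls=cls,
    )


def read_detector_boxes(path: str | Path, dims: ImageDims) -> list[RoiBox]:
    """Read "cls conf x_center y_center width height" normalized text lines."""
    boxes: list[RoiBox] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
        try:
            cls = int(fields[0])
            conf, x, y, w, h = map(float, fields[1:])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
        boxes.append(normbox_to_roibox(cls, conf, x, y, w, h, dims))
    return boxes
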