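"""Phantom radiograph generator with known circle ground truth.

The phantoms emulate the structure the circle pipeline consumes on an AP hip
radiograph: a bright femoral-head disc seated inside a bright acetabular rim
with a dark joint-space gap between them, degraded by additive Gaussian
noise, occluding arcs deleted from the rim (overlapping bone), and bright
line segments crossing the field (screws).  The cup rim is rendered with a
sharp inner boundary at the ground-truth cup radius and a linear outward
intensity fade over ``rim_width``, so the strongest rim edge — the one a
reader would annotate as the cup circle — sits exactly at ``cup.r``.

No attempt is made at radiographic physics (beam hardening, bone texture,
projection tilt); the pipeline consumes edges, not calibrated intensities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import (
    CLS_CUP,
    CLS_FEMORAL,
    Circle,
    ImageDims,
    NormalizedCircle,
    circle_to_normbox,
    normalize_circle,
)
from .wear import TimepointGeometry, WearReport, compute_wear_report

__all__ = [
    "PhantomSpec",
    "PrePostPair",
    "generate_phantom",
    "generate_dataset",
    "generate_pre_post_pair",
    "random_spec",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom image."""

    dims: ImageDims = field(default_factory=lambda: ImageDims(320, 320))
    femoral: Circle = Circle(160.0, 162.0, 38.0)
    cup: Circle = Circle(160.0, 160.0, 50.0)
    rim_width: float = 5.0
    rim_contrast: float = 80.0       # gray levels above background
    head_contrast: float = 90.0
    background_level: float = 40.0
    noise_sigma: float = 4.0
    occlusion_arcs: tuple[tuple[float, float], ...] = ()
    n_screw_lines: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cup.r > self.femoral.r:
            raise ValueError("cup radius must exceed femoral radius")
        gap = self.cup.r - self.femoral.r - math.hypot(
            self.cup.cx - self.femoral.cx, self.cup.cy - self.femoral.cy
        )
        if gap <= 0:
            raise ValueError("femoral head must sit inside the cup with a gap")
        if min(self.rim_contrast, self.head_contrast, self.noise_sigma) < 0:
            raise ValueError("contrasts and noise must be >= 0")


def _angle_in_arcs(angle: np.ndarray, arcs: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Boolean mask of angles (in [0, 2pi)) lying inside any arc."""
    mask = np.zeros(angle.shape, dtype=bool)
    two_pi = 2.0 * np.pi
    for a0, a1 in arcs:
        a0m, a1m = a0 % two_pi, a1 % two_pi
        if a0m <= a1m:
            mask |= (angle >= a0m) & (angle <= a1m)
        else:  # wraps through 0
            mask |= (angle >= a0m) | (angle <= a1m)
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, list[NormalizedCircle]]:
    """Render one phantom; returns the 8-bit image and its truth labels.

    Deterministic for a fixed spec (the seed drives the noise and the screw
    lines).  Truth labels are the normalized spec circles (class 0 femoral,
    class 1 cup).
    """
    W, H = spec.dims.W, spec.dims.H
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    img = np.full((H, W), spec.background_level, dtype=float)

    # femoral head: bright disc, 1-px anti-aliased edge
    d_fem = np.hypot(xx - spec.femoral.cx, yy - spec.femoral.cy)
    cover = np.clip(spec.femoral.r + 0.5 - d_fem, 0.0, 1.0)
    img += spec.head_contrast * cover

    # cup rim: sharp inner step at cup.r, linear fade outward over rim_width
    d_cup = np.hypot(xx - spec.cup.cx, yy - spec.cup.cy)
    inner = np.clip(d_cup - spec.cup.r + 0.5, 0.0, 1.0)          # anti-aliased step
    fade = np.clip(1.0 - (d_cup - spec.cup.r) / spec.rim_width, 0.0, 1.0)
    rim = spec.rim_contrast * inner * fade
    if spec.occlusion_arcs:
        angle = np.arctan2(yy - spec.cup.cy, xx - spec.cup.cx) % (2.0 * np.pi)
        rim[_angle_in_arcs(angle, spec.occlusion_arcs)] = 0.0
    img += rim

    rng = np.random.default_rng(spec.seed)
    # screw artifacts: bright line segments of ~2 px thickness
    for _ in range(spec.n_screw_lines):
        x0, x1 = rng.uniform(0, W, size=2)
        y0, y1 = rng.uniform(0, H, size=2)
        n = int(max(abs(x1 - x0), abs(y1 - y0))) * 2 + 2
        ts = np.linspace(0.0, 1.0, n)
        lx = x0 + ts * (x1 - x0)
        ly = y0 + ts * (y1 - y0)
        for off in (-0.5, 0.0, 0.5):
            ix = np.clip(np.rint(lx + off), 0, W - 1).astype(int)
            iy = np.clip(np.rint(ly), 0, H - 1).astype(int)
            img[iy, ix] = spec.background_level + 150.0

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = [
        normalize_circle(spec.femoral, spec.dims, CLS_FEMORAL),
        normalize_circle(spec.cup, spec.dims, CLS_CUP),
    ]
    return image, truth


def random_spec(
    rng: np.random.Generator,
    dims: ImageDims = ImageDims(320, 320),
    noise_sigma: tuple[float, float] = (2.0, 8.0),
    max_occlusion: float = math.radians(60.0),
    fem_r: tuple[float, float] = (30.0, 44.0),
    gap: tuple[float, float] = (9.0, 16.0),
) -> PhantomSpec:
    """Sample a phantom spec uniformly within the study parameter ranges."""
    r_fem = rng.uniform(*fem_r)
    g = rng.uniform(*gap)
    r_cup = r_fem + g
    cx = dims.W / 2.0 + rng.uniform(-10.0, 10.0)
    cy = dims.H / 2.0 + rng.uniform(-10.0, 10.0)
    # head center offset, strictly inside the cup with >1 px residual gap
    max_off = max(0.0, g - 2.0) / 2.0
    theta = rng.uniform(0.0, 2.0 * np.pi)
    off = rng.uniform(0.0, min(3.0, max_off))
    occl_total = rng.uniform(0.0, max_occlusion)
    occl_start = rng.uniform(0.0, 2.0 * np.pi)
    arcs = ((occl_start, occl_start + occl_total),) if occl_total > 1e-3 else ()
    return PhantomSpec(
        dims=dims,
        femoral=Circle(cx + off * math.cos(theta), cy + off * math.sin(theta), r_fem),
        cup=Circle(cx, cy, r_cup),
        rim_width=rng.uniform(4.0, 6.0),
        rim_contrast=rng.uniform(60.0, 100.0),
        head_contrast=rng.uniform(70.0, 110.0),
        background_level=rng.uniform(30.0, 50.0),
        noise_sigma=rng.uniform(*noise_sigma),
        occlusion_arcs=arcs,
        n_screw_lines=int(rng.integers(0, 3)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n: int,
    out_dir: str | Path,
    seed: int = 0,
    **range_overrides,
) -> dict:
    """Write ``n`` phantoms with circle labels, box labels and a manifest.

    Layout: ``images/*.png``, ``labels_circle/*.txt`` ("cls x y r"),
    ``labels_box/*.txt`` ("cls x y w h"), ``manifest.json`` listing the
    per-image seeds.  Parameter ranges may be overridden via keyword
    arguments forwarded to :func:`random_spec`.
    """
    from .io import write_box_labels, write_circle_annotations

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels_circle").mkdir(exist_ok=True)
    (out / "labels_box").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n):
        spec = random_spec(rng, **range_overrides)
        image, truth = generate_phantom(spec)
        name = f"phantom_{i:04d}"
        Image.fromarray(image).save(out / "images" / f"{name}.png")
        write_circle_annotations(truth, out / "labels_circle" / f"{name}.txt")
        boxes = [circle_to_normbox(nc, spec.dims) for nc in truth]
        write_box_labels(boxes, out / "labels_box" / f"{name}.txt")
        entries.append(
            {"name": name, "seed": spec.seed, "W": spec.dims.W, "H": spec.dims.H}
        )
    manifest = {"n": n, "seed": seed, "images": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


@dataclass(frozen=True)
class PrePostPair:
    """A PRE/POST phantom pair with its analytically expected wear report."""

    pre_spec: PhantomSpec
    post_spec: PhantomSpec
    pre_image: np.ndarray
    post_image: np.ndarray
    pre_truth: list[NormalizedCircle]
    post_truth: list[NormalizedCircle]
    expected: WearReport


def generate_pre_post_pair(
    base: PhantomSpec,
    head_shift: tuple[float, float] = (2.0, -3.0),
    post_scale: float = 1.0,
    seed: int = 1,
) -> PrePostPair:
    """Simulate a follow-up exam: head migration plus a magnification change.

    POST = PRE with the femoral center translated by ``head_shift`` (pixels,
    PRE scale), then ALL geometry — circles and image dimensions — multiplied
    by ``post_scale``.  The expected wear report is computed analytically from
    the spec circles; by construction the scale factor cancels ``post_scale``
    exactly.
    """
    if post_scale <= 0:
        raise ValueError("post_scale must be positive")
    k = post_scale
    fem_post = Circle(
        (base.femoral.cx + head_shift[0]) * k,
        (base.femoral.cy + head_shift[1]) * k,
        base.femoral.r * k,
    )
    cup_post = Circle(base.cup.cx * k, base.cup.cy * k, base.cup.r * k)
    gap = cup_post.r - fem_post.r - math.hypot(
        cup_post.cx - fem_post.cx, cup_post.cy - fem_post.cy
    )
    if gap <= 0:
        raise ValueError("head_shift pushes the head outside the cup")
    post_dims = ImageDims(
        max(1, int(round(base.dims.W * k))), max(1, int(round(base.dims.H * k)))
    )
    post_spec = replace(
        base,
        dims=post_dims,
        femoral=fem_post,
        cup=cup_post,
        rim_width=base.rim_width * k,
        seed=seed,
    )
    pre_image, pre_truth = generate_phantom(base)
    post_image, post_truth = generate_phantom(post_spec)
    expected = compute_wear_report(
        TimepointGeometry(base.femoral, base.cup, "PRE"),
        TimepointGeometry(fem_post, cup_post, "POST"),
    )
    return PrePostPair(
        pre_spec=base,
        post_spec=post_spec,
        pre_image=pre_image,
        post_image=post_image,
        pre_truth=pre_truth,
        post_truth=post_truth,
        expected=expected,
    )
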