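"""On-disk formats and pipeline configuration.

Annotation formats (one record per line, whitespace-separated, normalized
floats):

- circle annotations: ``cls x y r`` (class 0 femoral head, 1 acetabular cup);
- box labels: ``cls x_center y_center width height``.

The pipeline configuration is a YAML file with nested sections mirroring the
module structure; unknown keys are rejected and every value is type-checked
on load, so silent drift of a misspelled key is impossible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml
from PIL import Image

from .geometry import NormalizedBox, NormalizedCircle
from .preprocess import EnhanceConfig
from .refine import CupSearchConfig, EdgeSnapConfig, RansacConfig, RefineConfig

__all__ = [
    "ParseError",
    "read_circle_annotations",
    "write_circle_annotations",
    "read_box_labels",
    "write_box_labels",
    "load_image_gray",
    "load_config",
    "config_to_refine",
    "DEFAULT_CONFIG",
]


class ParseError(ValueError):
    """Malformed annotation or configuration input."""


def _parse_lines(path: str | Path, n_fields: int) -> list[tuple[int, list[float]]]:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != n_fields:
            raise ParseError(
                f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        try:
            cls = int(fields[0])
            values = [float(f) for f in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
        records.append((cls, values))
    return records


def read_circle_annotations(path: str | Path) -> list[NormalizedCircle]:
    """Read a ``cls x y r`` annotation file."""
    out = []
    for lineno, (cls, (x, y, r)) in enumerate(_parse_lines(path, 4), start=1):
        try:
            out.append(NormalizedCircle(cls=cls, x=x, y=y, r=r))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_circle_annotations(
    circles: Sequence[NormalizedCircle], path: str | Path
) -> None:
    lines = [f"{c.cls} {c.x:.6f} {c.y:.6f} {c.r:.6f}" for c in circles]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_box_labels(path: str | Path) -> list[NormalizedBox]:
    """Read a ``cls x_center y_center width height`` label file."""
    out = []
    for lineno, (cls, (x, y, w, h)) in enumerate(_parse_lines(path, 5), start=1):
        try:
            out.append(NormalizedBox(cls=cls, x_box=x, y_box=y, w=w, h=h))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_box_labels(boxes: Sequence[NormalizedBox], path: str | Path) -> None:
    lines = [
        f"{b.cls} {b.x_box:.6f} {b.y_box:.6f} {b.w:.6f} {b.h:.6f}" for b in boxes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_image_gray(path: str | Path) -> np.ndarray:
    """8-bit grayscale image; multi-channel inputs reduced by channel average."""
    img = np.asarray(Image.open(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return np.clip(np.rint(img.astype(float)), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "preprocess": {
        "clahe_clip": 0.01,
        "clahe_tiles": 8,
        "bilateral_d": 9,
        "bilateral_sigma_color": 25.0,
        "bilateral_sigma_space": 3.0,
        "canny_sigma": 0.33,
        "edge_weights": [0.5, 0.5],
        "unsharp_amount": 1.0,
        "sharpen": True,
    },
    "roi": {
        "margin_frac": 0.15,
        "jitter": 0.03,
    },
    "refine": {
        "n_angles": 360,
        "annulus_frac": 0.2,
        "min_support_frac": 0.1,
        "noise_floor": 0.2,
        "ransac_n_iter": 500,
        "inlier_tol": 2.0,
        "ring_frac": 0.15,
        "cup_n_shifts": 3,
        "cup_shift_frac": 0.08,
        "cup_scale_low": 0.9,
        "cup_scale_high": 1.15,
        "cup_n_scales": 5,
        "cup_use_ransac": True,
        "score_weights": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        "support_threshold": 0.25,
        "fallback_threshold": 0.35,
        "min_gap": 1.0,
        "min_edge_density": 0.02,
        "hough_r_step": 1.0,
        "hough_n_peaks": 5,
        "hough_vote_floor": 0.05,
        "seed": 0,
    },
    "metrics": {
        "iou_tau": 0.5,
        "conf_t": 0.0,
        "tolerances": [0.005, 0.01, 0.02, 0.03, 0.05],
    },
    "synth": {
        "width": 320,
        "height": 320,
        "noise_sigma_low": 2.0,
        "noise_sigma_high": 8.0,
        "max_occlusion_deg": 60.0,
    },
}


def _check_type(section: str, key: str, value: Any, default: Any) -> Any:
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ParseError(f"config {section}.{key}: expected bool")
        return value
    if isinstance(default, int) and not isinstance(default, bool):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ParseError(f"config {section}.{key}: expected int")
        return value
    if isinstance(default, float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ParseError(f"config {section}.{key}: expected number")
        return float(value)
    if isinstance(default, list):
        if not isinstance(value, list):
            raise ParseError(f"config {section}.{key}: expected list")
        return [float(v) for v in value]
    return value


def load_config(path: str | Path | None = None) -> dict[str, dict[str, Any]]:
    """Defaults merged with a YAML overlay; unknown keys raise ParseError."""
    config = {s: dict(kv) for s, kv in DEFAULT_CONFIG.items()}
    if path is None:
        return config
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(loaded, dict):
        raise ParseError(f"config {path}: top level must be a mapping")
    for section, kv in loaded.items():
        if section not in config:
            raise ParseError(f"config {path}: unknown section '{section}'")
        if not isinstance(kv, dict):
            raise ParseError(f"config {path}: section '{section}' must be a mapping")
        for key, value in kv.items():
            if key not in config[section]:
                raise ParseError(f"config {path}: unknown key '{section}.{key}'")
            config[section][key] = _check_type(
                section, key, value, DEFAULT_CONFIG[section][key]
            )
    return config


def config_to_refine(config: dict[str, dict[str, Any]]) -> RefineConfig:
    """Materialize a :class:`RefineConfig` from the nested config mapping."""
    p, r = config["preprocess"], config["refine"]
    return RefineConfig(
        enhance=EnhanceConfig(
            clahe_clip=p["clahe_clip"],
            clahe_tiles=p["clahe_tiles"],
            bilateral_d=p["bilateral_d"],
            bilateral_sigma_color=p["bilateral_sigma_color"],
            bilateral_sigma_space=p["bilateral_sigma_space"],
            unsharp_amount=p["unsharp_amount"],
            sharpen=p["sharpen"],
        ),
        canny_sigma=p["canny_sigma"],
        edge_weights=tuple(p["edge_weights"]),
        margin_frac=config["roi"]["margin_frac"],
        edge_snap=EdgeSnapConfig(
            n_angles=r["n_angles"],
            annulus_frac=r["annulus_frac"],
            min_support_frac=r["min_support_frac"],
            noise_floor=r["noise_floor"],
        ),
        ransac=RansacConfig(
            n_iter=r["ransac_n_iter"],
            inlier_tol=r["inlier_tol"],
            ring_frac=r["ring_frac"],
            seed=r["seed"],
        ),
        cup=CupSearchConfig(
            n_shifts=r["cup_n_shifts"],
            shift_frac=r["cup_shift_frac"],
            scale_range=(r["cup_scale_low"], r["cup_scale_high"]),
            n_scales=r["cup_n_scales"],
            use_ransac=r["cup_use_ransac"],
            score_weights=tuple(r["score_weights"]),
            support_threshold=r["support_threshold"],
            fallback_threshold=r["fallback_threshold"],
        ),
        min_gap=r["min_gap"],
        min_edge_density=r["min_edge_density"],
        hough_r_step=r["hough_r_step"],
        hough_n_peaks=r["hough_n_peaks"],
        hough_vote_floor=r["hough_vote_floor"],
        seed=r["seed"],
    )
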