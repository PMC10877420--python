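"""Seeded synthetic micro-pest scene generator.

Renders desk-scale stand-ins for macro photographs of small tea pests:
compact dark ellipse-plus-appendage blobs (four classes "A"-"D" with
class-specific hue and eccentricity, plus per-instance jitter, so classes
are similar but separable) on a leaf-green textured or sticky-board
yellow background, with variable illumination and optional partial
occlusion emulating body-impaired targets.  Ground-truth boxes tightly
bound the *full* blob extent even when part of it is occluded, matching
how an annotator labels a partially hidden insect.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .boxes import Box, ImageDims
from .datapipe import CLASS_LABELS, AnnotatedImage, write_voc_xml, write_yolo_txt
from .metrics import GroundTruthBox

__all__ = ["SceneConfig", "easy_config", "generate_scene", "generate_scenes",
           "generate_dataset"]

# class -> (base RGB, eccentricity): similar dark hues, different body shapes
_DEFAULT_PALETTE = {
    "A": ((95, 110, 55), 0.50),   # greenish leafhopper-like, elongated
    "B": ((105, 80, 45), 0.15),   # brown aphid-like, round
    "C": ((50, 45, 40), 0.35),    # near-black borer-like
    "D": ((115, 100, 70), 0.55),  # pale leafhopper-like, elongated
}

# visually well-separated palette for the "easy" configuration
_EASY_PALETTE = {
    "A": ((200, 50, 50), 0.45),
    "B": ((50, 70, 200), 0.15),
    "C": ((25, 25, 25), 0.35),
    "D": ((225, 200, 50), 0.55),
}


@dataclass(frozen=True)
class SceneConfig:
    """Scene generation parameters.

    Pest size is a fraction of the image side length (study setting:
    small, 2-8%).  Occlusion masks the stated fraction of a blob's pixels
    while the box keeps the full extent.
    """

    image_size: int = 256
    palette: dict = field(default_factory=lambda: dict(_DEFAULT_PALETTE))
    pests_per_image: tuple = (1, 6)
    pest_size_frac: tuple = (0.02, 0.08)
    illumination_gain: tuple = (0.6, 1.4)
    occlusion_prob: float = 0.3
    occluded_fraction: tuple = (0.2, 0.5)
    background: str = "leaf"           # "leaf" | "board"
    color_jitter: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValueError("occlusion_prob must lie in [0,1]")
        for name in ("pests_per_image", "pest_size_frac",
                     "illumination_gain", "occluded_fraction"):
            lo, hi = getattr(self, name)
            if hi < lo or lo < 0:
                raise ValueError(f"bad range for {name}: ({lo}, {hi})")


def easy_config(image_size: int = 64, seed: int = 0) -> SceneConfig:
    """High-contrast, unoccluded scenes with >=16 px pests — the separable
    setting used for end-to-end smoke training of the tiny detector."""
    return SceneConfig(
        image_size=image_size,
        palette=dict(_EASY_PALETTE),
        pests_per_image=(1, 3),
        pest_size_frac=(16 / image_size, 24 / image_size),
        illumination_gain=(0.9, 1.1),
        occlusion_prob=0.0,
        background="leaf",
        color_jitter=8.0,
        seed=seed,
    )


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    s = cfg.image_size
    base = np.array([75, 140, 65], float) if cfg.background == "leaf" \
        else np.array([230, 205, 70], float)
    tex = rng.normal(0.0, 1.0, (s, s, 3))
    tex = ndimage.gaussian_filter(tex, sigma=(s / 16, s / 16, 0))
    tex = tex / (np.abs(tex).max() + 1e-9) * 18.0
    img = base[None, None, :] + tex + rng.normal(0, 3.0, (s, s, 3))
    return np.clip(img, 0, 255)


def _blob_mask(size: int, cx: float, cy: float, a: float, b: float,
               phi: float) -> np.ndarray:
    """Ellipse body plus a smaller head ellipse along the major axis."""
    yy, xx = np.mgrid[0:size, 0:size]
    c, s = np.cos(phi), np.sin(phi)

    def ellipse(ecx, ecy, ea, eb):
        u = (xx - ecx) * c + (yy - ecy) * s
        v = -(xx - ecx) * s + (yy - ecy) * c
        return (u / ea) ** 2 + (v / eb) ** 2 <= 1.0

    body = ellipse(cx, cy, a, b)
    head = ellipse(cx + a * c, cy + a * s, max(b * 0.6, 1.0), max(b * 0.6, 1.0))
    return body | head


def generate_scene(cfg: SceneConfig, rng: np.random.Generator,
                   source_id: str = "scene") -> AnnotatedImage:
    """Render one annotated scene; fully deterministic given the rng state."""
    s = cfg.image_size
    img = _background(cfg, rng)
    labels = sorted(cfg.palette)
    n_lo, n_hi = cfg.pests_per_image
    n = int(rng.integers(n_lo, n_hi + 1))
    boxes: list[GroundTruthBox] = []
    for _ in range(n):
        label = labels[int(rng.integers(0, len(labels)))]
        (base_rgb, ecc) = cfg.palette[label]
        side = rng.uniform(*cfg.pest_size_frac) * s
        a = max(side / 2.0, 2.0)
        b = max(a * (1.0 - ecc), 1.5)
        margin = min(a + b + 2, s / 2.0 - 1.0)
        # keep new blobs from piling onto one another
        for _try in range(20):
            cx = rng.uniform(margin, s - margin)
            cy = rng.uniform(margin, s - margin)
            if all(np.hypot(cx - (g.box.x1 + g.box.x2) / 2,
                            cy - (g.box.y1 + g.box.y2) / 2) > a + 4
                   for g in boxes):
                break
        phi = rng.uniform(0, np.pi)
        mask = _blob_mask(s, cx, cy, a, b, phi)
        if not mask.any():
            continue
        ys, xs = np.nonzero(mask)
        box = Box(float(xs.min()), float(ys.min()),
                  float(xs.max() + 1), float(ys.max() + 1))
        color = np.array(base_rgb, float) + rng.uniform(
            -cfg.color_jitter, cfg.color_jitter, 3)
        render_mask = mask
        if cfg.occlusion_prob > 0 and rng.uniform() < cfg.occlusion_prob:
            frac = rng.uniform(*cfg.occluded_fraction)
            # hide the fraction of blob pixels furthest along a random axis
            direction = rng.uniform(0, 2 * np.pi)
            proj = xs * np.cos(direction) + ys * np.sin(direction)
            cut = np.quantile(proj, 1.0 - frac)
            hide = np.zeros_like(mask)
            hide[ys[proj >= cut], xs[proj >= cut]] = True
            render_mask = mask & ~hide
        speckle = rng.normal(0, 6.0, (s, s, 1))
        img = np.where(render_mask[..., None], color[None, None, :] + speckle, img)
        boxes.append(GroundTruthBox(box, label))
    gain = rng.uniform(*cfg.illumination_gain)
    pixels = np.clip(img * gain, 0, 255).round().astype(np.uint8)
    return AnnotatedImage(pixels, boxes, source_id).validate()


def generate_scenes(cfg: SceneConfig, n: int) -> list[AnnotatedImage]:
    """n scenes seeded from cfg.seed (scene i uses child seed [seed, i])."""
    return [
        generate_scene(cfg, np.random.default_rng([cfg.seed, i]), f"scene_{i:05d}")
        for i in range(n)
    ]


def generate_dataset(cfg: SceneConfig, n: int, out_dir, fmt: str = "yolo") -> dict:
    """Write n scenes plus annotations and a manifest to `out_dir`.

    fmt: "yolo", "voc" or "both".  Returns the manifest (also written as
    manifest.json): image count, seed, per-class box counts, file list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fmt not in ("yolo", "voc", "both"):
        raise ValueError(f"unknown format {fmt!r}")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    if fmt in ("yolo", "both"):
        (out / "labels").mkdir(exist_ok=True)
    if fmt in ("voc", "both"):
        (out / "annotations").mkdir(exist_ok=True)
    scenes = generate_scenes(cfg, n)
    class_counts = {c: 0 for c in sorted(cfg.palette)}
    files = []
    for scene in scenes:
        name = scene.source_id
        Image.fromarray(scene.pixels).save(out / "images" / f"{name}.png")
        files.append(f"images/{name}.png")
        if fmt in ("yolo", "both"):
            write_yolo_txt(out / "labels" / f"{name}.txt", scene.boxes, scene.dims)
        if fmt in ("voc", "both"):
            write_voc_xml(out / "annotations" / f"{name}.xml", scene.boxes,
                          scene.dims, filename=f"{name}.png")
        for g in scene.boxes:
            class_counts[g.class_id] += 1
    manifest = {
        "n_images": n,
        "seed": cfg.seed,
        "image_size": cfg.image_size,
        "format": fmt,
        "class_box_counts": class_counts,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
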