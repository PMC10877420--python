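"""Dataset handling for small-pest detection.

Covers the study-style data pipeline: five augmentation operators
(cropping, rotation, local enlargement, exposure adjustment, Gaussian
noise), expansion of a small original set by an integer factor (each
original retained plus factor-1 augmented variants), a low-quality filter
that flags images whose insects occupy too small an area fraction, a
per-class 6:2:2 train/test/validation split by largest-remainder
apportionment, and lossless YOLO-TXT / Pascal-VOC-XML annotation
round-trips.

All geometry stays in continuous 0-based corner coordinates; VOC files
use the conventional 1-based integer corners and are converted on the
way in/out.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image
from scipy import ndimage

from .boxes import Box, ImageDims
from .metrics import GroundTruthBox

__all__ = [
    "CLASS_LABELS", "AnnotatedImage", "AugmentConfig", "DatasetSplit",
    "augment_image", "expand_dataset", "quality_filter",
    "apportion", "split_dataset",
    "read_yolo_txt", "write_yolo_txt", "read_voc_xml", "write_voc_xml",
]

CLASS_LABELS = ("A", "B", "C", "D")

#: boxes thinner than this after clipping are dropped
MIN_BOX_SIZE = 2.0

AUGMENT_OPS = ("crop", "rotate", "enlarge", "exposure", "noise")


@dataclass
class AnnotatedImage:
    """An RGB image with its ground-truth boxes."""

    pixels: np.ndarray                 # (H, W, 3) uint8
    boxes: list[GroundTruthBox]
    source_id: str = ""

    @property
    def dims(self) -> ImageDims:
        h, w = self.pixels.shape[:2]
        return ImageDims(w, h)

    def validate(self):
        h, w = self.pixels.shape[:2]
        for gt in self.boxes:
            b = gt.box
            if b.x1 < 0 or b.y1 < 0 or b.x2 > w or b.y2 > h:
                raise ValueError(f"box {b} exceeds image bounds {w}x{h}")
        return self


@dataclass(frozen=True)
class AugmentConfig:
    """Parameter ranges of the five augmentation operators.

    Fractions/gains are drawn uniformly from the stated (lo, hi) ranges;
    noise sigma is on the 8-bit intensity scale.
    """

    crop_keep: tuple = (0.70, 0.95)
    rotation_deg: tuple = (-30.0, 30.0)
    axis_rotation_prob: float = 0.25   # chance a rotation snaps to +-90/180
    enlarge_scale: tuple = (1.2, 2.0)
    exposure_gain: tuple = (0.5, 1.5)
    noise_sigma: tuple = (5.0, 20.0)
    variants_per_original: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("crop_keep", "rotation_deg", "enlarge_scale",
                     "exposure_gain", "noise_sigma"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")
        if self.variants_per_original < 0:
            raise ValueError("variant count must be >= 0")


# ---------------------------------------------------------------------------
# geometric helpers
# ---------------------------------------------------------------------------

def _clip_boxes(boxes: list[GroundTruthBox], w: float, h: float) -> list[GroundTruthBox]:
    out = []
    for gt in boxes:
        b = gt.box
        x1, y1 = max(b.x1, 0.0), max(b.y1, 0.0)
        x2, y2 = min(b.x2, float(w)), min(b.y2, float(h))
        if x2 - x1 >= MIN_BOX_SIZE and y2 - y1 >= MIN_BOX_SIZE:
            out.append(GroundTruthBox(Box(x1, y1, x2, y2), gt.class_id))
    return out


def _rotate_point(x, y, cx, cy, theta):
    # positive angle: (x,y) -> (cx + cos*dx + sin*dy, cy - sin*dx + cos*dy)
    dx, dy = x - cx, y - cy
    return (cx + np.cos(theta) * dx + np.sin(theta) * dy,
            cy - np.sin(theta) * dx + np.cos(theta) * dy)


def _rotate_pixels(pixels: np.ndarray, theta: float) -> np.ndarray:
    """Rotate pixels with the exact inverse of :func:`_rotate_point` so the
    pixel and box transforms agree."""
    h, w = pixels.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # output (row, col) -> input (row, col)
    mat = np.array([[np.cos(theta), np.sin(theta)],
                    [-np.sin(theta), np.cos(theta)]])
    center = np.array([cy, cx])
    offset = center - mat @ center
    out = np.empty_like(pixels)
    for ch in range(pixels.shape[2]):
        out[..., ch] = ndimage.affine_transform(
            pixels[..., ch].astype(float), mat, offset=offset, order=1,
            mode="nearest").round().clip(0, 255).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# the five operators
# ---------------------------------------------------------------------------

def _op_crop(img: AnnotatedImage, rng, cfg: AugmentConfig) -> AnnotatedImage:
    h, w = img.pixels.shape[:2]
    keep = rng.uniform(*cfg.crop_keep)
    cw, ch = max(int(round(w * keep)), 8), max(int(round(h * keep)), 8)
    x0 = int(rng.integers(0, w - cw + 1))
    y0 = int(rng.integers(0, h - ch + 1))
    pixels = img.pixels[y0:y0 + ch, x0:x0 + cw].copy()
    boxes = [GroundTruthBox(Box(max(g.box.x1 - x0, 0), max(g.box.y1 - y0, 0),
                                max(g.box.x2 - x0, 0), max(g.box.y2 - y0, 0)),
                            g.class_id) for g in img.boxes]
    return AnnotatedImage(pixels, _clip_boxes(boxes, cw, ch), img.source_id)


def _op_rotate(img: AnnotatedImage, rng, cfg: AugmentConfig,
               angle_deg: float | None = None) -> AnnotatedImage:
    if angle_deg is None:
        if rng.uniform() < cfg.axis_rotation_prob:
            angle_deg = float(rng.choice([90.0, 180.0, 270.0]))
        else:
            angle_deg = float(rng.uniform(*cfg.rotation_deg))
    theta = np.deg2rad(angle_deg)
    h, w = img.pixels.shape[:2]
    # boxes live in continuous corner coordinates (image spans [0,w]x[0,h]);
    # pixels are rotated in index coordinates about ((w-1)/2, (h-1)/2), which
    # is the same physical point
    cy, cx = h / 2.0, w / 2.0
    if angle_deg % 360 == 0:
        return AnnotatedImage(img.pixels.copy(), list(img.boxes), img.source_id)
    pixels = _rotate_pixels(img.pixels, theta)
    boxes = []
    for g in img.boxes:
        corners = [(g.box.x1, g.box.y1), (g.box.x2, g.box.y1),
                   (g.box.x1, g.box.y2), (g.box.x2, g.box.y2)]
        pts = [_rotate_point(x, y, cx, cy, theta) for x, y in corners]
        xs, ys = zip(*pts)
        boxes.append(GroundTruthBox(Box(min(xs), min(ys), max(xs), max(ys)), g.class_id))
    return AnnotatedImage(pixels, _clip_boxes(boxes, w, h), img.source_id)


def _op_enlarge(img: AnnotatedImage, rng, cfg: AugmentConfig) -> AnnotatedImage:
    """Local enlargement: zoom into a random sub-window and resize back."""
    h, w = img.pixels.shape[:2]
    scale = rng.uniform(*cfg.enlarge_scale)
    cw, ch = max(int(round(w / scale)), 8), max(int(round(h / scale)), 8)
    x0 = int(rng.integers(0, w - cw + 1))
    y0 = int(rng.integers(0, h - ch + 1))
    window = img.pixels[y0:y0 + ch, x0:x0 + cw]
    pixels = np.asarray(Image.fromarray(window).resize((w, h), Image.BILINEAR))
    sx, sy = w / cw, h / ch
    boxes = [GroundTruthBox(Box(max((g.box.x1 - x0) * sx, 0), max((g.box.y1 - y0) * sy, 0),
                                max((g.box.x2 - x0) * sx, 0), max((g.box.y2 - y0) * sy, 0)),
                            g.class_id) for g in img.boxes]
    return AnnotatedImage(pixels.copy(), _clip_boxes(boxes, w, h), img.source_id)


def _op_exposure(img: AnnotatedImage, rng, cfg: AugmentConfig,
                 gain: float | None = None) -> AnnotatedImage:
    gain = rng.uniform(*cfg.exposure_gain) if gain is None else gain
    pixels = np.clip(img.pixels.astype(float) * gain, 0, 255).round().astype(np.uint8)
    return AnnotatedImage(pixels, list(img.boxes), img.source_id)


def _op_noise(img: AnnotatedImage, rng, cfg: AugmentConfig,
              sigma: float | None = None) -> AnnotatedImage:
    sigma = rng.uniform(*cfg.noise_sigma) if sigma is None else sigma
    noisy = img.pixels.astype(float)
    if sigma > 0:
        noisy = noisy + rng.normal(0.0, sigma, img.pixels.shape)
    pixels = np.clip(noisy, 0, 255).round().astype(np.uint8)
    return AnnotatedImage(pixels, list(img.boxes), img.source_id)


_OPS = {"crop": _op_crop, "rotate": _op_rotate, "enlarge": _op_enlarge,
        "exposure": _op_exposure, "noise": _op_noise}


def augment_image(img: AnnotatedImage, op: str, cfg: AugmentConfig | None = None,
                  seed: int | np.random.Generator = 0, **params) -> AnnotatedImage:
    """Apply one named operator; geometric operators transform the boxes,
    photometric ones (exposure, noise) leave them unchanged.  Boxes are
    clipped to bounds and dropped when reduced below 2 px a side."""
    if op not in _OPS:
        raise ValueError(f"unknown operator {op!r}; choose from {AUGMENT_OPS}")
    cfg = cfg or AugmentConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _OPS[op](img, rng, cfg, **params)


def expand_dataset(originals: list[AnnotatedImage], cfg: AugmentConfig,
                   factor: int | None = None) -> list[AnnotatedImage]:
    """Expand by `factor`: each original is retained and contributes
    factor-1 seeded random-operator variants; output size is exactly
    factor * len(originals)."""
    factor = (cfg.variants_per_original + 1) if factor is None else factor
    if factor < 1:
        raise ValueError("expansion factor must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    out: list[AnnotatedImage] = []
    for img in originals:
        out.append(img)
        for v in range(factor - 1):
            op = AUGMENT_OPS[int(rng.integers(0, len(AUGMENT_OPS)))]
            aug = _OPS[op](img, rng, cfg)
            aug.source_id = f"{img.source_id}#aug{v}:{op}"
            out.append(aug)
    return out


def quality_filter(imgs: list[AnnotatedImage], min_area_fraction: float = 0.2):
    """Split into (kept, flagged): an image is flagged when its total box
    area covers less than `min_area_fraction` of the image."""
    if not 0.0 < min_area_fraction < 1.0:
        raise ValueError("min_area_fraction must lie in (0,1)")
    kept, flagged = [], []
    for img in imgs:
        h, w = img.pixels.shape[:2]
        frac = sum(g.box.area for g in img.boxes) / (w * h)
        (kept if frac >= min_area_fraction else flagged).append(img)
    return kept, flagged


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    ratios: tuple
    assignment: dict = field(default_factory=dict)  # index -> partition name

    PARTITIONS = ("train", "test", "val")

    def indices(self, partition: str) -> list[int]:
        return [i for i, p in self.assignment.items() if p == partition]


def apportion(n: int, ratios: tuple) -> tuple:
    """Largest-remainder apportionment of n items into len(ratios)
    partitions; remainder ties go to the earlier partition."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    leftover = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        counts[i] += 1
    return tuple(counts)


def split_dataset(imgs: list[AnnotatedImage], ratios: tuple = (0.6, 0.2, 0.2),
                  seed: int = 0, key=None) -> DatasetSplit:
    """Per-class 6:2:2-style split.

    Images are grouped by `key` (default: the class of the first box, or
    "__none__"), each group's counts apportioned by largest remainder,
    and membership shuffled by `seed`.  Sizes are deterministic given the
    group counts; membership is reproducible given the seed.
    """
    if len(imgs) < len(ratios):
        raise ValueError("fewer images than partitions")
    key = key or (lambda im: im.boxes[0].class_id if im.boxes else "__none__")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[int]] = {}
    for i, img in enumerate(imgs):
        groups.setdefault(key(img), []).append(i)
    split = DatasetSplit(tuple(ratios))
    for label in sorted(groups):
        idx = np.array(groups[label])
        rng.shuffle(idx)
        counts = apportion(len(idx), tuple(ratios))
        pos = 0
        for part, cnt in zip(DatasetSplit.PARTITIONS, counts):
            for i in idx[pos:pos + cnt]:
                split.assignment[int(i)] = part
            pos += cnt
    return split


# ---------------------------------------------------------------------------
# annotation formats
# ---------------------------------------------------------------------------

def write_yolo_txt(path, boxes: list[GroundTruthBox], dims: ImageDims,
                   class_labels=CLASS_LABELS):
    """One line per box: `class_idx cx cy w h`, normalized, 6 decimals."""
    lines = []
    for g in boxes:
        if g.class_id not in class_labels:
            raise ValueError(f"unknown class {g.class_id!r}; known: {class_labels}")
        b = g.box
        cx, cy = (b.x1 + b.x2) / 2 / dims.w, (b.y1 + b.y2) / 2 / dims.h
        lines.append(f"{class_labels.index(g.class_id)} "
                     f"{cx:.6f} {cy:.6f} {b.w / dims.w:.6f} {b.h / dims.h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path, dims: ImageDims, class_labels=CLASS_LABELS) -> list[GroundTruthBox]:
    boxes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            idx = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: malformed line ({e})") from None
        if not (0 <= idx < len(class_labels)):
            raise ValueError(f"{path}:{lineno}: class index {idx} out of range")
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}:{lineno}: {name}={v} outside [0,1]")
        boxes.append(GroundTruthBox(
            Box((cx - w / 2) * dims.w, (cy - h / 2) * dims.h,
                (cx + w / 2) * dims.w, (cy + h / 2) * dims.h),
            class_labels[idx]))
    return boxes


def write_voc_xml(path, boxes: list[GroundTruthBox], dims: ImageDims,
                  filename: str = "", class_labels=CLASS_LABELS):
    """Pascal-VOC XML with 1-based integer corners: internal (x1,y1,x2,y2)
    maps to (round(x1)+1, round(y1)+1, round(x2), round(y2))."""
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = filename or Path(path).stem
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(dims.w)
    etree.SubElement(size, "height").text = str(dims.h)
    etree.SubElement(size, "depth").text = "3"
    for g in boxes:
        if g.class_id not in class_labels:
            raise ValueError(f"unknown class {g.class_id!r}; known: {class_labels}")
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = g.class_id
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = str(int(round(g.box.x1)) + 1)
        etree.SubElement(bb, "ymin").text = str(int(round(g.box.y1)) + 1)
        etree.SubElement(bb, "xmax").text = str(int(round(g.box.x2)))
        etree.SubElement(bb, "ymax").text = str(int(round(g.box.y2)))
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


def read_voc_xml(path, class_labels=CLASS_LABELS):
    """Returns (dims, boxes, filename); VOC 1-based integer corners become
    0-based continuous internal corners."""
    root = etree.parse(str(path)).getroot()
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise ValueError(f"{path}: missing size element")
    dims = ImageDims(int(size.findtext("width")), int(size.findtext("height")))
    boxes = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if name not in class_labels:
            raise ValueError(f"{path}: unknown class {name!r}; known: {class_labels}")
        bb = obj.find("bndbox")
        x1 = float(bb.findtext("xmin")) - 1
        y1 = float(bb.findtext("ymin")) - 1
        x2 = float(bb.findtext("xmax"))
        y2 = float(bb.findtext("ymax"))
        boxes.append(GroundTruthBox(Box(x1, y1, x2, y2), name))
    return dims, boxes, root.findtext("filename")
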