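"""Run configuration: YAML tree with defaults, validation and manifests.

Precedence is CLI flags > config file > defaults.  Unknown keys are
rejected so typos fail loudly rather than silently falling back to a
default.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_run_config", "merge_config", "config_hash",
           "write_manifest", "detector_config_from", "scene_config_from",
           "augment_config_from"]

DEFAULTS: dict = {
    "seed": 0,
    "out": "runs",
    "dataset": {
        "n": 100,
        "image_size": 64,
        "easy": True,
        "background": "leaf",
        "occlusion_prob": 0.3,
        "format": "yolo",
    },
    "augment": {
        "factor": 11,
        "crop_keep": [0.70, 0.95],
        "rotation_deg": [-30.0, 30.0],
        "enlarge_scale": [1.2, 2.0],
        "exposure_gain": [0.5, 1.5],
        "noise_sigma": [5.0, 20.0],
        "min_area_fraction": 0.2,
    },
    "split": {"ratios": [0.6, 0.2, 0.2]},
    "model": {
        "input_size": 64,
        "stride": 8,
        "channels": [16, 32, 32],
        "box_loss": "mpdiou",
        "lambda_box": 0.05,
        "lambda_obj": 1.0,
        "lambda_cls": 0.5,
        "scconv": {
            "enabled": True,
            "split_ratio": 0.5,
            "squeeze_ratio": 2,
            "gn_groups": 4,
            "gate_threshold": 1.0,
        },
        "bra": {"enabled": True, "S": 2, "topk": 4, "heads": 2, "lce_kernel": 5},
    },
    "train": {"epochs": 15, "batch_size": 4, "lr": 0.005},
    "eval": {
        "iou_threshold": 0.5,
        "conf_threshold": 0.1,
        "nms_iou": 0.45,
        "interpolation": "all_points",
    },
}


def _check_keys(cfg: dict, ref: dict, path: str = ""):
    bad = [f"{path}{k}" for k in cfg if k not in ref]
    if bad:
        raise ValueError(f"unknown configuration keys: {', '.join(sorted(bad))}")
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(ref[k], dict):
            _check_keys(v, ref[k], f"{path}{k}.")


def merge_config(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge_config(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_run_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults <- YAML file <- overrides, with unknown-key rejection."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        _check_keys(loaded, DEFAULTS)
        cfg = merge_config(cfg, loaded)
    if overrides:
        _check_keys(overrides, DEFAULTS)
        cfg = merge_config(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(out_dir, cfg: dict, extra: dict | None = None):
    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg.get("seed"),
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# -- adapters from the config tree to module dataclasses --------------------

def detector_config_from(cfg: dict):
    from .bra import BRAConfig
    from .detector import DetectorConfig
    m = cfg["model"]
    bra = m["bra"]
    return DetectorConfig(
        input_size=m["input_size"],
        stride=m["stride"],
        channels=tuple(m["channels"]),
        scconv_stage=m["scconv"]["enabled"],
        use_bra=bra["enabled"],
        bra=BRAConfig(S=bra["S"], topk=bra["topk"], heads=bra["heads"],
                      lce_kernel=bra["lce_kernel"]),
        box_loss=m["box_loss"],
        lambda_box=m["lambda_box"],
        lambda_obj=m["lambda_obj"],
        lambda_cls=m["lambda_cls"],
    )


def scene_config_from(cfg: dict):
    from .synth import SceneConfig, easy_config
    d = cfg["dataset"]
    if d["easy"]:
        return easy_config(image_size=d["image_size"], seed=cfg["seed"])
    return SceneConfig(image_size=d["image_size"], seed=cfg["seed"],
                       background=d["background"],
                       occlusion_prob=d["occlusion_prob"])


def augment_config_from(cfg: dict):
    from .datapipe import AugmentConfig
    a = cfg["augment"]
    return AugmentConfig(
        crop_keep=tuple(a["crop_keep"]),
        rotation_deg=tuple(a["rotation_deg"]),
        enlarge_scale=tuple(a["enlarge_scale"]),
        exposure_gain=tuple(a["exposure_gain"]),
        noise_sigma=tuple(a["noise_sigma"]),
        variants_per_original=a["factor"] - 1,
        seed=cfg["seed"],
    )
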