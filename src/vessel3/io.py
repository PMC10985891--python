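"""Shared I/O and configuration glue.

On-disk formats: 8-bit grayscale PNG for images, indexed (palette) 8-bit
PNG for label masks so the labels 0-3 are stored bit-exactly, one JSON
file per dataset for boxes, a JSON manifest tying ids to files and split
assignments, and CSV/JSON metric reports.  "Standard normalization" of
input images is min-max scaling into [0, 1] by bit depth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .roi import LabeledBox

VALID_LABELS = {0, 1, 2, 3}
CLASS_NAMES = {1: "PA", 2: "Ao", 3: "SVC"}
CLASS_IDS = {v: k for k, v in CLASS_NAMES.items()}

# fixed palette: background dark, PA red, Ao green, SVC blue
_PALETTE = [0, 0, 0, 220, 60, 60, 60, 200, 60, 80, 80, 230] + [0] * (252 * 3)


class IllegalLabelError(ValueError):
    pass


def write_image(image: np.ndarray, path) -> None:
    """Save a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 1)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)


def read_image(path) -> np.ndarray:
    """Load an image and min-max normalize it into [0, 1] by bit depth."""
    with Image.open(path) as im:
        if im.mode in ("I;16", "I;16B", "I"):
            arr = np.asarray(im, dtype=np.float64)
            return arr / 65535.0
        arr = np.asarray(im.convert("L"), dtype=np.float64)
        return arr / 255.0


def write_mask(mask: np.ndarray, path) -> None:
    """Save a label mask as an indexed 8-bit PNG (labels stored exactly)."""
    mask = np.asarray(mask)
    _check_labels(mask)
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    im.putpalette(_PALETTE)
    im.save(path)


def read_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode != "P":
            raise IllegalLabelError(f"{path}: mask PNG must be indexed (mode P)")
        mask = np.asarray(im, dtype=np.uint8)
    _check_labels(mask)
    return mask


def _check_labels(mask) -> None:
    found = set(np.unique(mask).tolist())
    if not found <= VALID_LABELS:
        raise IllegalLabelError(
            f"illegal mask labels {sorted(found - VALID_LABELS)}; expected subset of {sorted(VALID_LABELS)}")


# ---------------------------------------------------------------------------
# boxes

def boxes_to_records(sample_id: str, boxes) -> list[dict]:
    return [{"sample_id": sample_id, "class": CLASS_NAMES[b.class_id],
             "x_min": b.x_min, "y_min": b.y_min,
             "x_max": b.x_max, "y_max": b.y_max,
             "confidence": b.confidence} for b in boxes]


def records_to_boxes(records) -> list[LabeledBox]:
    return [LabeledBox(class_id=CLASS_IDS[r["class"]],
                       x_min=r["x_min"], y_min=r["y_min"],
                       x_max=r["x_max"], y_max=r["y_max"],
                       confidence=r.get("confidence", 1.0)) for r in records]


def write_boxes(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def read_boxes(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# manifest / dataset

MANIFEST_VERSION = 1


@dataclass
class DatasetManifest:
    """Sample records {id, image, mask, boxes, split} with unique ids."""

    root: Path
    records: list = field(default_factory=list)
    version: int = MANIFEST_VERSION

    def __post_init__(self):
        self.root = Path(self.root)
        ids = [r["id"] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in manifest")
        for r in self.records:
            split = r.get("split", "unassigned")
            if split not in ("train", "val", "test", "unassigned"):
                raise ValueError(f"illegal split {split!r} for id {r['id']}")

    def ids(self):
        return [r["id"] for r in self.records]

    def record(self, sample_id):
        for r in self.records:
            if r["id"] == sample_id:
                return r
        raise KeyError(f"sample id {sample_id!r} not in manifest")

    def save(self, path=None) -> Path:
        path = Path(path) if path else self.root / "manifest.json"
        with open(path, "w") as fh:
            json.dump({"version": self.version, "records": self.records},
                      fh, indent=2)
        return path

    @classmethod
    def load(cls, root) -> "DatasetManifest":
        root = Path(root)
        with open(root / "manifest.json") as fh:
            data = json.load(fh)
        m = cls(root=root, records=data["records"], version=data["version"])
        for r in m.records:
            for key in ("image", "mask"):
                if not (root / r[key]).exists():
                    raise FileNotFoundError(f"missing file {r[key]} for id {r['id']}")
        return m


def write_dataset(samples, out_dir) -> DatasetManifest:
    """Write phantom samples as PNGs + boxes.json + manifest.json."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    records, box_records = [], []
    for i, s in enumerate(samples):
        sid = f"phantom_{i:04d}"
        write_image(s.image, out / "images" / f"{sid}.png")
        write_mask(s.mask, out / "masks" / f"{sid}.png")
        box_records.extend(boxes_to_records(sid, s.boxes))
        records.append({"id": sid, "image": f"images/{sid}.png",
                        "mask": f"masks/{sid}.png", "seed": s.seed_used,
                        "split": "unassigned"})
    write_boxes(box_records, out / "boxes.json")
    manifest = DatasetManifest(root=out, records=records)
    manifest.save()
    return manifest


def read_sample(manifest: DatasetManifest, sample_id):
    """(image in [0,1], mask, boxes) for one manifest record."""
    r = manifest.record(sample_id)
    image = read_image(manifest.root / r["image"])
    mask = read_mask(manifest.root / r["mask"])
    all_records = read_boxes(manifest.root / "boxes.json")
    boxes = records_to_boxes([b for b in all_records if b["sample_id"] == sample_id])
    return image, mask, boxes


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG = {
    "out_size": 256,            # network input side after crop/resize
    "margin": 5,                # ROI expansion in pixels
    "split": [7, 1, 2],         # train : val : test
    "epochs": 35,
    "lr": 1e-3,
    "final_lr": 1e-4,
    "final_phase_epochs": 10,
    "adam_eps": 1e-8,
    "batch_size": 8,
    "seed": 0,
    "threshold": 0.5,
    "network": {
        "width": 512,
        "branch_count": 4,
        "dilations": [1, 6, 12, 18],
        "decode_channels": 256,
        "head": "amff",
    },
    "augment": {
        "enabled": True,
        "flip_prob": 0.5,
        "max_rotation_deg": 15.0,
        "scale_range": [0.9, 1.1],
    },
    "phantom": {
        "image_size": 256,
        "pa_radius": [14.0, 20.0],
        "ao_radius": [11.0, 16.0],
        "svc_radius": [3.0, 5.0],
        "collinearity_deg": 12.0,
        "lumen_intensity": 0.15,
        "wall_intensity": 0.75,
        "background_intensity": 0.45,
        "speckle_shape": 4.0,
        "clutter_count": 3,
    },
    "loss": {
        "per_batch_weights": False,
    },
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path="") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            uval = user.get(key, {})
            if not isinstance(uval, dict):
                raise ConfigError(f"{path}{key}: expected a mapping")
            out[key] = _merge(dval, uval, path=f"{path}{key}.")
        else:
            out[key] = user.get(key, dval)
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(path + k for k in unknown)}")
    return out


def _validate_config(cfg: dict) -> None:
    if cfg["margin"] < 0:
        raise ConfigError("margin: must be >= 0")
    if cfg["epochs"] < 1:
        raise ConfigError("epochs: must be >= 1")
    if cfg["out_size"] % 8:
        raise ConfigError("out_size: must be divisible by 8")
    if len(cfg["split"]) != 3 or any(r <= 0 for r in cfg["split"]):
        raise ConfigError("split: need three positive ratios")
    if cfg["lr"] <= 0 or cfg["final_lr"] <= 0:
        raise ConfigError("learning rates must be positive")


def load_config(path=None) -> dict:
    """YAML config with defaults filled and unknown keys rejected."""
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
    cfg = _merge(DEFAULT_CONFIG, user)
    _validate_config(cfg)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
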