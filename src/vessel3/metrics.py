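"""Segmentation evaluation: per-class IoU, Dice and Hausdorff distance.

For each vessel class the predicted and reference masks are binarized
one-vs-rest and compared by

* ``IoU  = TP / (TP + FN + FP)``  (reported as a percentage),
* ``Dice = 2*TP / (2*TP + FN + FP)``  (percentage; Dice = 2*IoU/(1+IoU)),
* ``HD(A, B) = max(max_a min_b d(a,b), max_b min_a d(b,a))`` — the
  symmetric Hausdorff distance in pixels between the two boundary point
  sets, with Euclidean ``d``.

Boundaries are foreground pixels with at least one background 4-neighbor
(pixels on the image edge count as boundary).  A class absent from both
masks is skipped rather than scored perfect; a class absent from exactly
one mask scores Dice = IoU = 0 but has no defined HD.  Batch evaluation
averages per-image per-class values (macro average) and reports the
arithmetic mean over the three classes, mirroring the usual per-vessel
results-table layout.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

CLASS_NAMES = {1: "PA", 2: "Ao", 3: "SVC"}


class UndefinedMetricError(ValueError):
    """Metric undefined for this mask pair (e.g. both masks empty)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_mask, gt_mask, class_id: int) -> ConfusionCounts:
    """Pixel counts for the one-vs-rest binarization of ``class_id``."""
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    p = pred == class_id
    g = gt == class_id
    return ConfusionCounts(
        tp=int((p & g).sum()), fp=int((p & ~g).sum()),
        fn=int((~p & g).sum()), tn=int((~p & ~g).sum()))


def iou(counts: ConfusionCounts) -> float:
    """Intersection over union, in percent."""
    union = counts.tp + counts.fn + counts.fp
    if union == 0:
        raise UndefinedMetricError("IoU undefined: class absent in both masks")
    return 100.0 * counts.tp / union


def dice_score(counts: ConfusionCounts) -> float:
    """Dice coefficient, in percent."""
    denom = 2 * counts.tp + counts.fn + counts.fp
    if denom == 0:
        raise UndefinedMetricError("Dice undefined: class absent in both masks")
    return 100.0 * 2 * counts.tp / denom


def extract_boundary(binary_mask) -> np.ndarray:
    """Foreground pixels with >= 1 background 4-neighbor, as (K, 2) rows/cols.

    The image border is treated as background, so foreground touching the
    edge is boundary.
    """
    m = np.asarray(binary_mask) != 0
    if not m.any():
        raise UndefinedMetricError("boundary undefined for an empty mask")
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(m, structure=cross, border_value=0)
    rows, cols = np.nonzero(m & ~interior)
    return np.stack([rows, cols], axis=1)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets, in pixels."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise UndefinedMetricError("Hausdorff undefined for an empty point set")
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def hausdorff_masks(pred_binary, gt_binary) -> float:
    """HD between the boundaries of two binary masks."""
    return hausdorff(extract_boundary(pred_binary), extract_boundary(gt_binary))


@dataclass
class MetricsReport:
    """Per-class Dice/IoU/HD plus class means, in results-table layout.

    ``per_class[name]`` maps to ``{"dice", "iou", "hd", "n_overlap",
    "n_hd"}`` where the ``n_*`` entries count the images on which each
    quantity was defined; undefined entries are excluded from averages.
    """

    per_class: dict = field(default_factory=dict)
    mean: dict = field(default_factory=dict)
    n_images: int = 0

    def to_dict(self) -> dict:
        return {"per_class": self.per_class, "mean": self.mean,
                "n_images": self.n_images}

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(per_class=d["per_class"], mean=d["mean"],
                   n_images=d["n_images"])

    def to_rows(self):
        """Rows (label, dice, iou, hd) for PA, Ao, SVC, Mean."""
        rows = []
        for name in ("PA", "Ao", "SVC"):
            c = self.per_class[name]
            rows.append((name, c["dice"], c["iou"], c["hd"]))
        rows.append(("Mean", self.mean["dice"], self.mean["iou"], self.mean["hd"]))
        return rows


def _nanmean(values):
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def evaluate_batch(pred_masks, gt_masks, classes=(1, 2, 3)) -> MetricsReport:
    """Macro-averaged per-class metrics over aligned mask lists."""
    preds = [np.asarray(p) for p in pred_masks]
    gts = [np.asarray(g) for g in gt_masks]
    if len(preds) == 0 or len(preds) != len(gts):
        raise ValueError("need equal-length, non-empty mask lists")
    acc = {k: {"dice": [], "iou": [], "hd": []} for k in classes}
    for p, g in zip(preds, gts):
        for k in classes:
            c = confusion(p, g, k)
            try:
                acc[k]["dice"].append(dice_score(c))
                acc[k]["iou"].append(iou(c))
            except UndefinedMetricError:
                pass                      # absent in both: skip, do not inflate
            try:
                acc[k]["hd"].append(hausdorff_masks(p == k, g == k))
            except UndefinedMetricError:
                pass
    per_class = {}
    for k in classes:
        name = CLASS_NAMES.get(k, str(k))
        per_class[name] = {
            "dice": _nanmean(acc[k]["dice"]),
            "iou": _nanmean(acc[k]["iou"]),
            "hd": _nanmean(acc[k]["hd"]),
            "n_overlap": len(acc[k]["dice"]),
            "n_hd": len(acc[k]["hd"]),
        }
    mean = {key: _nanmean([per_class[n][key] for n in per_class])
            for key in ("dice", "iou", "hd")}
    return MetricsReport(per_class=per_class, mean=mean, n_images=len(preds))


def write_report(report: MetricsReport, path) -> tuple[str, str]:
    """Emit ``<path>.csv`` and ``<path>.json``; JSON round-trips exactly."""
    import os
    base, ext = os.path.splitext(str(path))
    if ext in (".csv", ".json"):
        path = base
    csv_path, json_path = f"{path}.csv", f"{path}.json"
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    with open(csv_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["Class", "Dice", "IoU", "HD"])
        for label, d, i, h in report.to_rows():
            wr.writerow([label, f"{d:.2f}", f"{i:.2f}", f"{h:.2f}"])
    return csv_path, json_path


def read_report(json_path) -> MetricsReport:
    with open(json_path) as fh:
        return MetricsReport.from_dict(json.load(fh))
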