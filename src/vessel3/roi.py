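"""ROI localization geometry: box selection, merging, cropping, unmapping.

Stage 1 of the two-stage pipeline finds the region of interest (ROI) that
contains all three vessels, either from per-class detector boxes (keep the
highest-confidence box per class, take the minimum enclosing rectangle,
expand by a margin) or from a coarse binary vessel mask (tight foreground
bounding box, expanded by the same margin).  The ROI is cropped from the
original image, resized to the segmentation network's input size, and the
predicted mask is mapped back to full resolution.

All coordinates are 0-based, half-open ``[min, max)``; ``x`` indexes
columns and ``y`` rows.  The detector is a pluggable callable
``image -> list[LabeledBox]``; :func:`oracle_detector` builds a
ground-truth-jitter stand-in used throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize


class NoDetectionsError(RuntimeError):
    """Stage-1 produced nothing to merge; caller should fall back to full-size."""


class NoForegroundError(NoDetectionsError):
    """Binary stage-1 mask contained no foreground pixels."""


@dataclass(frozen=True)
class LabeledBox:
    """A detector (or ground-truth) box for one vessel class.

    class_id: 1 = PA, 2 = Ao, 3 = SVC.  Half-open pixel coordinates.
    """

    class_id: int
    x_min: int
    y_min: int
    x_max: int
    y_max: int
    confidence: float = 1.0

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")

    @property
    def area(self) -> int:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True)
class RoiRect:
    """The merged crop rectangle, clamped to image bounds."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    source: str = "detector"   # or "binary_mask"

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"empty ROI {self}")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width)."""
        return (self.y_max - self.y_min, self.x_max - self.x_min)

    def contains_box(self, box: LabeledBox) -> bool:
        return (self.x_min <= box.x_min and box.x_max <= self.x_max
                and self.y_min <= box.y_min and box.y_max <= self.y_max)


@dataclass(frozen=True)
class CropTransform:
    """Records how a crop was taken and resized, to invert it later."""

    roi: RoiRect
    crop_size: tuple[int, int]   # (height, width) before resize
    out_size: tuple[int, int]    # (height, width) after resize

    @property
    def scale(self) -> tuple[float, float]:
        """(row scale, column scale): out / crop."""
        return (self.out_size[0] / self.crop_size[0],
                self.out_size[1] / self.crop_size[1])


@dataclass
class BoxSelection:
    """Best box per class plus which classes went undetected."""

    boxes: list[LabeledBox] = field(default_factory=list)
    missing_classes: tuple[int, ...] = ()

    def __iter__(self):
        return iter(self.boxes)

    def __len__(self):
        return len(self.boxes)


def select_best_per_class(detections: list[LabeledBox],
                          classes=(1, 2, 3)) -> BoxSelection:
    """Keep, for each class, the detection with the highest confidence.

    Ties are broken by larger area, then by first occurrence, so the result
    is deterministic for any input ordering.
    """
    best: dict[int, tuple] = {}
    for idx, b in enumerate(detections):
        key = (b.confidence, b.area, -idx)     # later occurrence loses ties
        if b.class_id not in best or key > best[b.class_id][0]:
            best[b.class_id] = (key, b)
    boxes = [best[k][1] for k in classes if k in best]
    missing = tuple(k for k in classes if k not in best)
    return BoxSelection(boxes=boxes, missing_classes=missing)


def merge_to_roi(boxes, margin: int = 5, image_size=(256, 256),
                 source: str = "detector") -> RoiRect:
    """Minimum rectangle enclosing all boxes, expanded by ``margin`` px.

    The expansion is applied on every side and then clamped to the image
    bounds.  An empty box list signals stage-1 failure.
    """
    boxes = list(boxes)
    if not boxes:
        raise NoDetectionsError("no boxes to merge; fall back to full-size segmentation")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    h, w = image_size
    return RoiRect(
        x_min=max(0, min(b.x_min for b in boxes) - margin),
        y_min=max(0, min(b.y_min for b in boxes) - margin),
        x_max=min(w, max(b.x_max for b in boxes) + margin),
        y_max=min(h, max(b.y_max for b in boxes) + margin),
        source=source,
    )


def roi_from_binary_mask(binary_mask: np.ndarray, margin: int = 5) -> RoiRect:
    """ROI from a coarse binary vessel mask (stage-1 segmentation strategy).

    Equivalent to the tight foreground bounding box expanded by ``margin``.
    """
    m = np.asarray(binary_mask) != 0
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise NoForegroundError("binary mask has no foreground; fall back to full-size")
    h, w = m.shape
    return RoiRect(
        x_min=max(0, int(cols.min()) - margin),
        y_min=max(0, int(rows.min()) - margin),
        x_max=min(w, int(cols.max()) + 1 + margin),
        y_max=min(h, int(rows.max()) + 1 + margin),
        source="binary_mask",
    )


def crop_resize(image: np.ndarray, roi: RoiRect,
                out_size=(256, 256)) -> tuple[np.ndarray, CropTransform]:
    """Crop the ROI and bilinearly resize it to ``out_size``."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if not (0 <= roi.x_min and roi.x_max <= w and 0 <= roi.y_min and roi.y_max <= h):
        raise ValueError(f"ROI {roi} outside image of shape {(h, w)}")
    ch, cw = roi.shape
    if ch <= 1 or cw <= 1:
        raise ValueError(f"degenerate ROI {roi}: sides must exceed 1 px")
    crop = image[roi.y_min:roi.y_max, roi.x_min:roi.x_max]
    if (ch, cw) == tuple(out_size):
        out = crop.copy()
    else:
        out = _sk_resize(crop, out_size, order=1, preserve_range=True,
                         anti_aliasing=False)
    t = CropTransform(roi=roi, crop_size=(ch, cw), out_size=tuple(out_size))
    return out, t


def uncrop_mask(mask_in_roi: np.ndarray, transform: CropTransform,
                original_size) -> np.ndarray:
    """Map a crop-resolution label mask back to the full image.

    Nearest-neighbor resize back to the crop size, pasted at the ROI
    position; everything outside the ROI is background.
    """
    mask_in_roi = np.asarray(mask_in_roi)
    if mask_in_roi.shape != tuple(transform.out_size):
        raise ValueError(
            f"mask shape {mask_in_roi.shape} != transform out_size {transform.out_size}")
    ch, cw = transform.crop_size
    if mask_in_roi.shape == (ch, cw):
        back = mask_in_roi
    else:
        back = _sk_resize(mask_in_roi.astype(float), (ch, cw), order=0,
                          preserve_range=True, anti_aliasing=False)
    full = np.zeros(tuple(original_size), dtype=mask_in_roi.dtype)
    roi = transform.roi
    full[roi.y_min:roi.y_max, roi.x_min:roi.x_max] = np.rint(back).astype(mask_in_roi.dtype)
    return full


def oracle_detector(gt_boxes: list[LabeledBox], jitter_px: int = 0,
                    drop_prob: float = 0.0, seed: int = 0,
                    image_size=(256, 256)) -> list[LabeledBox]:
    """Ground-truth-jitter stand-in for a trained detector.

    Each ground-truth box is independently dropped with ``drop_prob``;
    surviving boxes have every corner perturbed uniformly within
    ``±jitter_px`` (clamped to image bounds, kept non-degenerate) and get a
    confidence drawn from [0.5, 1].  Real detectors (e.g. a YOLO-family
    model) plug in through the same ``image -> list[LabeledBox]`` contract.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    out = []
    for b in gt_boxes:
        if rng.uniform() < drop_prob:
            continue
        if jitter_px > 0:
            j = rng.integers(-jitter_px, jitter_px + 1, size=4)
        else:
            j = np.zeros(4, dtype=int)
        x0 = int(np.clip(b.x_min + j[0], 0, w - 1))
        y0 = int(np.clip(b.y_min + j[1], 0, h - 1))
        x1 = int(np.clip(b.x_max + j[2], x0 + 1, w))
        y1 = int(np.clip(b.y_max + j[3], y0 + 1, h))
        if jitter_px == 0 and drop_prob == 0:
            conf = b.confidence          # identity contract: boxes pass through
        else:
            conf = float(rng.uniform(0.5, 1.0))
        out.append(LabeledBox(b.class_id, x0, y0, x1, y1, conf))
    return out


def make_oracle_detector(sample_boxes, jitter_px=0, drop_prob=0.0, seed=0,
                         image_size=(256, 256)):
    """Close over ground-truth boxes to satisfy the detector callable contract."""
    def detector(image):
        return oracle_detector(sample_boxes, jitter_px=jitter_px,
                               drop_prob=drop_prob, seed=seed,
                               image_size=image.shape if hasattr(image, "shape") else image_size)
    return detector
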