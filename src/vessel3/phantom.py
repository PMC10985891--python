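"""Synthetic three-vessel-view (3VV) ultrasound phantoms.

The three target structures mimic the cross-sections of the pulmonary
artery (PA), aorta (Ao) and superior vena cava (SVC) as they appear in the
fetal 3VV plane: three roughly circular dark lumens with brighter walls,
approximately collinear, with a large size disparity (the SVC is much
smaller than the two arteries).  Images are corrupted by multiplicative
gamma speckle and optionally cluttered with background arcs/ellipses so
that every downstream stage (detection, ROI merging, segmentation,
evaluation) can be exercised without clinical data.

Label convention for masks: 0 = background, 1 = PA, 2 = Ao, 3 = SVC.
Bounding boxes use 0-based half-open pixel coordinates (x = column,
y = row).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse, ellipse_perimeter

from .roi import LabeledBox

CLASS_NAMES = {1: "PA", 2: "Ao", 3: "SVC"}
CLASS_IDS = {v: k for k, v in CLASS_NAMES.items()}


class InfeasibleSpecError(RuntimeError):
    """Raised when vessels cannot be placed inside the image."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic 3VV phantom.

    Radii are ranges in pixels, ordered PA >= Ao > SVC; the SVC range must
    not exceed 40% of the PA range (the size disparity that makes the SVC
    hard to segment).  Intensities are grayscale means in [0, 1].
    ``speckle_shape`` is the shape parameter of unit-mean multiplicative
    gamma noise; ``None`` disables speckle.
    """

    image_size: tuple[int, int] = (256, 256)
    pa_radius: tuple[float, float] = (14.0, 20.0)
    ao_radius: tuple[float, float] = (11.0, 16.0)
    svc_radius: tuple[float, float] = (3.0, 5.0)
    collinearity_deg: float = 12.0
    lumen_intensity: float = 0.15
    wall_intensity: float = 0.75
    background_intensity: float = 0.45
    wall_thickness: float = 2.5
    speckle_shape: float | None = 4.0
    clutter_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        radii = (self.pa_radius, self.ao_radius, self.svc_radius)
        for lo, hi in radii:
            if not (0 < lo <= hi):
                raise ValueError(f"radius range must satisfy 0 < lo <= hi, got ({lo}, {hi})")
            if hi + self.wall_thickness + 2 > min(h, w) / 2:
                raise ValueError("radii too large for image (need >= 2-pixel margin)")
        if not (self.pa_radius[1] >= self.ao_radius[1] and self.ao_radius[0] > self.svc_radius[1]):
            raise ValueError("radius ranges must be ordered PA >= Ao > SVC")
        if self.svc_radius[1] > 0.4 * self.pa_radius[1]:
            raise ValueError("SVC radius range must be <= 40% of the PA range")
        for name in ("lumen_intensity", "wall_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive (or None to disable)")
        if self.clutter_count < 0:
            raise ValueError("clutter_count must be >= 0")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class PhantomSample:
    """One synthetic record: image, per-pixel mask, tight per-class boxes."""

    image: np.ndarray          # float in [0, 1], shape (H, W)
    mask: np.ndarray           # uint8 labels {0,1,2,3}, shape (H, W)
    boxes: list[LabeledBox] = field(default_factory=list)
    seed_used: int = 0


def apply_speckle(image: np.ndarray, shape: float, seed: int) -> np.ndarray:
    """Multiply by unit-mean gamma noise (the standard speckle surrogate).

    Smaller ``shape`` means grainier images; the output is clipped back to
    [0, 1].  Deterministic for a fixed seed.
    """
    image = np.asarray(image, dtype=float)
    if shape is None or shape <= 0:
        raise ValueError(f"speckle shape parameter must be positive, got {shape}")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    noise = rng.gamma(shape, 1.0 / shape, size=image.shape)
    return np.clip(image * noise, 0.0, 1.0)


def mask_to_instance_boxes(mask: np.ndarray) -> list[LabeledBox]:
    """Tight axis-aligned bounding box of each present class (1..3).

    Boxes are half-open; absent classes yield no box; confidence is 1.0.
    """
    mask = np.asarray(mask)
    labels = np.unique(mask)
    if not set(labels.tolist()) <= {0, 1, 2, 3}:
        raise ValueError(f"mask labels must be within {{0,1,2,3}}, found {sorted(labels.tolist())}")
    boxes = []
    for k in (1, 2, 3):
        rows, cols = np.nonzero(mask == k)
        if rows.size == 0:
            continue
        boxes.append(LabeledBox(
            class_id=k,
            x_min=int(cols.min()), y_min=int(rows.min()),
            x_max=int(cols.max()) + 1, y_max=int(rows.max()) + 1,
            confidence=1.0,
        ))
    return boxes


def _draw_vessel(mask, image, label, cy, cx, radius, rng, spec):
    """Filled near-circular ellipse lumen with a brighter wall ring."""
    h, w = mask.shape
    # eccentricity <= 1.3, area preserved around radius**2
    ecc = rng.uniform(1.0, 1.3)
    a, b = radius * np.sqrt(ecc), radius / np.sqrt(ecc)
    theta = rng.uniform(0, np.pi)
    wall = spec.wall_thickness
    rr, cc = ellipse(cy, cx, a + wall, b + wall, shape=(h, w), rotation=theta)
    image[rr, cc] = spec.wall_intensity
    rr, cc = ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
    image[rr, cc] = spec.lumen_intensity
    mask[rr, cc] = label
    return rr, cc


def _place_centers(spec: PhantomSpec, radii, rng):
    """Centers for PA, Ao, SVC approximately on a line, inside the image."""
    h, w = spec.image_size
    margin = spec.wall_thickness + 2.0
    tol = np.deg2rad(spec.collinearity_deg)
    for _ in range(200):
        phi = rng.uniform(0, np.pi)
        d = np.array([np.cos(phi), np.sin(phi)])       # (dy, dx)
        n = np.array([-d[1], d[0]])
        gaps = rng.uniform(4.0, 10.0, size=2)
        # arc-length positions of the three centers along the line
        s = [0.0]
        s.append(s[-1] + radii[0] + radii[1] + gaps[0])
        s.append(s[-1] + radii[1] + radii[2] + gaps[1])
        start = np.array([rng.uniform(margin + radii[0], h - margin - radii[0]),
                          rng.uniform(margin + radii[0], w - margin - radii[0])])
        centers = []
        ok = True
        for i, si in enumerate(s):
            offset = np.tan(tol) * si * rng.uniform(-1, 1) if si > 0 else 0.0
            c = start + si * d + offset * n
            lim = margin + radii[i]
            if not (lim <= c[0] <= h - lim and lim <= c[1] <= w - lim):
                ok = False
                break
            centers.append(c)
        if not ok:
            continue
        # pairwise separation incl. walls
        sep = True
        for i in range(3):
            for j in range(i + 1, 3):
                dist = np.linalg.norm(centers[i] - centers[j])
                if dist < radii[i] + radii[j] + 2 * spec.wall_thickness + 2:
                    sep = False
        if sep:
            return centers
    raise InfeasibleSpecError(
        f"could not place three vessels with radii {radii} in image {spec.image_size}")


def _draw_clutter(image, mask, rng, spec):
    """Background distractors: arcs and ellipse outlines, never labeled."""
    h, w = image.shape
    for _ in range(spec.clutter_count):
        cy, cx = rng.integers(5, h - 5), rng.integers(5, w - 5)
        ry, rx = rng.integers(4, max(5, h // 5)), rng.integers(4, max(5, w // 5))
        orient = rng.uniform(0, np.pi)
        val = rng.uniform(0.3, 0.9)
        rr, cc = ellipse_perimeter(int(cy), int(cx), int(ry), int(rx),
                                   orientation=float(orient), shape=(h, w))
        keep = mask[rr, cc] == 0
        image[rr[keep], cc[keep]] = val


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomSample:
    """Generate one phantom; deterministic for a fixed (spec, seed)."""
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    radii = [rng.uniform(*spec.pa_radius),
             rng.uniform(*spec.ao_radius),
             rng.uniform(*spec.svc_radius)]
    centers = _place_centers(spec, radii, rng)

    image = np.full((h, w), spec.background_intensity, dtype=float)
    mask = np.zeros((h, w), dtype=np.uint8)
    _draw_clutter(image, mask, rng, spec)
    for label, c, r in zip((1, 2, 3), centers, radii):
        _draw_vessel(mask, image, label, c[0], c[1], r, rng, spec)
        if not (mask == label).any():
            raise InfeasibleSpecError(f"class {label} rendered empty (radius {r})")

    if spec.speckle_shape is not None:
        image = apply_speckle(image, spec.speckle_shape,
                              int(rng.integers(0, 2**31 - 1)))
    boxes = mask_to_instance_boxes(mask)
    return PhantomSample(image=image, mask=mask, boxes=boxes, seed_used=seed)


def sample_seeds(master_seed: int, n: int) -> list[int]:
    """Per-sample seeds derived deterministically from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def make_dataset(spec: PhantomSpec, n: int, seed: int,
                 out_dir=None) -> list[PhantomSample]:
    """Generate ``n`` samples; optionally write them to ``out_dir``.

    On-disk layout (when ``out_dir`` is given): ``images/<id>.png``,
    ``masks/<id>.png`` (indexed), one ``boxes.json``, one
    ``manifest.json`` — see :mod:`vessel3.io`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = [generate_phantom(spec, s) for s in sample_seeds(seed, n)]
    if out_dir is not None:
        from .io import write_dataset
        write_dataset(samples, out_dir)
    return samples
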