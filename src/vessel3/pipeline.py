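"""Training and inference orchestration for the two-stage pipeline.

Covers dataset splitting (7:1:2 by default), paired geometric
augmentation, the step learning-rate schedule (1e-3 dropping to 1e-4 for
the final 10 of 35 epochs, Adam with eps 1e-8), stage-2 training on
ROI crops, full two-stage inference (detector -> best box per class ->
merged ROI -> crop -> segment -> uncrop, with a full-size fallback when
the detector returns nothing), and the AMFF-vs-ASPP ablation harness.

The two stages are deliberately trained independently: stage-2 training
crops are built from ground-truth boxes (optionally jittered by the
oracle detector) so the segmentation model never depends on a particular
detector's weights.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, warp

from . import losses as L
from . import metrics as M
from .network import NetworkConfig, NetworkOutput, VesselSegNet, sigmoid
from .nn import Adam
from .roi import (NoDetectionsError, RoiRect, crop_resize, merge_to_roi,
                  oracle_detector, select_best_per_class, uncrop_mask)


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test ratios (default 7:1:2) and the shuffle seed."""

    ratios: tuple = (7, 1, 2)
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("need three positive ratios")


@dataclass(frozen=True)
class AugmentSettings:
    """Paired geometric augmentation: flip, rotation, isotropic scale."""

    enabled: bool = True
    flip_prob: float = 0.5
    max_rotation_deg: float = 15.0
    scale_range: tuple = (0.9, 1.1)


@dataclass(frozen=True)
class TrainConfig:
    """Stage-2 training schedule; defaults follow the reference protocol.

    35 epochs of Adam at learning rate 1e-3, stepping to 1e-4 for the
    final 10 epochs; 1e-8 is Adam's numerical-stability epsilon.  The
    network config defaults to the full-size architecture — tests and
    desk-scale runs pass a narrower one.
    """

    epochs: int = 35
    lr: float = 1e-3
    final_lr: float = 1e-4
    final_phase_epochs: int = 10
    adam_eps: float = 1e-8
    batch_size: int = 8
    seed: int = 0
    out_size: tuple = (256, 256)
    margin: int = 5
    threshold: float = 0.5
    augment: AugmentSettings = field(default_factory=AugmentSettings)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.lr <= 0 or self.final_lr <= 0:
            raise ValueError("epochs must be >= 1 and learning rates positive")

    def replace(self, **kw) -> "TrainConfig":
        return dataclasses.replace(self, **kw)


def split_dataset(sample_ids, spec: SplitSpec):
    """Shuffle by seed, then partition by ratios with largest-remainder rounding."""
    ids = list(sample_ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    total = sum(spec.ratios)
    exact = [n * r / total for r in spec.ratios]
    sizes = [int(np.floor(e)) for e in exact]
    rem = n - sum(sizes)
    # assign remainders to the largest fractional parts (ties: train, val, test)
    frac_order = sorted(range(3), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in frac_order[:rem]:
        sizes[i] += 1
    if any(s == 0 for s in sizes):
        raise ValueError(f"split sizes {sizes} include an empty split for n={n}")
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]


def augment_pair(image, mask, settings: AugmentSettings, seed: int):
    """Apply one random flip/rotation/scale identically to image and mask.

    The mask is warped with nearest-neighbor interpolation so no new
    labels can appear.  Deterministic per seed; identity parameters give
    back exact copies.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    rng = np.random.default_rng(seed)
    flip = settings.enabled and rng.uniform() < settings.flip_prob
    angle = rng.uniform(-settings.max_rotation_deg, settings.max_rotation_deg) \
        if settings.enabled else 0.0
    scale = rng.uniform(*settings.scale_range) if settings.enabled else 1.0
    if flip:
        image, mask = image[:, ::-1].copy(), mask[:, ::-1].copy()
    if abs(angle) < 1e-12 and abs(scale - 1.0) < 1e-12:
        return image.copy(), mask.copy()
    h, w = image.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t = (AffineTransform(translation=center)
         + AffineTransform(rotation=np.deg2rad(angle), scale=(scale, scale))
         + AffineTransform(translation=-center))
    img_out = warp(image, t, order=1, mode="constant", cval=float(image.mean()),
                   preserve_range=True)
    mask_out = warp(mask.astype(float), t, order=0, mode="constant", cval=0.0,
                    preserve_range=True)
    return img_out, np.rint(mask_out).astype(mask.dtype)


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Step schedule: initial LR, then the final LR for the last phase."""
    if not (0 <= epoch < config.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    boundary = config.epochs - config.final_phase_epochs
    return config.lr if epoch < boundary else config.final_lr


# ---------------------------------------------------------------------------
# stage-2 data preparation

def build_crop_pairs(samples, margin=5, out_size=(64, 64), jitter_px=0,
                     seed=0):
    """(cropped image, cropped mask) pairs from ground-truth boxes.

    With ``jitter_px > 0`` boxes pass through the oracle detector first,
    emulating imperfect stage-1 localization during training.
    """
    pairs = []
    for i, s in enumerate(samples):
        boxes = s.boxes
        if jitter_px:
            boxes = oracle_detector(boxes, jitter_px=jitter_px, seed=seed + i,
                                    image_size=s.image.shape)
        roi = merge_to_roi(boxes, margin=margin, image_size=s.image.shape)
        img, t = crop_resize(s.image, roi, out_size=out_size)
        msk_crop = s.mask[roi.y_min:roi.y_max, roi.x_min:roi.x_max]
        from skimage.transform import resize as _rs
        msk = np.rint(_rs(msk_crop.astype(float), out_size, order=0,
                          preserve_range=True, anti_aliasing=False)).astype(np.uint8)
        pairs.append((img, msk))
    return pairs


def build_fullsize_pairs(samples, out_size=(64, 64)):
    """Whole-image pairs resized to the network input (one-stage baseline)."""
    full = []
    for s in samples:
        h, w = s.image.shape
        roi = RoiRect(0, 0, w, h)
        img, _ = crop_resize(s.image, roi, out_size=out_size)
        from skimage.transform import resize as _rs
        msk = np.rint(_rs(s.mask.astype(float), out_size, order=0,
                          preserve_range=True, anti_aliasing=False)).astype(np.uint8)
        full.append((img, msk))
    return full


def _mean_dice(pred_masks, gt_masks, classes=(1, 2, 3)) -> float:
    vals = []
    for k in classes:
        per = []
        for p, g in zip(pred_masks, gt_masks):
            c = M.confusion(p, g, k)
            try:
                per.append(M.dice_score(c) / 100.0)
            except M.UndefinedMetricError:
                pass
        if per:
            vals.append(np.mean(per))
    return float(np.mean(vals)) if vals else float("nan")


@dataclass
class TrainResult:
    model: VesselSegNet
    log: list                      # per-epoch dicts
    best_state: dict
    best_val_dice: float
    class_weights: L.ClassWeights
    initial_loss: float = float("nan")   # loss of the untrained model


def train_stage2(train_pairs, val_pairs, config: TrainConfig,
                 head: str | None = None, verbose: bool = False) -> TrainResult:
    """Minimize the compound loss on crop pairs with the configured schedule.

    Fully seeded: weight init, batch order and augmentation all derive
    from ``config.seed``.  Logs train loss, val loss and val mean Dice per
    epoch and keeps the best-val-Dice weights.
    """
    net_cfg = config.network if head is None else \
        dataclasses.replace(config.network, head=head)
    net_cfg = dataclasses.replace(net_cfg, seed=config.seed)
    model = VesselSegNet(net_cfg)
    weights = L.compute_class_weights([m for _, m in train_pairs])
    opt = Adam(model.parameters(), lr=config.lr, eps=config.adam_eps)
    order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 977]))
    n = len(train_pairs)
    initial_loss = _dataset_loss(model, train_pairs, weights, config.batch_size)
    log = []
    best_state, best_val = model.state_dict(), -1.0
    for epoch in range(config.epochs):
        opt.lr = lr_at_epoch(epoch, config)
        model.train(True)
        perm = order_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            imgs, masks = [], []
            for j in idx:
                img, msk = train_pairs[j]
                if config.augment.enabled:
                    aug_seed = int(np.random.SeedSequence(
                        [config.seed, epoch, int(j)]).generate_state(1)[0] % (2**31 - 1))
                    img, msk = augment_pair(img, msk, config.augment, aug_seed)
                imgs.append(img)
                masks.append(msk)
            x = np.asarray(imgs, dtype=np.float32)[:, None]
            g = np.stack([L.mask_to_channels(m) for m in masks]).astype(np.float32)
            logits = model.forward(x)
            p = sigmoid(logits)
            value, dp = L.total_loss(p, g, weights, grad=True)
            if not np.isfinite(value.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {value}")
            dz = (dp * p * (1.0 - p)).astype(np.float32)
            model.zero_grad()
            model.backward(dz)
            opt.step()
            epoch_loss += value.total
            n_batches += 1
        entry = {"epoch": epoch, "lr": opt.lr,
                 "train_loss": epoch_loss / max(n_batches, 1)}
        if val_pairs:
            val_loss, val_dice = _validate(model, val_pairs, weights, config)
            entry.update(val_loss=val_loss, val_dice=val_dice)
            if val_dice > best_val:
                best_val, best_state = val_dice, model.state_dict()
        log.append(entry)
        if verbose:
            print("  " + "  ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                                   for k, v in entry.items()))
    if not val_pairs:
        best_state, best_val = model.state_dict(), float("nan")
    return TrainResult(model=model, log=log, best_state=best_state,
                       best_val_dice=best_val, class_weights=weights,
                       initial_loss=initial_loss)


def _dataset_loss(model, pairs, weights, batch_size):
    """Compound loss over a dataset without updating parameters.

    Uses train-mode (batch) normalization statistics, so it is comparable
    with the logged per-epoch training losses.
    """
    model.train(True)
    total, nb = 0.0, 0
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        x = np.asarray([im for im, _ in chunk], dtype=np.float32)[:, None]
        g = np.stack([L.mask_to_channels(m) for _, m in chunk]).astype(np.float32)
        p = sigmoid(model.forward(x))
        total += L.total_loss(p, g, weights).total
        nb += 1
    return total / max(nb, 1)


def _validate(model, val_pairs, weights, config):
    model.eval()
    x = np.asarray([im for im, _ in val_pairs], dtype=np.float32)[:, None]
    g = np.stack([L.mask_to_channels(m) for _, m in val_pairs]).astype(np.float32)
    logits = model.forward(x)
    p = sigmoid(logits)
    value = L.total_loss(p, g, weights)
    out = NetworkOutput(logits=logits, probabilities=p)
    preds = out.masks(threshold=config.threshold)
    dice = _mean_dice(list(preds), [m for _, m in val_pairs])
    model.train(True)
    return value.total, dice


# ---------------------------------------------------------------------------
# inference

def segment_full_size(image, model: VesselSegNet, out_size=(256, 256),
                      threshold=0.5) -> np.ndarray:
    """One-stage inference: resize whole image, segment, map back."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    roi = RoiRect(0, 0, w, h)
    img, t = crop_resize(image, roi, out_size=out_size)
    out = model.predict(img[None, None].astype(np.float32))
    mask = out.masks(threshold=threshold)[0]
    return uncrop_mask(mask, t, (h, w))


def run_two_stage(image, detector, model: VesselSegNet, margin: int = 5,
                  out_size=(256, 256), threshold: float = 0.5) -> np.ndarray:
    """Detector -> best-per-class -> merged ROI -> crop -> segment -> uncrop.

    Falls back to full-size segmentation when the detector returns no
    boxes (the documented stage-1 failure mode).  Output mask always has
    the input image's size.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    sel = select_best_per_class(detector(image))
    try:
        roi = merge_to_roi(sel.boxes, margin=margin, image_size=(h, w))
    except NoDetectionsError:
        return segment_full_size(image, model, out_size=out_size,
                                 threshold=threshold)
    img, t = crop_resize(image, roi, out_size=out_size)
    out = model.predict(img[None, None].astype(np.float32))
    mask = out.masks(threshold=threshold)[0]
    return uncrop_mask(mask, t, (h, w))


# ---------------------------------------------------------------------------
# ablation harness

@dataclass
class AblationReport:
    """Side-by-side AMFF vs ASPP results over several seeds."""

    runs: list                    # per-seed dicts with both reports + deltas
    summary: dict                 # per-class mean/std of Dice deltas

    def to_dict(self):
        return {"runs": self.runs, "summary": self.summary}


def ablation_run(samples, config: TrainConfig, seeds=(0, 1, 2),
                 verbose: bool = False) -> AblationReport:
    """Train AMFF-head and ASPP-head models on identical splits and seeds.

    For each seed the same crop pairs and the same split feed both heads;
    both models are evaluated with :func:`vessel3.metrics.evaluate_batch`
    on the identical test crops.  The report carries per-class Dice deltas
    (AMFF - ASPP) and their mean/spread over seeds; the sign of the delta
    is an experimental outcome, not a built-in assumption.
    """
    ids = list(range(len(samples)))
    runs = []
    deltas = {name: [] for name in ("PA", "Ao", "SVC")}
    for seed in seeds:
        tr, va, te = split_dataset(ids, SplitSpec(seed=seed))
        pairs = build_crop_pairs(samples, margin=config.margin,
                                 out_size=config.out_size)
        train_pairs = [pairs[i] for i in tr]
        val_pairs = [pairs[i] for i in va]
        test_pairs = [pairs[i] for i in te]
        cfg = config.replace(seed=seed)
        run = {"seed": seed, "test_ids": list(te)}
        reports = {}
        for head in ("amff", "aspp"):
            result = train_stage2(train_pairs, val_pairs, cfg, head=head,
                                  verbose=verbose)
            result.model.load_state_dict(result.best_state)
            result.model.eval()
            x = np.asarray([im for im, _ in test_pairs],
                           dtype=np.float32)[:, None]
            out = result.model.predict(x)
            preds = list(out.masks(threshold=cfg.threshold))
            report = M.evaluate_batch(preds, [m for _, m in test_pairs])
            reports[head] = report
            run[head] = report.to_dict()
        for name in deltas:
            d = reports["amff"].per_class[name]["dice"] \
                - reports["aspp"].per_class[name]["dice"]
            deltas[name].append(d)
        run["delta_dice"] = {name: deltas[name][-1] for name in deltas}
        runs.append(run)
    summary = {name: {"mean": float(np.mean(v)), "std": float(np.std(v))}
               for name, v in deltas.items()}
    summary["mean_overall"] = float(np.mean([np.mean(v) for v in deltas.values()]))
    return AblationReport(runs=runs, summary=summary)
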