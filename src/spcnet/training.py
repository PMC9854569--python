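"""Losses, augmentation, histogram equalization, and the training loop.

The total objective is ``alpha * L_BCE + beta * L_WMAE`` with defaults
``alpha=0.5, beta=1``: binary cross-entropy on the object-probability head and
a mean absolute error on the radial-distance head, weighted per pixel by the
ground-truth object probability so pixels near each cell core count more.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from spcnet import nn
from spcnet.codec import encode_targets
from spcnet.network import NetworkConfig, SPCNet

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "bce_loss",
    "wmae_loss",
    "total_loss",
    "augment",
    "equalize_histogram",
    "train",
]

_EPS = 1e-7


@dataclass
class AugmentConfig:
    """Probabilities and magnitudes for the six augmentation transforms."""

    p_flip: float = 0.5
    p_rotate: float = 0.5
    rotate_deg: float = 90.0
    p_scale: float = 0.5
    scale_range: tuple[float, float] = (0.8, 1.2)
    p_translate: float = 0.5
    translate_frac: float = 0.1
    p_crop: float = 0.3
    crop_frac: float = 0.8
    p_elastic: float = 0.3
    elastic_alpha: float = 8.0
    elastic_sigma: float = 6.0


@dataclass
class TrainConfig:
    alpha: float = 0.5
    beta: float = 1.0
    learning_rate: float = 1e-3
    momentum: float = 0.99
    weight_decay: float = 1e-8
    batch_size: int = 12
    epochs: int = 650
    split_ratio: float = 0.8
    seed: int = 0
    normalize_by: str = "all_pixels"  # or "foreground_pixels"
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    equalize: bool = True
    log_csv: str | None = None
    checkpoint_dir: str | None = None
    checkpoint_every: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.normalize_by not in ("all_pixels", "foreground_pixels"):
            raise ValueError(f"unknown normalize_by: {self.normalize_by!r}")


# --------------------------------------------------------------------------- #
# losses (plain-array forms; the training loop rebuilds them as graph ops)


def _pixel_count(prob_true: np.ndarray, normalize_by: str) -> float:
    if normalize_by == "foreground_pixels":
        return float(max(np.count_nonzero(prob_true > 0), 1))
    return float(prob_true.size)


def bce_loss(prob_pred: np.ndarray, prob_true: np.ndarray) -> float:
    """Mean two-term binary cross-entropy with soft targets.

    ``-(1/N) sum_i [y_i log x_i + (1 - y_i) log(1 - x_i)]`` over all N pixels,
    predictions clamped to ``[1e-7, 1 - 1e-7]``.
    """
    x = np.asarray(prob_pred, dtype=np.float64)
    y = np.asarray(prob_true, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    x = np.clip(x, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(x) + (1.0 - y) * np.log(1.0 - x)))


def wmae_loss(
    dist_pred: np.ndarray,
    dist_true: np.ndarray,
    prob_true: np.ndarray,
    normalize_by: str = "all_pixels",
) -> float:
    """Probability-weighted mean absolute radial-distance error.

    ``(1/N) sum_i y_i sum_j |t_ij - p_ij|`` with the ground-truth probability
    ``y_i`` weighting each pixel's sum over the ray channels; background
    pixels (y=0) contribute nothing.
    """
    p = np.asarray(dist_pred, dtype=np.float64)
    t = np.asarray(dist_true, dtype=np.float64)
    y = np.asarray(prob_true, dtype=np.float64)
    if p.shape != t.shape or p.shape[:-1] != y.shape:
        raise ValueError(f"shape mismatch: pred {p.shape}, true {t.shape}, prob {y.shape}")
    per_pixel = np.abs(t - p).sum(axis=-1) * y
    return float(per_pixel.sum() / _pixel_count(y, normalize_by))


def total_loss(
    prob_pred: np.ndarray,
    prob_true: np.ndarray,
    dist_pred: np.ndarray,
    dist_true: np.ndarray,
    alpha: float = 0.5,
    beta: float = 1.0,
    normalize_by: str = "all_pixels",
) -> float:
    """``alpha * BCE + beta * WMAE``."""
    return alpha * bce_loss(prob_pred, prob_true) + beta * wmae_loss(
        dist_pred, dist_true, prob_true, normalize_by
    )


def _graph_loss(
    prob: nn.Tensor,
    dist: nn.Tensor,
    prob_true: np.ndarray,
    dist_true: np.ndarray,
    cfg: TrainConfig,
) -> nn.Tensor:
    """Differentiable total loss on an NCHW batch (targets as constants)."""
    dtype = prob.data.dtype
    y = nn.Tensor(prob_true.astype(dtype))  # (N, 1, H, W)
    t = nn.Tensor(dist_true.astype(dtype))  # (N, M, H, W)
    n_img_pixels = prob_true.shape[0] * prob_true.shape[2] * prob_true.shape[3]
    x = nn.clip(prob, _EPS, 1.0 - _EPS)
    bce = -1.0 * nn.mean(y * nn.log(x) + (1.0 - y) * nn.log(1.0 - x))
    if cfg.normalize_by == "foreground_pixels":
        denom = float(max(np.count_nonzero(prob_true > 0), 1))
    else:
        denom = float(n_img_pixels)
    wmae = (1.0 / denom) * nn.sum_(y * nn.sum_(nn.abs_(dist - t), axis=1, keepdims=True))
    return cfg.alpha * bce + cfg.beta * wmae


# --------------------------------------------------------------------------- #
# data transforms


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Global histogram equalization over the image's gray-level CDF.

    Level v maps to ``cdf(v) * max_level`` where ``cdf`` is the inclusive
    fraction of pixels at or below v and ``max_level`` is the dtype maximum for
    integer images (the input maximum for float images). Integer input keeps
    its dtype; float input returns float.
    """
    image = np.asarray(image)
    levels, inverse, counts = np.unique(image, return_inverse=True, return_counts=True)
    cdf = np.cumsum(counts) / image.size
    if np.issubdtype(image.dtype, np.integer):
        max_level = float(np.iinfo(image.dtype).max)
        out = np.rint(cdf[inverse] * max_level).reshape(image.shape)
        return out.astype(image.dtype)
    max_level = float(image.max()) if image.size else 0.0
    return (cdf[inverse] * max_level).reshape(image.shape).astype(np.float64)


def _affine_pair(image, labels, matrix, offset):
    img_out = ndimage.affine_transform(image.astype(np.float64), matrix, offset=offset, order=1, mode="constant", cval=float(image.min()))
    lbl_out = ndimage.affine_transform(labels, matrix, offset=offset, order=0, mode="constant", cval=0, output=labels.dtype)
    return img_out, lbl_out


def augment(
    image: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly composed scale / elastic / rotation / translation / crop / flip.

    Geometric transforms hit the image bilinearly and the label map with
    nearest-neighbor sampling, so instance ids survive unchanged; the output
    size always equals the input size.
    """
    cfg = config or AugmentConfig()
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError("image and labels must be aligned")
    h, w = image.shape
    img, lbl = image.astype(np.float64), labels

    # flips (cheap; applied first)
    if rng.random() < cfg.p_flip:
        img, lbl = img[:, ::-1], lbl[:, ::-1]
    if rng.random() < cfg.p_flip:
        img, lbl = img[::-1, :], lbl[::-1, :]

    # one combined affine: rotation + isotropic scale + translation about center
    angle = np.deg2rad(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg)) if rng.random() < cfg.p_rotate else 0.0
    scale = rng.uniform(*cfg.scale_range) if rng.random() < cfg.p_scale else 1.0
    if rng.random() < cfg.p_translate:
        t_r = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * h
        t_c = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * w
    else:
        t_r = t_c = 0.0
    if angle != 0.0 or scale != 1.0 or t_r or t_c:
        c, s = np.cos(angle), np.sin(angle)
        inv = np.array([[c, -s], [s, c]]) / scale  # output->input map
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = center - inv @ (center + np.array([t_r, t_c]))
        img, lbl = _affine_pair(img, np.ascontiguousarray(lbl), inv, offset)

    # elastic deformation
    if rng.random() < cfg.p_elastic:
        dr = ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.elastic_sigma) * cfg.elastic_alpha
        dc = ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.elastic_sigma) * cfg.elastic_alpha
        rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
        coords = np.stack([rr + dr, cc + dc])
        img = ndimage.map_coordinates(img, coords, order=1, mode="reflect")
        lbl = ndimage.map_coordinates(lbl, coords, order=0, mode="constant", cval=0)

    # random crop, resized back to the input size
    if rng.random() < cfg.p_crop:
        frac = rng.uniform(cfg.crop_frac, 1.0)
        ch_, cw_ = max(int(round(h * frac)), 8), max(int(round(w * frac)), 8)
        r0 = int(rng.integers(0, h - ch_ + 1))
        c0 = int(rng.integers(0, w - cw_ + 1))
        img_c = img[r0 : r0 + ch_, c0 : c0 + cw_]
        lbl_c = lbl[r0 : r0 + ch_, c0 : c0 + cw_]
        img = nn.resize_bilinear(img_c.astype(np.float64), (h, w))
        rr = np.clip(np.rint(np.arange(h) * ch_ / h - 0.5 + ch_ / (2 * h)), 0, ch_ - 1).astype(int)
        cc = np.clip(np.rint(np.arange(w) * cw_ / w - 0.5 + cw_ / (2 * w)), 0, cw_ - 1).astype(int)
        lbl = lbl_c[np.ix_(rr, cc)]

    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        img = np.clip(np.rint(img), info.min, info.max).astype(image.dtype)
    return img, np.ascontiguousarray(lbl)


# --------------------------------------------------------------------------- #
# training loop


def _prepare_sample(image, labels, n_rays, equalize):
    img = equalize_histogram(image) if equalize else np.asarray(image)
    img = img.astype(np.float32)
    if img.max() > 1.5:
        img = img / 255.0
    prob, dist = encode_targets(labels, n_rays)
    return img, prob.astype(np.float32), dist.astype(np.float32)


def train(
    dataset,
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    model: SPCNet | None = None,
    progress: bool = False,
) -> tuple[SPCNet, list[float]]:
    """Optimize a model on (image, label-map) pairs; returns (model, history).

    ``history`` holds the mean total loss of each epoch. Fully reproducible
    from ``train_config.seed`` on fixed hardware; with ``epochs=0`` the initial
    weights and an empty history are returned. When augmentation is disabled
    the (deterministic) targets are encoded once and cached across epochs.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    net_config = net_config or NetworkConfig()
    cfg = train_config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = SPCNet(net_config, seed=cfg.seed)
    optimizer = nn.SGD(model.store, lr=cfg.learning_rate, momentum=cfg.momentum,
                       weight_decay=cfg.weight_decay)

    cache = None
    if cfg.augment is None:
        cache = [_prepare_sample(img, lbl, net_config.n_rays, cfg.equalize) for img, lbl in dataset]

    history: list[float] = []
    log_rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(dataset), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            imgs, probs, dists = [], [], []
            for i in idx:
                if cache is not None:
                    img, prob, dist = cache[i]
                else:
                    image, labels = dataset[i]
                    image, labels = augment(image, labels, rng, cfg.augment)
                    img, prob, dist = _prepare_sample(image, labels, net_config.n_rays, cfg.equalize)
                imgs.append(img)
                probs.append(prob)
                dists.append(dist)
            x = np.stack(imgs)[:, None]  # (B, 1, H, W)
            y = np.stack(probs)[:, None]
            t = np.stack(dists).transpose(0, 3, 1, 2)  # (B, M, H, W)
            prob_pred, dist_pred = model.forward(x)
            loss = _graph_loss(prob_pred, dist_pred, y, t, cfg)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        log_rows.append((epoch, history[-1]))
        if progress:
            print(f"epoch {epoch + 1}/{cfg.epochs}  loss {history[-1]:.4f}", flush=True)
        if cfg.checkpoint_dir and cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            model.save(f"{cfg.checkpoint_dir}/checkpoint_ep{epoch + 1:04d}.npz")

    if cfg.log_csv:
        with open(cfg.log_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "mean_loss"])
            writer.writerows(log_rows)
    return model, history


def split_dataset(dataset, split_ratio: float = 0.8, seed: int = 0):
    """Shuffled train/test split at the configured ratio."""
    dataset = list(dataset)
    order = np.random.default_rng(seed).permutation(len(dataset))
    n_train = int(round(len(dataset) * split_ratio))
    return [dataset[i] for i in order[:n_train]], [dataset[i] for i in order[n_train:]]
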