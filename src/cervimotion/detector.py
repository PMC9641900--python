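"""Heatmap-regression landmark detector (desk-scale, CPU).

The detector regresses one Gaussian-bump heatmap per landmark (22
channels) from a resized grayscale view, takes each channel's argmax as
the predicted position, and maps it back to the original image through
the recorded affine — the standard pipeline for anatomical keypoint
localization.  The trunk is a two-branch multi-resolution network
(:class:`~cervimotion.nn.TwoBranchHeatmapNet`); training minimizes the
mean-squared error between predicted and target heatmaps with SGD.

Desk defaults (128x128 input, width-12 trunk, 30 epochs) train in minutes
on one CPU thread from synthetic renders; the full-scale settings of a
clinical deployment (512x512 input, 4-stage trunk, large cohorts) are
reachable through the same config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp

from .errors import EmptyDataset, EmptyImage, NonFiniteLoss, OutOfFrame
from .landmarks import SCHEME, ViewAnnotation
from .nn import SGD, TwoBranchHeatmapNet, DTYPE


@dataclass(frozen=True)
class DetectorConfig:
    input_size: tuple[int, int] = (128, 128)  # (width, height)
    n_channels_out: int = 22
    stride: int = 4
    gaussian_sigma: float = 2.0  # in heatmap cells
    width: int = 16  # high-resolution branch channels; low branch is 2x
    n_stages: int = 2
    optimizer: str = "sgd"
    learning_rate: float = 1.5
    lr_schedule: str = "cosine"  # cosine | constant
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 90
    batch_size: int = 8
    augment_rotation_deg: float = 8.0
    augment_scale: tuple[float, float] = (0.9, 1.1)
    augment_flip: bool = False  # flipping a lateral view swaps anterior/posterior
    coord_channels: bool = True  # append normalized x/y planes to the input
    seed: int = 0

    def __post_init__(self):
        if self.n_channels_out != len(SCHEME):
            raise ValueError(f"n_channels_out must be {len(SCHEME)}")
        if self.input_size[0] % self.stride or self.input_size[1] % self.stride:
            raise ValueError("stride must divide the input size")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")

    @property
    def heatmap_size(self) -> tuple[int, int]:
        return (self.input_size[0] // self.stride, self.input_size[1] // self.stride)


@dataclass
class HeatmapStack:
    """22 activation planes plus the affine mapping cells to image pixels."""

    planes: np.ndarray  # (22, hh, hw)
    affine_to_image: np.ndarray  # 3x3, heatmap (x, y, 1) -> original px

    def __post_init__(self):
        if self.planes.shape[0] != len(SCHEME):
            raise ValueError(f"expected {len(SCHEME)} planes")
        if not np.all(np.isfinite(self.planes)):
            raise ValueError("non-finite activations")


def _as_grayscale(image) -> np.ndarray:
    img = np.asarray(image)
    if img.size == 0:
        raise EmptyImage("empty image")
    if img.ndim == 3:
        img = img.mean(axis=2)
    img = img.astype(np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def preprocess(
    image,
    cfg: DetectorConfig,
    landmarks: np.ndarray | None = None,
    *,
    augment: bool = False,
    rng: np.random.Generator | None = None,
):
    """Resize (and optionally augment) an image; return (image, affine, lms).

    ``affine`` is the 3x3 matrix mapping original-image (x, y) to network
    input coordinates; it is invertible and is also applied to the
    landmarks when provided.
    """
    img = _as_grayscale(image)
    h, w = img.shape
    tw, th = cfg.input_size
    m = np.diag([(tw - 1) / max(w - 1, 1), (th - 1) / max(h - 1, 1), 1.0])
    if augment:
        rng = np.random.default_rng() if rng is None else rng
        angle = np.radians(rng.uniform(-cfg.augment_rotation_deg, cfg.augment_rotation_deg))
        scale = rng.uniform(*cfg.augment_scale)
        flip = bool(cfg.augment_flip and rng.integers(0, 2))
        cx, cy = (tw - 1) / 2, (th - 1) / 2
        t_neg = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
        t_pos = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        sc = np.diag([scale, scale, 1.0])
        fl = np.diag([-1.0 if flip else 1.0, 1.0, 1.0])
        m = t_pos @ rot @ sc @ fl @ t_neg @ m
    out = warp(
        img,
        AffineTransform(matrix=np.linalg.inv(m)),
        output_shape=(th, tw),
        order=1,
        mode="edge",
        preserve_range=True,
    )
    lms = None
    if landmarks is not None:
        pts = np.asarray(landmarks, dtype=float)
        hom = np.column_stack([pts, np.ones(len(pts))])
        lms = (hom @ m.T)[:, :2]
    return out.astype(DTYPE), m, lms


def make_target_heatmaps(landmarks_input: np.ndarray, cfg: DetectorConfig,
                         affine_image_to_input: np.ndarray | None = None) -> HeatmapStack:
    """Unnormalized Gaussian bump (peak 1.0) per channel at heatmap scale.

    ``landmarks_input`` are (22, 2) coordinates in the network input frame.
    """
    pts = np.asarray(landmarks_input, dtype=float)
    tw, th = cfg.input_size
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > tw - 1) or \
       np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > th - 1):
        raise OutOfFrame("landmarks outside the network input frame")
    hw, hh = cfg.heatmap_size
    centers = pts / cfg.stride
    xs = np.arange(hw)[None, None, :]
    ys = np.arange(hh)[None, :, None]
    dx2 = (xs - centers[:, 0, None, None]) ** 2
    dy2 = (ys - centers[:, 1, None, None]) ** 2
    planes = np.exp(-(dx2 + dy2) / (2 * cfg.gaussian_sigma**2)).astype(DTYPE)
    if affine_image_to_input is None:
        affine_image_to_input = np.eye(3)
    affine_to_image = np.linalg.inv(affine_image_to_input) @ np.diag(
        [cfg.stride, cfg.stride, 1.0]
    )
    return HeatmapStack(planes=planes, affine_to_image=affine_to_image)


def decode_heatmaps(stack: HeatmapStack):
    """Argmax decoding: (22, 2) original-frame coords, confidences, flags.

    Ties resolve to the first row-major occurrence.  Channels with no
    positive activation are flagged ``all_zero`` (confidence 0); exactly
    uniform channels are flagged ``tie`` and decode to cell (0, 0).
    """
    planes = stack.planes
    n, hh, hw = planes.shape
    coords_hm = np.empty((n, 2))
    confidence = np.empty(n)
    flags = []
    for ch in range(n):
        plane = planes[ch]
        idx = int(np.argmax(plane))
        row, col = divmod(idx, hw)
        peak = float(plane[row, col])
        flag = ""
        if peak == float(plane.min()):
            flag = "tie"
        if peak <= 0:
            flag = "all_zero"
            peak = 0.0
        coords_hm[ch] = (col, row)
        confidence[ch] = peak
        flags.append(flag)
    hom = np.column_stack([coords_hm, np.ones(n)])
    coords = (hom @ stack.affine_to_image.T)[:, :2]
    return coords, confidence, flags


@dataclass
class DetectorModel:
    """A trained detector: network weights plus the config that built it."""

    net: TwoBranchHeatmapNet
    cfg: DetectorConfig

    def save(self, path) -> None:
        state = self.net.state_dict()
        np.savez(path, __config__=json.dumps(asdict(self.cfg)), **state)

    @classmethod
    def load(cls, path) -> "DetectorModel":
        with np.load(path, allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["__config__"]))
            for key in ("input_size", "augment_scale"):
                cfg_dict[key] = tuple(cfg_dict[key])
            cfg = DetectorConfig(**cfg_dict)
            net = TwoBranchHeatmapNet(
                cfg.n_channels_out, cfg.width, cfg.n_stages,
                in_channels=3 if cfg.coord_channels else 1,
                rng=np.random.default_rng(cfg.seed),
            )
            net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return cls(net=net, cfg=cfg)


def _net_input(img: np.ndarray, cfg: DetectorConfig) -> np.ndarray:
    """Stack the grayscale plane with normalized coordinate planes.

    The coordinate planes give the desk-scale trunk, whose receptive field
    is small, the absolute position cue it needs to tell apart the
    same-role corners of adjacent vertebrae.
    """
    if not cfg.coord_channels:
        return img[None]
    th, tw = img.shape
    ys, xs = np.mgrid[0:th, 0:tw].astype(DTYPE)
    return np.stack([img, xs / (tw - 1) - 0.5, ys / (th - 1) - 0.5])


def _forward_loss(net, images, targets, *, backward: bool) -> float:
    pred = net.forward(images)
    diff = pred - targets
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    if backward:
        net.backward((2.0 / diff.size * diff).astype(DTYPE))
    return loss


def _batch(samples, cfg, *, augment, rng):
    imgs, tgts = [], []
    for image, landmarks in samples:
        img, affine, lms = preprocess(image, cfg, landmarks, augment=augment, rng=rng)
        if augment:
            # re-draw augmentations that push landmarks off the input frame
            tries = 0
            tw, th = cfg.input_size
            while lms is not None and (
                lms.min() < 0 or lms[:, 0].max() > tw - 1 or lms[:, 1].max() > th - 1
            ) and tries < 10:
                img, affine, lms = preprocess(image, cfg, landmarks, augment=True, rng=rng)
                tries += 1
            if tries == 10:
                img, affine, lms = preprocess(image, cfg, landmarks, augment=False)
        target = make_target_heatmaps(lms, cfg, affine)
        imgs.append(_net_input(img, cfg))
        tgts.append(target.planes)
    return np.stack(imgs), np.stack(tgts)


def train_detector(train_set, val_set, cfg: DetectorConfig):
    """Train on (image, landmarks) pairs; return (model, history).

    The returned model carries the epoch checkpoint with the lowest
    validation loss.  Fully reproducible for a fixed config/seed under
    single-threaded execution.
    """
    train_set, val_set = list(train_set), list(val_set)
    if not train_set or not val_set:
        raise EmptyDataset("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    net = TwoBranchHeatmapNet(
        cfg.n_channels_out, cfg.width, cfg.n_stages,
        in_channels=3 if cfg.coord_channels else 1, rng=rng,
    )
    opt = SGD(net.params, cfg.learning_rate, cfg.momentum, cfg.weight_decay)

    val_images, val_targets = _batch(val_set, cfg, augment=False, rng=rng)

    def val_loss():
        total, count = 0.0, 0
        for start in range(0, len(val_images), cfg.batch_size):
            sl = slice(start, start + cfg.batch_size)
            total += _forward_loss(net, val_images[sl], val_targets[sl], backward=False) * (
                len(val_images[sl])
            )
            count += len(val_images[sl])
        return total / count

    history = []
    best = (float("inf"), net.copy_state(), -1)
    initial_val = val_loss()
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / cfg.epochs))
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            samples = [train_set[i] for i in order[start:start + cfg.batch_size]]
            images, targets = _batch(samples, cfg, augment=True, rng=rng)
            opt.zero_grad()
            loss = _forward_loss(net, images, targets, backward=True)
            if not np.isfinite(loss):
                raise NonFiniteLoss(f"epoch {epoch}, step {start // cfg.batch_size}")
            opt.step()
            epoch_losses.append(loss)
        v = val_loss()
        if not np.isfinite(v):
            raise NonFiniteLoss(f"validation loss at epoch {epoch}")
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)), "val_loss": v}
        )
        if v < best[0]:
            best = (v, net.copy_state(), epoch)
    net.load_state_dict(best[1])
    hist = pd.DataFrame(history)
    hist.attrs["initial_val_loss"] = initial_val
    hist.attrs["best_epoch"] = best[2]
    return DetectorModel(net=net, cfg=cfg), hist


def predict_landmarks(
    model: DetectorModel,
    image,
    spacing_mm: float,
    *,
    view: str = "neutral",
) -> tuple[ViewAnnotation, np.ndarray, list[str]]:
    """Detect all 22 landmarks on one image.

    Returns a ViewAnnotation (original-image pixels), per-landmark peak
    confidences, and per-landmark flags (``all_zero`` channels decode with
    confidence 0 rather than crashing).
    """
    cfg = model.cfg
    img, affine, _ = preprocess(image, cfg, augment=False)
    pred = model.net.forward(_net_input(img, cfg)[None])[0]
    stack = HeatmapStack(
        planes=pred.astype(np.float64),
        affine_to_image=np.linalg.inv(affine) @ np.diag([cfg.stride, cfg.stride, 1.0]),
    )
    coords, confidence, flags = decode_heatmaps(stack)
    gray = _as_grayscale(image)
    h, w = gray.shape
    coords = np.clip(coords, 0, [w - 1, h - 1])
    points = {lid: tuple(coords[k]) for k, lid in enumerate(SCHEME.ids)}
    ann = ViewAnnotation(
        view=view,
        points=points,
        pixel_spacing_mm=float(spacing_mm),
        image_size_px=(w, h),
        facing="unknown",
        annotator="model",
    )
    return ann, confidence, flags
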