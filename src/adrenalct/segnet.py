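"""3-D residual U-Net: architecture, Dice+focal loss, training, inference.

The encoder halves resolution between levels (strided convolution) while the
channel count follows ``channel_plan`` (default 32-64-128-256-512); the
decoder mirrors it with transposed convolutions and skip concatenation, each
level a residual unit (two 3x3x3 convolutions with an identity/projection
shortcut).  Training optimizes w_dice * dice + w_focal * focal with Adam,
annealing the learning rate to 0.9x every 20 epochs, checkpointing on best
validation loss.  Inference tiles large volumes with an overlapping sliding
window and averages the per-patch probabilities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import LabelMask
from .nn import Adam, Conv3d, ConvTranspose3d, InstanceNorm3d, ReLU
from .preprocess import PatchPair, PreprocessConfig, augment, sample_patches

logger = logging.getLogger(__name__)

__all__ = [
    "SegModel",
    "TrainConfig",
    "TrainHistory",
    "build_model",
    "dice_loss",
    "focal_loss",
    "combined_loss",
    "train",
    "sliding_window_infer",
    "save_checkpoint",
    "load_checkpoint",
]


class ResidualUnit:
    """conv-norm-relu-conv-norm (+ shortcut) -relu; plain variant drops the
    shortcut, giving the baseline U-Net block."""

    def __init__(self, c_in, c_out, stride=1, residual=True, rng=None):
        self.residual = residual
        self.conv1 = Conv3d(c_in, c_out, 3, stride, rng=rng)
        self.norm1 = InstanceNorm3d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(c_out, c_out, 3, 1, rng=rng)
        self.norm2 = InstanceNorm3d(c_out)
        self.relu2 = ReLU()
        self.shortcut = None
        if residual and (stride != 1 or c_in != c_out):
            self.shortcut = Conv3d(c_in, c_out, 1, stride, rng=rng)

    def layers(self):
        out = [self.conv1, self.norm1, self.conv2, self.norm2]
        if self.shortcut is not None:
            out.append(self.shortcut)
        return out

    def forward(self, x):
        h = self.relu1.forward(self.norm1.forward(self.conv1.forward(x)))
        h = self.norm2.forward(self.conv2.forward(h))
        if self.residual:
            h = h + (self.shortcut.forward(x) if self.shortcut is not None else x)
        return self.relu2.forward(h)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dx_skip = 0.0
        if self.residual:
            dx_skip = self.shortcut.backward(d) if self.shortcut is not None else d
        d = self.norm2.backward(d)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.norm1.backward(d)
        d = self.conv1.backward(d)
        return d + dx_skip


class SegModel:
    """Symmetric 3-D encoder-decoder with skip connections.

    Output spatial shape equals input shape; ``predict_proba`` returns
    per-voxel class probabilities summing to 1.
    """

    def __init__(self, channel_plan=(32, 64, 128, 256, 512), n_classes=3,
                 residual=True, in_channels=1, seed=0):
        plan = tuple(int(c) for c in channel_plan)
        if len(plan) < 2 or any(b <= a for a, b in zip(plan, plan[1:])):
            raise ValueError(
                f"channel_plan must be strictly increasing with length >= 2, got {plan}"
            )
        self.channel_plan = plan
        self.n_classes = int(n_classes)
        self.residual = bool(residual)
        self.in_channels = int(in_channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)

        self.stem = ResidualUnit(in_channels, plan[0], 1, residual, rng)
        self.encoders = [
            ResidualUnit(plan[i - 1], plan[i], 2, residual, rng)
            for i in range(1, len(plan))
        ]
        self.upsamplers = []
        self.decoders = []
        for i in range(len(plan) - 1, 0, -1):
            self.upsamplers.append(ConvTranspose3d(plan[i], plan[i - 1], rng=rng))
            self.decoders.append(
                ResidualUnit(2 * plan[i - 1], plan[i - 1], 1, residual, rng)
            )
        self.head = Conv3d(plan[0], self.n_classes, 1, 1, rng=rng)
        # zero-init the head: training starts from uniform class
        # probabilities, which avoids seed-dependent collapse into the
        # all-background minimum on highly imbalanced patches
        self.head.params["W"][...] = 0.0
        self._skip_channels = None

    # -- plumbing ---------------------------------------------------------
    def _units(self):
        units = [("stem", self.stem)]
        units += [(f"enc{i}", u) for i, u in enumerate(self.encoders)]
        units += [(f"up{i}", u) for i, u in enumerate(self.upsamplers)]
        units += [(f"dec{i}", u) for i, u in enumerate(self.decoders)]
        units += [("head", self.head)]
        return units

    def named_parameters(self):
        for name, unit in self._units():
            layers = unit.layers() if isinstance(unit, ResidualUnit) else [unit]
            for j, layer in enumerate(layers):
                yield f"{name}.{j}", layer.params, layer.grads

    def parameter_count(self) -> int:
        return sum(p.size for _, params, _ in self.named_parameters() for p in params.values())

    def state_dict(self):
        return {
            f"{name}/{key}": arr
            for name, params, _ in self.named_parameters()
            for key, arr in params.items()
        }

    def load_state_dict(self, state):
        for name, params, _ in self.named_parameters():
            for key in params:
                params[key][...] = state[f"{name}/{key}"]

    def min_divisor(self) -> int:
        return 2 ** (len(self.channel_plan) - 1)

    # -- forward/backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (N, n_classes, D, H, W); spatial dims must be divisible by
        2^(levels-1)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        div = self.min_divisor()
        if any(s % div for s in x.shape[2:]):
            raise ValueError(f"spatial dims {x.shape[2:]} must be divisible by {div}")
        skips = []
        h = self.stem.forward(x)
        for enc in self.encoders:
            skips.append(h)
            h = enc.forward(h)
        self._skip_channels = []
        for up, dec in zip(self.upsamplers, self.decoders):
            skip = skips.pop()
            h = up.forward(h)
            self._skip_channels.append(skip.shape[1])
            h = dec.forward(np.concatenate([skip, h], axis=1))
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        m = len(self.decoders)
        # decoder i consumed skip index m-1-i (decoder 0 takes the deepest)
        dskip_by_index = [None] * m
        for i in range(m - 1, -1, -1):
            c_skip = self._skip_channels[i]
            dcat = self.decoders[i].backward(d)
            dskip_by_index[m - 1 - i] = dcat[:, :c_skip]
            d = self.upsamplers[i].backward(np.ascontiguousarray(dcat[:, c_skip:]))
        for j in range(m - 1, -1, -1):
            d = self.encoders[j].backward(d) + dskip_by_index[j]
        self.stem.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def build_model(channel_plan=(32, 64, 128, 256, 512), n_classes=3, residual=True,
                seed=0) -> SegModel:
    return SegModel(channel_plan, n_classes, residual, seed=seed)


# ---------------------------------------------------------------------------
# losses: each returns (scalar loss, dloss/dprobs)
# ---------------------------------------------------------------------------

def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    t = np.asarray(target)
    if t.ndim == 3:
        t = t[None]
    return np.moveaxis(np.eye(n_classes, dtype=np.float32)[t.astype(int)], -1, 1)


def _check_probs(probs, target):
    probs = np.asarray(probs)  # dtype preserved: float64 oracles stay exact
    if probs.ndim == 4:
        probs = probs[None]
    t = np.asarray(target)
    if t.ndim == 3:
        t = t[None]
    if probs.shape[0] != t.shape[0] or probs.shape[2:] != t.shape[1:]:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {t.shape}")
    return probs, t


def dice_loss(probs, target, eps: float = 1e-5, return_grad: bool = False):
    """Soft Dice loss averaged over the foreground classes present in the
    target (all foreground classes when none is present, where the smoothing
    term makes each contribute ~0).  Value in [0, 1]."""
    probs, t = _check_probs(probs, target)
    n_classes = probs.shape[1]
    onehot = _one_hot(t, n_classes)
    fg = list(range(1, n_classes))
    present = [c for c in fg if onehot[:, c].sum() > 0]
    counted = present if present else fg
    grad = np.zeros_like(probs) if return_grad else None
    total = 0.0
    for c in counted:
        p, tc = probs[:, c], onehot[:, c]
        inter = float((p * tc).sum())
        denom = float(p.sum() + tc.sum())
        d = (2.0 * inter + eps) / (denom + eps)
        total += 1.0 - d
        if return_grad:
            grad[:, c] = -(2.0 * tc * (denom + eps) - (2.0 * inter + eps)) / (
                (denom + eps) ** 2
            ) / len(counted)
    loss = total / len(counted)
    if return_grad:
        return loss, grad
    return loss


def focal_loss(probs, target, gamma: float = 2.0, alpha: float = 1.0,
               p_floor: float = 1e-7, return_grad: bool = False):
    """Mean over voxels of -alpha * (1 - p_t)^gamma * log(p_t)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    probs, t = _check_probs(probs, target)
    n_classes = probs.shape[1]
    onehot = _one_hot(t, n_classes).astype(bool)
    pt = np.maximum(np.where(onehot, probs, 0.0).sum(axis=1), p_floor)
    n_vox = pt.size
    loss = float((-alpha * (1.0 - pt) ** gamma * np.log(pt)).sum() / n_vox)
    if not return_grad:
        return loss
    if gamma == 0:
        dpt = -alpha / pt
    else:
        dpt = alpha * gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt) - alpha * (
            1.0 - pt
        ) ** gamma / pt
    grad = np.zeros_like(probs)
    np.copyto(grad, (dpt / n_vox)[:, None], where=onehot)
    return loss, grad


def combined_loss(probs, target, w_dice=1.0, w_focal=1.0, gamma=2.0, alpha=1.0,
                  return_grad: bool = False):
    if return_grad:
        ld, gd = dice_loss(probs, target, return_grad=True)
        lf, gf = focal_loss(probs, target, gamma=gamma, alpha=alpha, return_grad=True)
        return w_dice * ld + w_focal * lf, w_dice * gd + w_focal * gf
    return w_dice * dice_loss(probs, target) + w_focal * focal_loss(
        probs, target, gamma=gamma, alpha=alpha
    )


def grad_wrt_logits(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Backprop dL/dprobs through the softmax."""
    inner = (probs * dprobs).sum(axis=1, keepdims=True)
    return probs * (dprobs - inner)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainConfig:
    lr0: float = 3e-4
    epochs: int = 200
    decay_factor: float = 0.9
    decay_every: int = 20
    loss_weights: Tuple[float, float] = (1.0, 1.0)
    focal_gamma: float = 2.0
    focal_alpha: float = 1.0
    batch_size: int = 1
    patches_per_epoch: int = 8
    patch_size: Tuple[int, int, int] = (96, 96, 96)
    foreground_bias: float = 0.5
    noise_sigma_aug: float = 0.02
    rotation_range_deg: float = 15.0
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not 0.0 < self.decay_factor < 1.0:
            raise ValueError("decay_factor must be in (0, 1)")
        w = self.loss_weights
        if w[0] < 0 or w[1] < 0 or (w[0] == 0 and w[1] == 0):
            raise ValueError("loss weights must be nonnegative and not both zero")

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.decay_factor ** (epoch // self.decay_every)


@dataclasses.dataclass
class TrainHistory:
    epochs: List[int] = dataclasses.field(default_factory=list)
    train_loss: List[float] = dataclasses.field(default_factory=list)
    valid_loss: List[float] = dataclasses.field(default_factory=list)
    lr: List[float] = dataclasses.field(default_factory=list)
    checkpoint_saved: List[bool] = dataclasses.field(default_factory=list)

    def as_dict(self):
        return dataclasses.asdict(self)


def _epoch_patches(pairs, config: TrainConfig, rng, do_augment):
    pre = PreprocessConfig(
        patch_size=config.patch_size,
        foreground_bias=config.foreground_bias,
        noise_sigma_aug=config.noise_sigma_aug,
        rotation_range_deg=config.rotation_range_deg,
        seed=int(rng.integers(2**31 - 1)),
    )
    out = []
    for _ in range(config.patches_per_epoch):
        vol, msk = pairs[int(rng.integers(len(pairs)))]
        pre.seed = int(rng.integers(2**31 - 1))
        patch = sample_patches(vol, msk, pre, 1)[0]
        if do_augment and config.augment:
            patch = augment(patch, pre, int(rng.integers(2**31 - 1)))
        out.append(patch)
    return out


def _loss_on_patch(model, patch: PatchPair, config: TrainConfig, with_grad):
    logits = model.forward(patch.image_patch)
    probs = softmax(logits)
    w_d, w_f = config.loss_weights
    if with_grad:
        loss, dprobs = combined_loss(
            probs, patch.mask_patch, w_d, w_f, config.focal_gamma,
            config.focal_alpha, return_grad=True,
        )
        model.backward(grad_wrt_logits(probs, dprobs))
    else:
        loss = combined_loss(
            probs, patch.mask_patch, w_d, w_f, config.focal_gamma, config.focal_alpha
        )
    return loss


def train(model: SegModel, train_set: Sequence, valid_set: Sequence,
          config: TrainConfig):
    """Optimize the combined loss on sampled, augmented patches.

    ``train_set`` / ``valid_set``: sequences of (CTVolume, LabelMask), already
    preprocessed.  Best-validation-loss parameters are restored at the end.
    Returns (model, TrainHistory).
    """
    if not len(train_set):
        raise ValueError("train set is empty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.named_parameters(), lr=config.lr0)
    history = TrainHistory()
    best_loss = np.inf
    best_state = None
    valid_rng = np.random.default_rng(config.seed + 1)
    valid_patches = (
        _epoch_patches(valid_set, config, valid_rng, do_augment=False)
        if len(valid_set)
        else None
    )
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        optimizer.lr = lr
        losses = []
        for patch in _epoch_patches(train_set, config, rng, do_augment=True):
            optimizer.zero_grad()
            loss = _loss_on_patch(model, patch, config, with_grad=True)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            optimizer.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        if valid_patches is not None:
            valid_loss = float(
                np.mean([
                    _loss_on_patch(model, p, config, with_grad=False)
                    for p in valid_patches
                ])
            )
        else:
            valid_loss = train_loss
        saved = valid_loss < best_loss
        if saved:
            best_loss = valid_loss
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        history.epochs.append(epoch)
        history.train_loss.append(train_loss)
        history.valid_loss.append(valid_loss)
        history.lr.append(lr)
        history.checkpoint_saved.append(bool(saved))
        logger.info(
            "epoch %d lr %.2e train %.4f valid %.4f%s",
            epoch, lr, train_loss, valid_loss, " *" if saved else "",
        )
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _tile_starts(size: int, patch: int, step: int):
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch + 1, step))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def sliding_window_infer(model: SegModel, volume, patch_size=(96, 96, 96),
                         overlap: float = 0.25) -> np.ndarray:
    """Tile the volume, predict each patch, average overlaps.

    Returns a (n_classes, D, H, W) probability array; ``argmax`` over axis 0
    gives the label map.  Volumes smaller than the patch are padded,
    predicted and cropped back.
    """
    if not 0.0 <= overlap <= 0.9:
        raise ValueError("overlap must be in [0, 0.9]")
    data = volume.voxels if hasattr(volume, "voxels") else np.asarray(volume)
    data = data.astype(np.float32)
    orig_shape = data.shape
    ps = tuple(int(p) for p in patch_size)
    pad = [(0, max(0, p - s)) for p, s in zip(ps, orig_shape)]
    if any(p[1] for p in pad):
        data = np.pad(data, pad)
    shape = data.shape
    steps = [max(1, int(round(p * (1.0 - overlap)))) for p in ps]
    acc = np.zeros((model.n_classes, *shape), dtype=np.float32)
    cnt = np.zeros(shape, dtype=np.float32)
    for i in _tile_starts(shape[0], ps[0], steps[0]):
        for j in _tile_starts(shape[1], ps[1], steps[1]):
            for k in _tile_starts(shape[2], ps[2], steps[2]):
                sl = (slice(i, i + ps[0]), slice(j, j + ps[1]), slice(k, k + ps[2]))
                probs = model.predict_proba(data[sl])[0]
                acc[(slice(None),) + sl] += probs
                cnt[sl] += 1.0
    assert (cnt > 0).all()
    acc /= cnt
    crop = (slice(None),) + tuple(slice(0, s) for s in orig_shape)
    return acc[crop]


def predicted_mask(probs: np.ndarray, like=None) -> LabelMask:
    labels = probs.argmax(axis=0).astype(np.int16)
    if like is not None:
        return LabelMask(
            labels, spacing=like.spacing, orientation=like.orientation,
            origin=like.origin,
        )
    return LabelMask(labels)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegModel, path, history: Optional[TrainHistory] = None,
                    train_config: Optional[TrainConfig] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "channel_plan": list(model.channel_plan),
        "n_classes": model.n_classes,
        "residual": model.residual,
        "in_channels": model.in_channels,
        "seed": model.seed,
        "history": history.as_dict() if history else None,
        "train_config": dataclasses.asdict(train_config) if train_config else None,
    }
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())
    return path


def load_checkpoint(path):
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        model = SegModel(
            tuple(meta["channel_plan"]), meta["n_classes"], meta["residual"],
            in_channels=meta["in_channels"], seed=meta["seed"],
        )
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model.load_state_dict(state)
    history = None
    if meta.get("history"):
        history = TrainHistory(**meta["history"])
    return model, history
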