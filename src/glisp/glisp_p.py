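"""GLISP-P: the patch-level predictor.

A compact CNN — four stride-2 convolutional blocks (3x3 kernels, ReLU),
global average pooling, and an MLP head — trained per genetic task under
weak supervision: every patch inherits its case's binary status. The
penultimate MLP activation is the patch *encoding* consumed by the
slide-level MIL meta-model.

Default widths are 3 -> 8 -> 16 -> 32 -> 64 with a 64 -> 64 -> 1 head
(encoding_dim 64); the architecture is deliberately small — one independent
model per task keeps training and interpretation cheap — and every constant
is configurable through :class:`GlispPConfig`.
"""

from __future__ import annotations

import json
import time
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import nn
from .labels import GeneLabelTable, TASKS
from .tiling import PatchImage

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# augmentation

@dataclass
class AugmentationPolicy:
    """Mixed-distortion protocol: with probability ``p`` a training patch
    receives a random flip/rotation, colour jitter and Gaussian blur."""

    p: float = 0.5
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    hue: float = 0.05
    blur_sigma: tuple[float, float] = (0.1, 1.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("mixed-distortion probability must be in [0, 1]")


# RGB <-> YIQ; hue jitter is a rotation of the chroma (I, Q) plane, the
# classic linear hue-rotate operator — one 3x3 matrix per patch
_RGB2YIQ = np.array([[0.299, 0.587, 0.114],
                     [0.596, -0.274, -0.322],
                     [0.211, -0.523, 0.312]], dtype=np.float32)
_YIQ2RGB = np.linalg.inv(_RGB2YIQ).astype(np.float32)


def _color_jitter(img: np.ndarray, policy: AugmentationPolicy,
                  rng: np.random.Generator) -> np.ndarray:
    out = img.astype(np.float32)
    if policy.brightness:
        out *= 1.0 + np.float32(rng.uniform(-policy.brightness, policy.brightness))
    if policy.contrast:
        mean = out.mean(dtype=np.float32)
        out = mean + (out - mean) * np.float32(
            1.0 + rng.uniform(-policy.contrast, policy.contrast))
    if policy.saturation:
        gray = out.mean(axis=2, keepdims=True, dtype=np.float32)
        out = gray + (out - gray) * np.float32(
            1.0 + rng.uniform(-policy.saturation, policy.saturation))
    if policy.hue:
        theta = np.float32(2.0 * np.pi * rng.uniform(-policy.hue, policy.hue))
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=np.float32)
        out = out @ (_YIQ2RGB @ rot @ _RGB2YIQ).T
    return out


def augment(patch: PatchImage | np.ndarray, policy: AugmentationPolicy,
            rng: np.random.Generator) -> np.ndarray:
    """Apply the augmentation protocol; returns a uint8 array of the same shape."""
    img = patch.pixels if isinstance(patch, PatchImage) else np.asarray(patch)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) patch, got {img.shape}")
    if policy.p == 0.0 or rng.random() >= policy.p:
        return img.copy()
    k = rng.integers(0, 4)  # quarter-turn rotation
    out = np.rot90(img, k=int(k))
    if rng.random() < 0.5:
        out = out[:, ::-1]  # horizontal flip
    if rng.random() < 0.5:
        out = out[::-1]  # vertical flip
    out = _color_jitter(np.ascontiguousarray(out), policy, rng)
    sigma = rng.uniform(*policy.blur_sigma)
    out = gaussian_filter(out, sigma=(sigma, sigma, 0.0), truncate=2.5)
    return np.clip(out, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# layer primitives

#: layer specifications are the NumPy layers themselves
ConvLayerSpec = nn.Conv2d
LinearLayerSpec = nn.Linear


def conv_forward(x: np.ndarray, layer: nn.Conv2d) -> np.ndarray:
    """Single-sample convolution: (C_t, H, W) -> (C_{t+1}, H', W').

    Output channel c is ``b_c + sum_k W_{c,k} cross-correlated with X_t(k)``.
    """
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {x.shape}")
    return layer.forward(x[None])[0]


def linear_forward(x: np.ndarray, layer: nn.Linear) -> np.ndarray:
    """Single-sample fully connected layer: returns ``x @ W + b``."""
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D feature vector, got shape {x.shape}")
    return layer.forward(x[None])[0]


# ---------------------------------------------------------------------------
# model

@dataclass
class GlispPConfig:
    channels: tuple[int, ...] = (8, 16, 32, 64)  # four conv blocks
    kernel_size: int = 3
    stride: int = 2
    encoding_dim: int = 64
    input_pool: int = 2  # fixed average-pool stem before conv 1 (1 = off)


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 20
    patience: int = 3  # early stop on validation loss
    val_fraction: float = 0.2
    class_weighting: bool = True  # inverse-prevalence weights
    augmentation: AugmentationPolicy | None = field(default_factory=AugmentationPolicy)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("lr, batch_size and max_epochs must be positive")


def normalize_patches(x: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 (N, 3, H, W) centred on 0."""
    out = x.transpose(0, 3, 1, 2).astype(np.float32, order="C")
    out *= 1.0 / 255.0
    out -= 0.5
    return out


class GlispPModel:
    """Per-task patch classifier; forward yields probability + encoding."""

    def __init__(self, task: str = "idh", config: GlispPConfig | None = None,
                 seed: int = 0):
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.config = config or GlispPConfig()
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        cfg = self.config
        layers: list[nn.Layer] = []
        cin = 3
        if cfg.input_pool > 1:
            layers.append(nn.AvgPool2d(cfg.input_pool))
        pad = cfg.kernel_size // 2
        for cout in cfg.channels:
            layers.append(nn.Conv2d(cin, cout, cfg.kernel_size, stride=cfg.stride,
                                    padding=pad, rng=rng))
            layers.append(nn.ReLU())
            cin = cout
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Linear(cin, cfg.encoding_dim, rng=rng))
        layers.append(nn.ReLU())
        layers.append(nn.Linear(cfg.encoding_dim, 1, rng=rng))
        self.backbone = nn.Sequential(layers)  # ends at the logit
        # training/inference view: the fixed pooling stem is fused into input
        # preparation (pooling and normalisation commute, both affine)
        start = 1 if cfg.input_pool > 1 else 0
        self.core = nn.Sequential(layers[start:])
        self.trained = False

    def prepare(self, batch: np.ndarray) -> np.ndarray:
        """uint8 (N, H, W, 3) -> pooled, normalised float32 (N, 3, h, w)."""
        k = self.config.input_pool
        x = batch.astype(np.float32)
        if k > 1:
            n, h, w, c = x.shape
            x = x.reshape(n, h // k, k, w // k, k, c).mean(axis=(2, 4))
        x *= 1.0 / 255.0
        x -= 0.5
        return x.transpose(0, 3, 1, 2).astype(np.float32, order="C")

    @property
    def encoding_dim(self) -> int:
        return self.config.encoding_dim

    def as_sequential(self, include_sigmoid: bool = True) -> nn.Sequential:
        layers = list(self.backbone.layers)
        if include_sigmoid:
            layers = layers + [nn.Sigmoid()]
        return nn.Sequential(layers)

    # -- inference ----------------------------------------------------------
    def forward_logits(self, prepared: np.ndarray) -> np.ndarray:
        """Logits for an already-prepared float32 batch (see :meth:`prepare`)."""
        return self.core.forward(prepared).ravel()

    def _forward_with_encoding(self, prepared: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = prepared
        enc = None
        for layer in self.core.layers:
            x = layer.forward(x)
            if isinstance(layer, nn.ReLU) and x.ndim == 2:
                enc = x  # penultimate MLP features
        return x.ravel(), enc

    def predict_proba(self, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Probabilities for uint8 patches (N, 256, 256, 3) or a single patch."""
        single = patches.ndim == 3
        x = patches[None] if single else patches
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward_logits(self.prepare(x[i : i + batch_size]))
            probs.append(nn.sigmoid(logits))
        out = np.concatenate(probs)
        return float(out[0]) if single else out

    def encode(self, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Penultimate-layer encodings, shape (N, encoding_dim)."""
        single = patches.ndim == 3
        x = patches[None] if single else patches
        encs = []
        for i in range(0, len(x), batch_size):
            _, e = self._forward_with_encoding(self.prepare(x[i : i + batch_size]))
            encs.append(e)
        out = np.concatenate(encs)
        return out[0] if single else out

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.backbone.state_dict())
        sidecar = {
            "task": self.task,
            "encoding_dim": self.encoding_dim,
            "config": asdict(self.config),
            "seed": self.seed,
            "trained": self.trained,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GlispPModel":
        path = Path(path)
        try:
            sidecar = json.loads(path.with_suffix(".json").read_text())
            state = dict(np.load(path.with_suffix(".npz")))
        except (OSError, json.JSONDecodeError, KeyError) as exc:
            raise IOError(f"unreadable checkpoint {path}: {exc}") from exc
        cfg = sidecar["config"]
        cfg["channels"] = tuple(cfg["channels"])
        model = cls(task=sidecar["task"], config=GlispPConfig(**cfg), seed=sidecar["seed"])
        model.backbone.load_state_dict(state)
        model.trained = sidecar.get("trained", False)
        return model


def predict_patch(model: GlispPModel, patch: PatchImage | np.ndarray) -> float:
    """Probability of the genetic event for one patch."""
    if not model.trained:
        raise IOError("model is untrained; train or load a checkpoint first")
    pixels = patch.pixels if isinstance(patch, PatchImage) else np.asarray(patch)
    return float(model.predict_proba(pixels))


def encode_patch(model: GlispPModel, patch: PatchImage | np.ndarray) -> np.ndarray:
    """Penultimate-layer encoding vector for one patch."""
    pixels = patch.pixels if isinstance(patch, PatchImage) else np.asarray(patch)
    return model.encode(pixels)


# ---------------------------------------------------------------------------
# training

def split_cases(case_ids: np.ndarray, case_labels: dict[str, int],
                val_fraction: float, rng: np.random.Generator) -> tuple[set, set]:
    """Stratified case-level holdout; no case contributes to both sides."""
    cases = np.asarray(sorted(set(case_ids)))
    val: list = []
    for cls in (0, 1):
        members = [c for c in cases if case_labels[c] == cls]
        n_val = max(1, round(val_fraction * len(members))) if members else 0
        val.extend(rng.permutation(members)[:n_val])
    val_set = set(val)
    return set(cases) - val_set, val_set


def train_glisp_p(
    images: np.ndarray,
    manifest,
    labels: GeneLabelTable,
    task: str,
    config: TrainConfig | None = None,
    model_config: GlispPConfig | None = None,
) -> tuple[GlispPModel, dict]:
    """Train a per-task patch model under weak (case-inherited) supervision.

    ``images`` is the (N, 256, 256, 3) uint8 stack aligned row-for-row with
    ``manifest`` (columns ``case_id`` at minimum). Returns the model and a
    training log with per-epoch train/validation losses and the split.
    """
    cfg = config or TrainConfig()
    case_status = labels.for_task(task)
    known = manifest["case_id"].isin(case_status.index).to_numpy()
    if not known.any():
        raise ValueError(f"no labeled cases for task {task!r}")
    idx_all = np.flatnonzero(known)
    case_of = manifest["case_id"].to_numpy()[idx_all]
    y_all = case_status.loc[case_of].to_numpy().astype(np.float32)
    if len(np.unique(y_all)) < 2:
        raise ValueError(f"task {task!r}: only one class present after "
                         "missing-label exclusion")

    ss = np.random.SeedSequence(cfg.seed)
    split_rng, shuffle_rng, aug_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    train_cases, val_cases = split_cases(case_of, case_status.to_dict(),
                                         cfg.val_fraction, split_rng)
    tr_mask = np.isin(case_of, list(train_cases))
    idx_tr, idx_val = idx_all[tr_mask], idx_all[~tr_mask]
    y_tr, y_val = y_all[tr_mask], y_all[~tr_mask]
    assert not (set(case_of[tr_mask]) & set(case_of[~tr_mask])), \
        "case-level leakage between train and validation"

    if cfg.class_weighting:
        pos = max(y_tr.mean(), 1e-6)
        w_pos, w_neg = 0.5 / pos, 0.5 / max(1.0 - pos, 1e-6)
    else:
        w_pos = w_neg = 1.0

    model = GlispPModel(task=task, config=model_config, seed=cfg.seed)
    params = model.core.state_dict()  # shares arrays with the full backbone
    opt = nn.Adam(params, lr=cfg.lr)

    history = {"train_loss": [], "val_loss": [], "epoch_seconds": [],
               "train_cases": sorted(train_cases), "val_cases": sorted(val_cases)}
    best_val, best_state, patience_left = np.inf, None, cfg.patience
    for epoch in range(cfg.max_epochs):
        t0 = time.time()
        order = shuffle_rng.permutation(len(idx_tr))
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            batch_imgs = images[idx_tr[sel]]
            if cfg.augmentation is not None and cfg.augmentation.p > 0:
                batch_imgs = np.stack([augment(im, cfg.augmentation, aug_rng)
                                       for im in batch_imgs])
            xb = model.prepare(batch_imgs)
            yb = y_tr[sel]
            wb = np.where(yb > 0.5, w_pos, w_neg)
            logits = model.core.forward(xb).ravel()
            loss, gl = nn.bce_loss_and_grad(logits, yb, wb)
            model.core.backward(gl.reshape(-1, 1))
            grads = {f"{i}.{n}": layer.grads[n]
                     for i, layer in enumerate(model.core.layers)
                     for n in layer.params}
            opt.step(grads)
            ep_loss += loss
            n_batches += 1
        # validation loss (no augmentation)
        val_losses = []
        for start in range(0, len(idx_val), cfg.batch_size):
            sel = idx_val[start : start + cfg.batch_size]
            logits = model.core.forward(model.prepare(images[sel])).ravel()
            yb = y_val[start : start + cfg.batch_size]
            wb = np.where(yb > 0.5, w_pos, w_neg)
            loss, _ = nn.bce_loss_and_grad(logits, yb, wb)
            val_losses.append(loss * len(sel))
        val_loss = float(np.sum(val_losses) / max(len(idx_val), 1))
        history["train_loss"].append(ep_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        history["epoch_seconds"].append(time.time() - t0)
        log.info("task %s epoch %d: train %.4f val %.4f", task, epoch,
                 history["train_loss"][-1], val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.backbone.state_dict().items()}
            patience_left = cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                log.info("task %s: early stop at epoch %d", task, epoch)
                break
    if best_state is not None:
        model.backbone.load_state_dict(best_state)
    model.trained = True
    return model, history
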