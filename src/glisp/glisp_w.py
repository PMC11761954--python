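"""GLISP-W: the slide-level MIL meta-model over bags of patch encodings.

A bag is K (default 32) patch encodings drawn without replacement from one
slide — the size of a small (~0.5 mm^2) biopsy area. MLP1 transforms each
instance, a learned attention layer assigns a convex weight to each
transformed instance (softmax of per-instance scores, so weights are
non-negative and sum to one), and MLP2 maps the attention-pooled vector to
the slide probability. The model is permutation-invariant by construction
and reduces to MLP2(MLP1(h)) for K = 1.

The attention is the standard (non-gated) formulation
``score_k = w^T tanh(V h'_k + c)``; a gated variant (multiplicative sigmoid
branch) is available via :class:`GlispWConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import Adam, bce_loss_and_grad, sigmoid
from .labels import GeneLabelTable, TASKS
from .tiling import sample_bag

log = logging.getLogger(__name__)


@dataclass
class GlispWConfig:
    encoding_dim: int = 64
    hidden_dim: int = 64  # MLP1 output width
    attn_dim: int = 32
    head_hidden: int = 32  # MLP2 hidden width
    bag_size: int = 32  # K
    gated_attention: bool = False


@dataclass
class WTrainConfig:
    lr: float = 2e-3
    batch_size: int = 16
    max_epochs: int = 60
    patience: int = 10
    val_fraction: float = 0.2
    bags_per_epoch: int = 4  # fresh bag draws per slide per epoch
    val_draws: int = 4  # bag draws averaged for the validation loss
    class_weighting: bool = True
    seed: int = 0


def attention_pool(h: np.ndarray, V: np.ndarray, c: np.ndarray,
                   w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Attention-pool K instance vectors.

    ``h`` is (K, d); scores are ``w^T tanh(h V + c)``; weights are their
    softmax; the pooled vector is the weighted sum. Returns (pooled, weights).
    """
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("attention_pool needs a non-empty (K, d) matrix")
    scores = np.tanh(h @ V + c) @ w
    scores = scores - scores.max()
    e = np.exp(scores)
    a = e / e.sum()
    return a @ h, a


class GlispWModel:
    """Two-MLP attention-MIL bag classifier for one genetic task."""

    def __init__(self, task: str = "idh", config: GlispWConfig | None = None,
                 seed: int = 0):
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.config = config or GlispWConfig()
        self.seed = seed
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

        def init(shape, fan_in):
            return rng.normal(0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)

        d, h1, a, h2 = cfg.encoding_dim, cfg.hidden_dim, cfg.attn_dim, cfg.head_hidden
        self.params: dict[str, np.ndarray] = {
            "W1": init((d, h1), d), "b1": np.zeros(h1),
            "V": init((h1, a), h1), "c": np.zeros(a),
            "w": init((a,), a),
            "W2": init((h1, h2), h1), "b2": np.zeros(h2),
            "w3": init((h2, 1), h2), "b3": np.zeros(1),
        }
        if cfg.gated_attention:
            self.params["U"] = init((h1, a), h1)
            self.params["u0"] = np.zeros(a)
        self.trained = False

    @property
    def bag_size(self) -> int:
        return self.config.bag_size

    # -- forward / backward --------------------------------------------------
    def _forward(self, x: np.ndarray, need_cache: bool = False):
        """x: (N, K, d) float; returns (logits (N,), weights (N, K), cache)."""
        p = self.params
        if x.ndim != 3 or x.shape[2] != self.config.encoding_dim:
            raise ValueError(
                f"expected bags (N, K, {self.config.encoding_dim}), got {x.shape}")
        pre1 = x @ p["W1"] + p["b1"]
        h = np.maximum(pre1, 0.0)  # (N, K, h1)
        u = np.tanh(h @ p["V"] + p["c"])  # (N, K, A)
        if self.config.gated_attention:
            g = 1.0 / (1.0 + np.exp(-(h @ p["U"] + p["u0"])))
            ug = u * g
        else:
            g = None
            ug = u
        s = ug @ p["w"]  # (N, K)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        a = e / e.sum(axis=1, keepdims=True)  # attention weights
        assert np.all(a >= 0) and np.allclose(a.sum(axis=1), 1.0, atol=1e-6), \
            "attention weights must be a convex combination"
        z = np.einsum("nk,nkh->nh", a, h)  # pooled (N, h1)
        pre2 = z @ p["W2"] + p["b2"]
        q = np.maximum(pre2, 0.0)
        logits = (q @ p["w3"] + p["b3"]).ravel()
        cache = (x, pre1, h, u, g, a, z, pre2, q) if need_cache else None
        return logits, a, cache

    def _backward(self, cache, glogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        x, pre1, h, u, g, a, z, pre2, q = cache
        gl = glogits.reshape(-1, 1)  # (N, 1)
        grads = {"w3": q.T @ gl, "b3": gl.sum(axis=0)}
        dq = gl @ p["w3"].T
        dq[pre2 <= 0] = 0.0
        grads["W2"] = z.T @ dq
        grads["b2"] = dq.sum(axis=0)
        dz = dq @ p["W2"].T  # (N, h1)
        da = np.einsum("nh,nkh->nk", dz, h)
        dh = a[..., None] * dz[:, None, :]
        ds = a * (da - (a * da).sum(axis=1, keepdims=True))
        if self.config.gated_attention:
            ug_grad = ds[..., None] * p["w"]  # d/d(u*g)
            du = ug_grad * g
            dg = ug_grad * u
            grads["w"] = ((u * g) * ds[..., None]).sum(axis=(0, 1))
            dpre_g = dg * g * (1.0 - g)
            grads["U"] = np.einsum("nkh,nka->ha", h, dpre_g)
            grads["u0"] = dpre_g.sum(axis=(0, 1))
            dh += dpre_g @ p["U"].T
        else:
            grads["w"] = (u * ds[..., None]).sum(axis=(0, 1))
            du = ds[..., None] * p["w"]
        dpre_u = du * (1.0 - u ** 2)
        grads["V"] = np.einsum("nkh,nka->ha", h, dpre_u)
        grads["c"] = dpre_u.sum(axis=(0, 1))
        dh += dpre_u @ p["V"].T
        dh[pre1 <= 0] = 0.0
        grads["W1"] = np.einsum("nkd,nkh->dh", x, dh)
        grads["b1"] = dh.sum(axis=(0, 1))
        return grads

    # -- public inference ----------------------------------------------------
    def forward_bag(self, encodings: np.ndarray) -> tuple[float, np.ndarray]:
        """One bag (K, d) -> (slide probability, attention weights)."""
        enc = np.asarray(encodings, dtype=np.float64)
        if enc.ndim != 2 or enc.shape[0] < 1:
            raise ValueError("a bag must be a non-empty (K, d) matrix")
        logits, a, _ = self._forward(enc[None])
        return float(sigmoid(logits)[0]), a[0]

    def forward_bags(self, bags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logits, a, _ = self._forward(np.asarray(bags, dtype=np.float64))
        return sigmoid(logits), a

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {"task": self.task, "config": asdict(self.config),
                   "seed": self.seed, "trained": self.trained}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GlispWModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(task=sidecar["task"], config=GlispWConfig(**sidecar["config"]),
                    seed=sidecar["seed"])
        model.params = {k: np.asarray(v) for k, v in np.load(path.with_suffix(".npz")).items()}
        model.trained = sidecar.get("trained", False)
        return model


def glisp_w_forward(bag_encodings: np.ndarray, model: GlispWModel) -> tuple[float, np.ndarray]:
    """Slide probability and attention weights for one bag of encodings."""
    return model.forward_bag(bag_encodings)


def _draw_bags(slide_encodings: dict[str, np.ndarray], slide_ids: list[str],
               k: int, rng: np.random.Generator) -> np.ndarray:
    bags = np.empty((len(slide_ids), k, next(iter(slide_encodings.values())).shape[1]))
    for i, sid in enumerate(slide_ids):
        enc = slide_encodings[sid]
        bag = sample_bag(list(range(len(enc))), k=k, seed=int(rng.integers(2**31)))
        bags[i] = enc[bag.members]
    return bags


def train_glisp_w(
    slide_encodings: dict[str, np.ndarray],
    slide_cases: dict[str, str],
    labels: GeneLabelTable,
    task: str,
    config: WTrainConfig | None = None,
    model_config: GlispWConfig | None = None,
) -> tuple[GlispWModel, dict]:
    """Train the bag-level meta-model on frozen patch encodings.

    ``slide_encodings`` maps slide_id -> (n_patches, encoding_dim) matrix
    (the output of the frozen per-task patch model); ``slide_cases`` maps
    slide_id -> case_id. Bags are redrawn every epoch with a fresh
    substream, acting as bag-level augmentation.
    """
    cfg = config or WTrainConfig()
    case_status = labels.for_task(task)
    slides = sorted(s for s in slide_encodings if slide_cases[s] in case_status.index)
    if not slides:
        raise ValueError(f"no labeled slides for task {task!r}")
    y = case_status.loc[[slide_cases[s] for s in slides]].to_numpy().astype(np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError(f"task {task!r}: only one class present")

    ss = np.random.SeedSequence(cfg.seed)
    split_rng, bag_rng, shuffle_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    from .glisp_p import split_cases

    slide_case_arr = np.array([slide_cases[s] for s in slides])
    train_cases, val_cases = split_cases(slide_case_arr, case_status.to_dict(),
                                         cfg.val_fraction, split_rng)
    tr = np.isin(slide_case_arr, list(train_cases))
    slides_tr = [s for s, m in zip(slides, tr) if m]
    slides_val = [s for s, m in zip(slides, tr) if not m]
    y_tr, y_val = y[tr], y[~tr]

    if cfg.class_weighting:
        pos = max(y_tr.mean(), 1e-6)
        w_pos, w_neg = 0.5 / pos, 0.5 / max(1.0 - pos, 1e-6)
    else:
        w_pos = w_neg = 1.0

    mcfg = model_config or GlispWConfig(
        encoding_dim=next(iter(slide_encodings.values())).shape[1])
    model = GlispWModel(task=task, config=mcfg, seed=cfg.seed)
    opt = Adam(model.params, lr=cfg.lr)
    k = mcfg.bag_size

    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, patience_left = np.inf, None, cfg.patience
    for epoch in range(cfg.max_epochs):
        # resample bags every epoch: bag-level augmentation on a fixed cohort
        bags_tr = np.concatenate([_draw_bags(slide_encodings, slides_tr, k, bag_rng)
                                  for _ in range(cfg.bags_per_epoch)])
        y_ep = np.tile(y_tr, cfg.bags_per_epoch)
        order = shuffle_rng.permutation(len(bags_tr))
        ep_loss, nb = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            logits, _, cache = model._forward(bags_tr[sel], need_cache=True)
            yb = y_ep[sel]
            wb = np.where(yb > 0.5, w_pos, w_neg)
            loss, gl = bce_loss_and_grad(logits, yb, wb)
            grads = model._backward(cache, gl.astype(np.float64))
            opt.step(grads)
            ep_loss += loss
            nb += 1
        wv = np.where(y_val > 0.5, w_pos, w_neg)
        val_losses = []
        for _ in range(cfg.val_draws):
            bags_val = _draw_bags(slide_encodings, slides_val, k, bag_rng)
            logits, _, _ = model._forward(bags_val)
            val_losses.append(bce_loss_and_grad(logits, y_val, wv)[0])
        val_loss = float(np.mean(val_losses))
        history["train_loss"].append(ep_loss / max(nb, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {kk: v.copy() for kk, v in model.params.items()}
            patience_left = cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_state is not None:
        model.params = best_state
    model.trained = True
    history["train_slides"] = slides_tr
    history["val_slides"] = slides_val
    return model, history


def predict_slide(model: GlispWModel, encodings: np.ndarray, n_draws: int = 8,
                  seed: int = 0) -> float:
    """Slide probability: mean over ``n_draws`` seeded bag draws."""
    rng = np.random.default_rng(seed)
    k = model.bag_size
    probs = []
    for _ in range(n_draws):
        bag = sample_bag(list(range(len(encodings))), k=k, seed=int(rng.integers(2**31)))
        probs.append(model.forward_bag(encodings[bag.members])[0])
    return float(np.mean(probs))


def predict_case(model: GlispWModel, case_slide_encodings: list[np.ndarray],
                 n_draws: int = 8, seed: int = 0) -> float:
    """Case probability: mean of per-slide probabilities over seeded bag draws."""
    if not case_slide_encodings:
        raise ValueError("a case needs at least one slide")
    rng = np.random.default_rng(seed)
    slide_probs = [predict_slide(model, enc, n_draws=n_draws,
                                 seed=int(rng.integers(2**31)))
                   for enc in case_slide_encodings]
    return float(np.mean(slide_probs))
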