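"""DeepLIFT (rescale rule) attribution for the patch-level model.

Contributions are computed relative to a reference input: affine layers
(convolution, fully connected, average pooling) propagate multipliers
exactly like input-gradients, and elementwise nonlinearities use the rescale
multiplier delta_out / delta_in (falling back to the derivative at the input
when the input difference vanishes). On networks without multiplicative
interactions this satisfies summation-to-delta: the attributions sum to
f(x) - f(reference) up to floating point.

The patch-level summary score is the arithmetic mean of all pixel-level
scores; per-channel attributions are summed over RGB before spatial
averaging. The default reference is the per-dataset mean patch (fallback:
an all-white patch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .glisp_p import GlispPModel, normalize_patches

_EPS = 1e-7


@dataclass
class AttributionMap:
    """Pixel-level DeepLIFT scores for one patch (channel-summed, H x W)."""

    scores: np.ndarray
    baseline_desc: str = "dataset-mean patch"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("attribution map contains non-finite values")


@dataclass
class PatchScore:
    score: float
    patch_ref: tuple  # (slide_id, x, y) provenance
    task: str = ""


def deeplift_sequential(seq: nn.Sequential, x: np.ndarray,
                        baseline: np.ndarray) -> np.ndarray:
    """Attribution of a scalar-output Sequential w.r.t. its input array.

    ``x`` and ``baseline`` share a shape with leading batch dim 1 (or are
    batched identically). Returns an array shaped like ``x``.
    """
    x = np.asarray(x, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if x.shape != baseline.shape:
        raise ValueError(f"input {x.shape} and baseline {baseline.shape} differ in shape")

    ins_x, ins_b = [], []
    ax, ab = x, baseline
    for layer in seq.layers:
        ins_x.append(ax)
        ins_b.append(ab)
        ax = layer.forward(ax)
        ab = layer.forward(ab)
    out_x, out_b = ax, ab

    m = np.ones_like(out_x)
    for layer, xi, bi in zip(reversed(seq.layers), reversed(ins_x), reversed(ins_b)):
        if isinstance(layer, nn.layers.ELEMENTWISE):
            d_in = xi - bi
            d_out = layer.fn(xi) - layer.fn(bi)
            ratio = np.where(np.abs(d_in) > _EPS, d_out / np.where(np.abs(d_in) > _EPS, d_in, 1.0),
                             layer.deriv(xi))
            m = m * ratio
        elif getattr(layer, "affine", False):
            m = layer.input_grad(m, in_shape=xi.shape)
        else:  # pragma: no cover - no other layer kinds exist
            raise TypeError(f"cannot propagate multipliers through {type(layer).__name__}")
    attr = m * (x - baseline)
    # consistency of the computed delta is the caller-facing contract
    del out_b
    return attr


def mean_patch_baseline(images: np.ndarray) -> np.ndarray:
    """Per-dataset mean patch (uint8); all-white when no images are given."""
    if images is None or len(images) == 0:
        return np.full((256, 256, 3), 255, dtype=np.uint8)
    return images.astype(np.float64).mean(axis=0).round().astype(np.uint8)


def deeplift_attribution(model: GlispPModel, patch: np.ndarray,
                         baseline: np.ndarray, output: str = "prob") -> AttributionMap:
    """Pixel-level DeepLIFT map of a patch against a same-shape reference.

    ``output`` selects the attributed quantity: the event probability
    (``"prob"``, sigmoid included) or the raw logit.
    """
    patch = np.asarray(patch)
    baseline = np.asarray(baseline)
    if patch.shape != baseline.shape:
        raise ValueError("patch and baseline must share a shape")
    seq = model.as_sequential(include_sigmoid=(output == "prob"))
    attr = deeplift_sequential(seq, normalize_patches(patch[None]),
                               normalize_patches(baseline[None]))
    # (1, 3, H, W) -> channel-summed (H, W)
    return AttributionMap(attr[0].sum(axis=0))


def patch_score(attribution: AttributionMap | np.ndarray,
                patch_ref: tuple = ("", 0, 0), task: str = "") -> PatchScore:
    """Patch-level score: the mean of all pixel-level scores."""
    scores = attribution.scores if isinstance(attribution, AttributionMap) else np.asarray(attribution)
    if scores.size == 0:
        raise ValueError("empty attribution map")
    return PatchScore(score=float(scores.mean()), patch_ref=tuple(patch_ref), task=task)


def rank_patches(scores: list[PatchScore], n: int) -> tuple[list[PatchScore], list[PatchScore]]:
    """Top-n most positive and top-n most negative patches.

    Ties break deterministically by provenance (slide_id, x, y).
    """
    if n > len(scores):
        raise ValueError(f"requested top {n} of {len(scores)} scores")
    by_pos = sorted(scores, key=lambda s: (-s.score, s.patch_ref))
    by_neg = sorted(scores, key=lambda s: (s.score, s.patch_ref))
    return by_pos[:n], by_neg[:n]


def score_patches(model: GlispPModel, images: np.ndarray, manifest: pd.DataFrame,
                  baseline: np.ndarray | None = None) -> pd.DataFrame:
    """DeepLIFT patch scores for a whole manifest; returns a scores table."""
    if baseline is None:
        baseline = mean_patch_baseline(images)
    rows = []
    for i, row in manifest.reset_index(drop=True).iterrows():
        amap = deeplift_attribution(model, images[i], baseline)
        ps = patch_score(amap, (row["slide_id"], row["x"], row["y"]), model.task)
        rows.append({"patch_path": row.get("patch_path", ""), "slide_id": row["slide_id"],
                     "x": row["x"], "y": row["y"], "task": model.task, "score": ps.score})
    return pd.DataFrame(rows)
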