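"""Grad-CAM saliency for the adjudicator and ROI-level localization scores.

For a chosen convolutional stage with post-ReLU feature maps A^k, channel
importances are the spatially averaged gradients of the adjudicator
probability,

    w_k = (1/Z) sum_{u,v} d y_hat / d A^k_{u,v},

and the class-activation map is ReLU(sum_k w_k A^k), bilinearly upsampled
to the patch and divided by its maximum (when positive).  Heatmaps are
compared against expert boxes with mask IoU/Dice after relative
thresholding and with the pointing game (does the heatmap argmax fall
inside the box).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .adjnet import AdjudicatorModel
from .boxes import Box


@dataclass(frozen=True)
class SaliencyResult:
    heatmap: np.ndarray  # patch_size x patch_size, >= 0, max 1 unless all-zero
    channel_weights: np.ndarray  # w_k per feature map
    raw_map: np.ndarray  # un-upsampled ReLU(sum_k w_k A^k)


def gradcam(
    model: AdjudicatorModel,
    patch: np.ndarray,
    s: float,
    target_layer: int = -1,
) -> SaliencyResult:
    """Grad-CAM heatmap of the adjudicator probability for one ROI.

    ``target_layer`` indexes the backbone's conv blocks (default: the last
    convolutional stage).  The map is non-negative by construction and
    max-normalized to [0, 1] unless identically zero.
    """
    n_blocks = len(model.convs)
    k = target_layer if target_layer >= 0 else n_blocks + target_layer
    if not 0 <= k < n_blocks:
        raise ValueError(f"target_layer {target_layer} not in backbone (0..{n_blocks - 1})")
    x = np.asarray(patch, dtype=float)
    if x.ndim == 2:
        x = x[None]
    y_hat = model.forward(x, np.array([float(s)]))
    acts = model._cache["acts"]
    # d y_hat / d logit = y_hat (1 - y_hat); propagate a unit output gradient
    model.zero_grad()
    dlogit = (y_hat * (1.0 - y_hat)).reshape(-1)
    grads = model.backward(dlogit, collect_activation_grads=True)
    model.zero_grad()
    a = acts[k][0]  # (C, h, w)
    g = grads[k][0]
    weights = g.mean(axis=(1, 2))  # (1/Z) sum_uv dy/dA
    raw = np.maximum(np.einsum("k,kuv->uv", weights, a), 0.0)
    size = x.shape[-1]
    heat = _sk_resize(
        raw, (size, size), order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    heat = np.maximum(heat, 0.0)
    m = heat.max()
    if m > 0:
        heat = heat / m
    return SaliencyResult(heatmap=heat, channel_weights=weights, raw_map=raw)


def heatmap_to_mask(heatmap: np.ndarray, rel_threshold: float = 0.5) -> np.ndarray:
    """Binary mask at a threshold relative to the heatmap maximum.

    An identically-zero heatmap yields an all-zero mask.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must be in (0, 1)")
    h = np.asarray(heatmap, dtype=float)
    m = h.max()
    if m <= 0:
        return np.zeros_like(h, dtype=bool)
    return h >= rel_threshold * m


def localization_scores(
    heatmap: np.ndarray, mask: np.ndarray, expert_box: Box
) -> tuple[float, float, int]:
    """(mask IoU, Dice, pointing hit) of a saliency map against an expert box.

    The box (patch coordinates, half-open) is rasterized to a filled
    rectangle; the pointing hit is 1 iff the row-major-first argmax pixel of
    the heatmap lies inside it.
    """
    h = np.asarray(heatmap, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    size_y, size_x = mask.shape
    x0 = int(np.floor(expert_box.x_min))
    y0 = int(np.floor(expert_box.y_min))
    x1 = int(np.ceil(expert_box.x_max))
    y1 = int(np.ceil(expert_box.y_max))
    if not (0 <= x0 < x1 <= size_x and 0 <= y0 < y1 <= size_y):
        raise ValueError("expert box must lie within the patch")
    rect = np.zeros_like(mask)
    rect[y0:y1, x0:x1] = True
    inter = int(np.sum(mask & rect))
    union = int(np.sum(mask | rect))
    iou_val = inter / union if union else 0.0
    denom = int(mask.sum()) + int(rect.sum())
    dice = 2.0 * inter / denom if denom else 0.0
    # ties broken by first occurrence in row-major order (np.argmax contract)
    flat = int(np.argmax(h))
    py, px = divmod(flat, h.shape[1])
    hit = int(rect[py, px])
    return float(iou_val), float(dice), hit


def pointing_game_accuracy(hits: np.ndarray | list[int]) -> float:
    """Mean pointing-game hit rate over a set of ROIs."""
    hits = np.asarray(hits, dtype=float)
    if hits.size == 0:
        raise ValueError("no pointing-game results to average")
    return float(hits.mean())
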