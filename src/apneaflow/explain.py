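"""Attribution methods for the airflow event-count regressor.

Two complementary views of what the network uses:

* **Grad-CAM**, aggregated over every convolutional block: for each block the
  post-ReLU feature maps are weighted by the temporal mean of the gradient of
  the scalar output with respect to them, summed and rectified; the per-block
  heatmaps are min-max normalized, linearly resized to the input length, and
  averaged into one relevance map in [0, 1].

* **Deep-SHAP**: DeepLIFT-style multipliers (rescale rule at ReLUs, exact
  affine propagation through convolutions, inference batch-norm and the
  linear head, a delta-proportional rule at max-pooling) propagated from the
  scalar output to the input and averaged over a background set of reference
  segments. The resulting signed attributions satisfy the completeness
  (local-accuracy) identity: they sum to ``f(x) - mean_b f(b)``.

Both operate on the trained regressor in inference mode and return values
aligned sample-by-sample with the input segment. Activation tensors follow
the network's channels-last ``(batch, time, channel)`` layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cnn import CNNRegressor
from .simulate import EventAnnotation, RESPIRATORY_KINDS
from .training import TrainedModel

__all__ = [
    "AttributionMap",
    "grad_cam_layer",
    "grad_cam_aggregate",
    "deep_shap",
    "localization_score",
    "LocalizationScore",
]

_COMPLETENESS_TOL = 1e-3


@dataclass
class AttributionMap:
    """Per-sample relevance aligned to one input segment."""

    subject_id: str
    segment_index: int
    values: np.ndarray
    kind: str  # "gradcam" or "shap"
    meta: dict


def _model_of(trained) -> CNNRegressor:
    return trained.model if isinstance(trained, TrainedModel) else trained


def _forward_with_grads(model: CNNRegressor, segment: np.ndarray):
    """Inference-path forward + backward for one segment; returns the output,
    the per-block post-ReLU feature maps (time, channel) and the gradient of
    the output with respect to each of them."""
    x = np.asarray(segment, dtype=model.dtype)[None, :, None]
    h = x
    caches = []
    for blk in model.blocks:
        h = blk["conv"].forward(h, training=False)
        h = blk["bn"].forward(h, training=False)
        relu_in = h
        a = np.maximum(h, 0.0)
        h = blk["pool"].forward(a, training=True)  # caches argmax for backward
        caches.append({"relu_in": relu_in, "act": a, "blk": blk})
    flat = h.reshape(1, -1)
    out = float((flat @ model.head.W.T + model.head.b)[0, 0])

    g = model.head.W.reshape(1, *model.flat_shape).astype(model.dtype)
    act_grads = []
    for cache in reversed(caches):
        blk = cache["blk"]
        g = blk["pool"].backward(g)
        act_grads.append(g[0])
        g = g * (cache["relu_in"] > 0)
        g = g * blk["bn"].inference_scale()
        g = blk["conv"].input_grad(g)
    act_grads.reverse()
    activations = [c["act"][0] for c in caches]
    return out, activations, act_grads


def grad_cam_layer(trained, segment: np.ndarray, block_index: int) -> np.ndarray:
    """Grad-CAM heatmap of one convolutional block at its own resolution.

    Weights each post-ReLU feature map by the temporal mean of the output
    gradient and rectifies the weighted sum; the result is non-negative with
    length equal to the block's (pre-pool) temporal length.
    """
    model = _model_of(trained)
    if not 0 <= block_index < model.config.n_blocks:
        raise ValueError(f"block_index must be in [0, {model.config.n_blocks})")
    _, activations, act_grads = _forward_with_grads(model, segment)
    A = activations[block_index]  # (T, C)
    alpha = act_grads[block_index].mean(axis=0)  # (C,)
    return np.maximum(A @ alpha, 0.0).astype(float)


def _normalize_resize(heatmap: np.ndarray, length: int) -> np.ndarray:
    """Min-max normalize to [0, 1] (all-zero maps stay zero), then linearly
    interpolate to the requested length."""
    lo, hi = float(heatmap.min()), float(heatmap.max())
    if hi - lo < 1e-12:
        norm = np.zeros_like(heatmap, dtype=float)
    else:
        norm = (heatmap.astype(float) - lo) / (hi - lo)
    if norm.size == length:
        return norm
    src = np.linspace(0.0, 1.0, norm.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, norm)


def grad_cam_aggregate(trained, segment: np.ndarray) -> np.ndarray:
    """Final multi-layer Grad-CAM heatmap: per-block maps normalized,
    resized to the input length and averaged; values lie in [0, 1]."""
    model = _model_of(trained)
    L = model.config.input_length
    _, activations, act_grads = _forward_with_grads(model, segment)
    maps = []
    for A, G in zip(activations, act_grads):
        alpha = G.mean(axis=0)
        cam = np.maximum(A @ alpha, 0.0)
        maps.append(_normalize_resize(cam, L))
    return np.mean(maps, axis=0)


# ---------------------------------------------------------------------------
# Deep-SHAP


def _pool_multiplier(m_out, x_in, b_in, pool: int):
    """Propagate multipliers through max-pooling with a delta-proportional
    rule: each window's output delta is distributed over the window inputs in
    proportion to their deltas, so summation-to-delta holds exactly. Windows
    whose deltas all vanish carry zero delta and contribute nothing."""
    if pool == 1:
        return m_out
    B, L2, C = m_out.shape
    L = x_in.shape[1]
    xr = x_in[:, : L2 * pool, :].reshape(B, L2, pool, C)
    br = b_in[:, : L2 * pool, :].reshape(B, L2, pool, C)
    d_in = xr - br  # (B, L2, pool, C)
    d_out = xr.max(axis=2) - br.max(axis=2)  # (B, L2, C)
    denom = np.sum(d_in**2, axis=2)
    safe = denom > 1e-12
    coef = np.where(safe, d_out * m_out / np.where(safe, denom, 1.0), 0.0)
    m_in = coef[:, :, None, :] * d_in
    m_in = m_in.reshape(B, L2 * pool, C)
    if L2 * pool < L:
        m_in = np.pad(m_in, ((0, 0), (0, L - L2 * pool), (0, 0)))
    return m_in


def _layer_inputs(model: CNNRegressor, x: np.ndarray):
    """Inference forward over a batch, recording each block's pre-ReLU tensor
    and pooling input."""
    h = np.asarray(x, dtype=model.dtype)[:, :, None]
    rec = []
    for blk in model.blocks:
        h = blk["conv"].forward(h, training=False)
        h = blk["bn"].forward(h, training=False)
        relu_in = h
        h = np.maximum(h, 0.0)
        pool_in = h
        h = blk["pool"].forward(h, training=False)
        rec.append({"relu_in": relu_in, "pool_in": pool_in})
    preds = (h.reshape(x.shape[0], -1) @ model.head.W.T + model.head.b)[:, 0]
    return rec, preds.astype(float)


def deep_shap(
    trained,
    segment: np.ndarray,
    background: np.ndarray,
    check_completeness: bool = True,
) -> np.ndarray:
    """Signed per-sample SHAP attributions for one segment.

    ``background`` is a ``(B, L)`` array of reference segments (typically
    quiet-breathing segments with zero events). Attributions are averaged
    over references and satisfy completeness:
    ``|sum(phi) - (f(x) - mean_b f(b))| <= 1e-3 * max(1, |delta|)``,
    verified at emit time unless ``check_completeness`` is disabled.
    """
    model = _model_of(trained)
    x = np.asarray(segment, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] < 1:
        raise ValueError("need at least one background segment")
    if background.shape[1] != x.size:
        raise ValueError(
            f"background length {background.shape[1]} does not match "
            f"segment length {x.size}"
        )
    B = background.shape[0]
    rec_x, pred_x = _layer_inputs(model, x[None, :])
    rec_b, pred_b = _layer_inputs(model, background)

    # multipliers flow backward with the reference batch in the lead axis
    m = np.broadcast_to(
        model.head.W.reshape(1, *model.flat_shape).astype(model.dtype),
        (B, *model.flat_shape),
    ).copy()
    for i in range(model.config.n_blocks - 1, -1, -1):
        blk = model.blocks[i]
        x_pool = np.broadcast_to(rec_x[i]["pool_in"], rec_b[i]["pool_in"].shape)
        m = _pool_multiplier(m, x_pool, rec_b[i]["pool_in"], model.config.pool)
        # ReLU rescale rule: m *= (relu(x) - relu(b)) / (x - b)
        xi = np.broadcast_to(rec_x[i]["relu_in"], rec_b[i]["relu_in"].shape)
        bi = rec_b[i]["relu_in"]
        dx = xi - bi
        big = np.abs(dx) > 1e-7
        ratio = np.where(
            big,
            (np.maximum(xi, 0) - np.maximum(bi, 0)) / np.where(big, dx, 1.0),
            (xi > 0).astype(model.dtype),
        )
        m = m * ratio
        # inference batch-norm is affine
        m = m * blk["bn"].inference_scale()
        # convolution is linear: same transform as gradient backprop
        m = blk["conv"].input_grad(m)
    m = m[:, :, 0].astype(float)  # single input channel
    phi = np.mean(m * (x[None, :] - background), axis=0)

    if check_completeness:
        delta = float(pred_x[0] - pred_b.mean())
        err = abs(float(phi.sum()) - delta)
        if err > _COMPLETENESS_TOL * max(1.0, abs(delta)):
            raise RuntimeError(
                f"Deep-SHAP completeness violated: |sum(phi) - delta| = {err:.3e} "
                f"for delta = {delta:.3e}"
            )
    return phi


# ---------------------------------------------------------------------------
# localization scoring


@dataclass(frozen=True)
class LocalizationScore:
    ratio: float
    inside_mean: float
    outside_mean: float
    undefined: bool  # outside mean was zero


def localization_score(
    values: np.ndarray,
    annotations: Sequence[EventAnnotation],
    segment_start: float,
    segment_minutes: int,
    kind: str = "gradcam",
    fs: float = 4.0,
    margin_s: float = 5.0,
) -> LocalizationScore:
    """Mean relevance inside annotated event windows (+/- margin) divided by
    the mean relevance elsewhere in the segment.

    For signed SHAP attributions the magnitude is scored. A ratio > 1 means
    the attribution concentrates on the injected respiratory events.
    """
    values = np.asarray(values, dtype=float)
    if kind == "shap":
        values = np.abs(values)
    L = values.size
    seg_end = segment_start + segment_minutes * 60.0
    mask = np.zeros(L, dtype=bool)
    n_events = 0
    for a in annotations:
        if a.kind not in RESPIRATORY_KINDS:
            continue
        lo, hi = a.onset - margin_s, a.end + margin_s
        if hi <= segment_start or lo >= seg_end:
            continue
        n_events += 1
        i0 = max(0, int(np.floor((lo - segment_start) * fs)))
        i1 = min(L, int(np.ceil((hi - segment_start) * fs)))
        mask[i0:i1] = True
    if n_events == 0:
        raise ValueError(
            "segment contains no respiratory events; filter event-bearing "
            "segments before scoring localization"
        )
    inside = float(values[mask].mean())
    outside_vals = values[~mask]
    outside = float(outside_vals.mean()) if outside_vals.size else 0.0
    if outside <= 0.0:
        return LocalizationScore(np.inf, inside, outside, undefined=True)
    return LocalizationScore(inside / outside, inside, outside, undefined=False)
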