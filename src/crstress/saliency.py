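"""Grad-CAM saliency maps and a quantitative lesion-encapsulation score.

Grad-CAM weights each channel of a chosen convolutional block's activation
by the spatial mean of the output gradient with respect to that
activation, sums the weighted channels, gates through a ReLU, upsamples
bilinearly to the network-input extent and normalizes the maximum to 1.

The encapsulation score replaces visual judgement of whether the salient
region covers the annotated lesion: the heatmap is binarized at its own
intensity quantile (default 0.8, i.e. the top 20% of pixels are "salient")
and the score is the fraction of lesion-mask pixels falling inside that
region. ``hit`` records whether the salient region touches the mask at
all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .cnn3 import TrainedModel
from .preprocess import SideInput


def default_cam_layer(model: TrainedModel, min_extent: int = 16) -> int:
    """Deepest conv block whose pre-pool ReLU grid is >= min_extent per
    axis; the last block if none qualifies."""
    from ._nn.layers import conv_out_size

    h, w = model.input_shape
    cfg = model.config
    best = len(model.conv_relu_indices) - 1
    for i in range(len(model.conv_relu_indices)):
        h = conv_out_size(h, cfg.kernel, cfg.stride, cfg.padding)
        w = conv_out_size(w, cfg.kernel, cfg.stride, cfg.padding)
        if min(h, w) >= min_extent:
            best = i
        h, w = h // cfg.pool_kernel, w // cfg.pool_kernel
    return best


@dataclass
class SaliencyResult:
    heatmap: np.ndarray           # [0, 1], congruent to the side input
    predicted_prob: float
    encapsulation: float | None   # defined only when a mask is present
    hit: bool | None


def grad_cam(model: TrainedModel, side: SideInput,
             layer_index: int | None = None,
             quantile: float = 0.8) -> SaliencyResult:
    """Saliency map of one side input under a trained model.

    ``layer_index`` addresses one of the three conv blocks (0-based). The
    default is the deepest block whose activation grid still has at least
    16x16 spatial extent — at small input sizes the deeper blocks
    collapse to a handful of cells and carry no localization — falling
    back to the last block. The gradient is taken on the output logit, which
    yields the same normalized map as the probability (the sigmoid
    contributes a positive scalar factor).
    """
    if not model.trained:
        raise ValueError("grad_cam needs a trained model")
    if layer_index is None:
        layer_index = default_cam_layer(model)
    if not 0 <= layer_index < len(model.conv_relu_indices):
        raise ValueError(f"layer_index {layer_index} out of range")
    capture = model.conv_relu_indices[layer_index]

    x = side.pixels.astype(np.float32)[None, None]
    logit = model.net.forward(x, train=False, capture=capture)[0, 0]
    act = model.net.captured[0]              # (C, h, w)
    dout = np.ones((1, 1), dtype=np.float32)
    dact = model.net.backward(dout, stop_at=capture)[0]

    weights = dact.mean(axis=(1, 2))         # pooled gradient per channel
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    cam = _sk_resize(cam, side.pixels.shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak

    prob = float(1.0 / (1.0 + np.exp(-logit)))
    enc, hit = None, None
    if side.mask is not None and side.mask.any():
        enc, hit = encapsulation_score(cam, side.mask, quantile)
    return SaliencyResult(cam.astype(np.float64), prob, enc, hit)


def encapsulation_score(heatmap: np.ndarray, mask: np.ndarray,
                        quantile: float = 0.8) -> tuple[float, bool]:
    """Fraction of lesion pixels inside the binarized salient region.

    The heatmap is thresholded at its own ``quantile`` (so roughly
    ``1 - quantile`` of pixels are salient regardless of scale); a
    uniformly random heatmap therefore scores ~``1 - quantile`` in
    expectation, which is the chance floor.
    """
    heatmap = np.asarray(heatmap)
    mask = np.asarray(mask).astype(bool)
    if heatmap.shape != mask.shape:
        raise ValueError("heatmap and mask shapes differ")
    if not mask.any():
        raise ValueError("encapsulation undefined for an empty mask")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    thresh = np.quantile(heatmap, quantile)
    # zero-valued pixels carry no influence (ReLU-gated) and are never
    # salient, even when the quantile threshold collapses to zero
    salient = (heatmap >= thresh) & (heatmap > 0)
    enc = float((salient & mask).sum() / mask.sum())
    return enc, enc > 0


def study_saliency(model: TrainedModel, left: SideInput, right: SideInput,
                   layer_index: int | None = None, quantile: float = 0.8):
    """Saliency for both sides of a study; returns {"left": ..., "right": ...}."""
    return {"left": grad_cam(model, left, layer_index, quantile),
            "right": grad_cam(model, right, layer_index, quantile)}
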