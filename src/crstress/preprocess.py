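"""View preprocessing: resize -> view-specific crop -> paired-view
concatenation into one network input per breast side.

The crop keeps the half of the image next to the chest wall (left half for
left-laterality views, right half for right-laterality views) and removes
the fifth of rows far from the breast (top fifth for MLO projections,
bottom fifth for CC). The CC and MLO crops of one side are then placed
side by side (CC leftmost) and rescaled to [0, 1]; lesion masks ride along
through the identical geometry and are unioned.

Rounding conventions: resized extents use round-half-up per axis; crops
discard floor(W/2) columns and floor(H/5) rows. Row 0 is the image top,
column 0 its left edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .synthdata import MAX_I, LesionMask, StudyRecord, ViewImage


@dataclass
class SideInput:
    """The network's input: one side's concatenated views in [0, 1]."""

    pixels: np.ndarray
    side: str  # {"left", "right"}
    label: int  # 1 = malignant study, 0 = normal/benign
    source_cr: float = 1.0
    mask: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self):
        if not np.isfinite(self.pixels).all():
            raise ValueError("non-finite pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixels must lie in [0, 1]")
        if self.mask is not None and self.mask.shape != self.pixels.shape:
            raise ValueError("mask incongruent with pixels")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def resized_dims(height: int, width: int, factor: float) -> tuple[int, int]:
    return _round_half_up(factor * height), _round_half_up(factor * width)


def resize_view(view: ViewImage, factor: float,
                mask: LesionMask | None = None):
    """Bilinear resize to ``round(factor * dim)`` per axis.

    Masks are resized with nearest-neighbour sampling so every set output
    pixel maps back to a set input pixel.
    """
    if not 0 < factor <= 1:
        raise ValueError("resize factor must lie in (0, 1]")
    h, w = resized_dims(view.height, view.width, factor)
    if h < 8 or w < 8:
        raise ValueError("resized view smaller than 8 px per side")
    if factor == 1.0:
        out_view = ViewImage(view.pixels.copy(), view.view)
        out_mask = LesionMask(mask.mask.copy(), mask.present) if mask else None
    else:
        resized = _sk_resize(view.pixels.astype(np.float64), (h, w), order=1,
                             mode="edge", anti_aliasing=False,
                             preserve_range=True)
        out_view = ViewImage(np.clip(resized, 0, MAX_I).astype(np.uint16),
                             view.view)
        out_mask = None
        if mask is not None:
            rm = _sk_resize(mask.mask.astype(np.float64), (h, w), order=0,
                            mode="edge", anti_aliasing=False,
                            preserve_range=True) > 0.5
            out_mask = LesionMask(rm if mask.present else np.zeros((h, w), bool),
                                  mask.present)
    return (out_view, out_mask) if mask is not None else out_view


def crop_extents(height: int, width: int, view_tag: str):
    """Half-open (row, col) slices kept by the crop for a given view."""
    half = width // 2
    fifth = height // 5
    cols = slice(0, half) if view_tag[0] == "L" else slice(width - half, width)
    rows = (slice(fifth, height) if view_tag.endswith("MLO")
            else slice(0, height - fifth))
    return rows, cols


def crop_view(view: ViewImage, mask: LesionMask | None = None):
    rows, cols = crop_extents(view.height, view.width, view.view)
    out_view = ViewImage(view.pixels[rows, cols].copy(), view.view)
    if mask is None:
        return out_view
    out_mask = LesionMask(mask.mask[rows, cols].copy()
                          if mask.present else
                          np.zeros(out_view.pixels.shape, bool), mask.present)
    return out_view, out_mask


def concat_side(cc: ViewImage, mlo: ViewImage,
                cc_mask: LesionMask | None = None,
                mlo_mask: LesionMask | None = None,
                label: int = 0, source_cr: float = 1.0,
                subject_id: str = "") -> SideInput:
    """Place the CC view left of the MLO view; pad the shorter at the
    bottom; rescale to [0, 1]; union the masks."""
    if cc.laterality != mlo.laterality:
        raise ValueError("cannot concatenate views of different lateralities")
    h = max(cc.height, mlo.height)

    def pad(v: np.ndarray) -> np.ndarray:
        return np.pad(v, ((0, h - v.shape[0]), (0, 0)))

    pixels = np.hstack([pad(cc.pixels), pad(mlo.pixels)]).astype(np.float32)
    pixels /= MAX_I
    mask = None
    if cc_mask is not None and mlo_mask is not None:
        mask = np.hstack([pad(cc_mask.mask), pad(mlo_mask.mask)]).astype(bool)
    return SideInput(pixels, cc.laterality, int(label), float(source_cr),
                     mask, subject_id)


def preprocess_study(study: StudyRecord, factor: float = 0.3,
                     pixels_override: dict[str, np.ndarray] | None = None,
                     source_cr: float = 1.0) -> tuple[SideInput, SideInput]:
    """resize -> crop -> concatenate, per side.

    ``pixels_override`` substitutes decoded (compressed) pixel arrays for
    the study's stored views, keyed by view tag — the label and the lesion
    masks always come from the uncompressed ground truth.
    """
    label = int(study.label == "malignant")
    sides = {}
    for side, cc_tag, mlo_tag in (("left", "LCC", "LMLO"),
                                  ("right", "RCC", "RMLO")):
        parts = {}
        for tag in (cc_tag, mlo_tag):
            vi = study.views[tag]
            if pixels_override is not None and tag in pixels_override:
                vi = ViewImage(pixels_override[tag], tag)
            v, m = resize_view(vi, factor, study.masks[tag])
            parts[tag] = crop_view(v, m)
        (cc_v, cc_m), (mlo_v, mlo_m) = parts[cc_tag], parts[mlo_tag]
        sides[side] = concat_side(cc_v, mlo_v, cc_m, mlo_m, label,
                                  source_cr, study.subject_id)
    return sides["left"], sides["right"]
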