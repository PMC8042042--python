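"""Synthetic mammography-like studies with ground-truth lesion masks.

A *study* is one subject's four screening views — left/right craniocaudal
(LCC, RCC) and left/right mediolateral-oblique (LMLO, RMLO) — as 16-bit
grayscale images, plus a binary lesion mask per view and a study-level
label in {normal, benign, malignant}.

The phantom is deliberately simple: a half-elliptical "breast" of
band-limited noise texture (the stand-in for parenchymal tissue) over a
dark background, with the flat chest-wall edge on the left for
left-laterality views and on the right for right-laterality views, so the
standard half-image crop retains the tissue. Malignant studies carry a
lesion complex — a low-contrast Gaussian mass plus a cluster of compact,
high-intensity microcalcification-like specks, the high-spatial-frequency
evidence that lossy compression destroys first — whose half-peak contour
defines the ground-truth mask. Benign studies carry smooth low-contrast
masses with no annotated mask (screening annotations exist only for
malignant findings). Every view, whatever its label, also receives a few
dense-tissue islands drawn from the same smooth-mass family, so the bare
presence of a blob carries no class signal: discriminating malignant from
the rest requires the speck detail, and the phantom's class signal
degrades with compression the way fine structure in real mammograms
does.

The module also implements the cohort-selection filter applied to a
longitudinal subject manifest: non-malignant subjects qualify through two
consecutive exams at least a year apart with an unchanged BI-RADS score
(their most recent exam is kept); malignant subjects qualify through
surgery (their latest, i.e. preoperative, exam is kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

VIEWS = ("LCC", "LMLO", "RCC", "RMLO")
LABELS = ("normal", "benign", "malignant")

MAX_I = 65535  # 16-bit white level

# Phantom intensity program (16-bit counts). Chosen once to resemble the
# dynamic range of digital mammography after windowing: bright-ish tissue
# over a dark field, texture strong enough that lossy compression has
# structure to destroy.
_TISSUE_MEAN = 22000.0
_TISSUE_TEXTURE_SD = 3500.0
_TEXTURE_SMOOTH_SIGMA = 3.0  # px; low-pass cutoff of the parenchymal texture
_FIELD_MEAN = 600.0
_FIELD_SD = 150.0
_LESION_AMP = 18000.0  # peak lesion contrast at separability = 1


@dataclass
class ViewImage:
    """One projection view: 2-D uint16 pixels plus its view tag."""

    pixels: np.ndarray
    view: str

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValueError(f"unknown view tag {self.view!r}")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint16 or self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D uint16 array")
        if min(self.pixels.shape) < 16:
            raise ValueError("view smaller than 16 px per side")

    @property
    def laterality(self) -> str:
        return "left" if self.view[0] == "L" else "right"

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LesionMask:
    """Binary annotation congruent to its view; absent masks are all-zero."""

    mask: np.ndarray
    present: bool

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if not self.present and self.mask.any():
            raise ValueError("absent mask must be all-zero")


@dataclass
class StudyRecord:
    """One subject's four views, masks, label and manifest metadata."""

    subject_id: str
    views: dict[str, ViewImage]
    masks: dict[str, LesionMask]
    label: str
    exam_date: pd.Timestamp
    birads: int

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if set(self.views) != set(VIEWS) or set(self.masks) != set(VIEWS):
            raise ValueError("study must carry exactly the four standard views")
        for v in VIEWS:
            if self.masks[v].mask.shape != self.views[v].pixels.shape:
                raise ValueError(f"mask/view shape mismatch for {v}")
        if self.label == "normal" and self.birads != 1:
            raise ValueError("normal studies carry BI-RADS 1")
        if self.label == "benign" and self.birads not in (2, 3):
            raise ValueError("benign studies carry BI-RADS 2 or 3")
        if self.label == "malignant" and not any(
                m.present for m in self.masks.values()):
            raise ValueError("malignant study needs at least one present mask")


def _tissue_region(height: int, width: int, view: str) -> np.ndarray:
    """Half-ellipse breast footprint, flat side on the chest-wall edge."""
    yy, xx = np.mgrid[0:height, 0:width]
    left = view[0] == "L"
    x0 = 0.0 if left else width - 1.0
    a = 0.82 * width
    # MLO projections show a taller tissue profile than CC
    b = (0.46 if view.endswith("MLO") else 0.42) * height
    return ((xx - x0) / a) ** 2 + ((yy - height / 2) / b) ** 2 <= 1.0


def _lesion_center(rng, height, width, view) -> tuple[float, float]:
    """A position that survives the half-crop and fifth-crop: near the
    chest wall horizontally, mid-image vertically."""
    left = view[0] == "L"
    fx = rng.uniform(0.08, 0.38)
    cx = fx * (width - 1) if left else (1 - fx) * (width - 1)
    cy = rng.uniform(0.32, 0.64) * (height - 1)
    return cy, cx


def _radial_blob(height, width, cy, cx, sigma):
    yy, xx = np.ogrid[0:height, 0:width]
    return np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2)))


def _lesion_complex(rng, height, width, view, amp) -> np.ndarray:
    """The malignant phenotype: a low-contrast mass plus a cluster of
    sharp, microcalcification-like Gaussian specks — compact,
    high-contrast, high-spatial-frequency evidence."""
    cy, cx = _lesion_center(rng, height, width, view)
    return _complex_at(rng, height, width, cy, cx, amp, smooth_sigma=None)


def _complex_at(rng, height, width, cy, cx, amp,
                smooth_sigma: float | None) -> np.ndarray:
    field = 0.35 * amp * _radial_blob(height, width, cy, cx,
                                      rng.uniform(0.040, 0.060) * width)
    cluster_sigma = 0.035 * width
    for _ in range(int(rng.integers(6, 13))):
        sy = cy + rng.normal(0, cluster_sigma)
        sx = cx + rng.normal(0, cluster_sigma)
        s = rng.uniform(0.007, 0.013) * width
        a = amp * rng.uniform(0.7, 1.0)
        if smooth_sigma is not None:
            a *= s * s / (s * s + smooth_sigma ** 2)  # energy-conserving
            s = np.sqrt(s * s + smooth_sigma ** 2)
        field += a * _radial_blob(height, width, sy, sx, s)
    return field


def _benign_structure(rng, height, width, cy, cx, amp) -> np.ndarray:
    """The benign/dense-tissue phenotype: a smooth structure with no
    speck-scale detail, drawn from a mixture of two families.

    Half are the malignant construction convolved with a Gaussian of
    2.5-4.0 % of image width (closed form per speck, energy conserved) —
    these share the complex's extended, lumpy low-frequency footprint and
    its integrated energy, so once heavy compression blurs a real complex
    the two are indistinguishable. The other half are single smooth
    masses parameterized by integrated energy, drawn to straddle the
    complex's energy budget (~600 x amp px^2) and post-blur width.
    Either way the smallest feature scale is several times the speck
    scale, so under mild compression the sharp specks remain the one
    reliable marker of malignancy.
    """
    if rng.random() < 0.5:
        return _complex_at(rng, height, width, cy, cx, amp,
                           smooth_sigma=rng.uniform(0.025, 0.040) * width)
    sigma = rng.uniform(0.042, 0.065) * width
    energy = rng.uniform(420, 780) * amp * (width / 256) ** 2
    peak = energy / (2 * np.pi * sigma ** 2)
    return peak * _radial_blob(height, width, cy, cx, sigma)


def generate_study(rng_seed: int, label: str, width: int = 256,
                   height: int = 320, separability: float = 0.8,
                   subject_id: str = "S00000",
                   exam_date=None, birads: int | None = None) -> StudyRecord:
    """Generate one four-view study.

    Parameters
    ----------
    rng_seed : int
        Fully determines the pixel content; same seed, same study.
    label : {"normal", "benign", "malignant"}
    width, height : int
        View dimensions in pixels; at least 64 each so a lesion fits.
    separability : float in (0, 1]
        Lesion contrast relative to the background texture. At 1 the
        malignant lesion peaks ~5 texture standard deviations above the
        tissue; lower values blend it into the parenchyma.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    if width < 64 or height < 64:
        raise ValueError("views must be at least 64x64 to place a lesion")
    if not 0 < separability <= 1:
        raise ValueError("separability must lie in (0, 1]")

    rng = np.random.default_rng(rng_seed)
    # multifocality is class-symmetric so lesion count carries no signal
    affected = rng.choice(["left", "right"]) if label != "normal" else None
    n_lesions = 1 + (rng.random() < 0.15)

    views: dict[str, ViewImage] = {}
    masks: dict[str, LesionMask] = {}
    for view in VIEWS:
        tissue = _tissue_region(height, width, view)
        noise = rng.standard_normal((height, width))
        texture = gaussian_filter(noise, _TEXTURE_SMOOTH_SIGMA)
        texture *= _TISSUE_TEXTURE_SD / texture.std()
        img = np.where(tissue, _TISSUE_MEAN + texture,
                       _FIELD_MEAN + _FIELD_SD / _TISSUE_TEXTURE_SD * texture)
        mask = np.zeros((height, width), dtype=bool)
        present = False

        side = "left" if view[0] == "L" else "right"
        amp = separability * _LESION_AMP
        # dense-tissue islands: smooth benign-looking distractors present
        # in every class, so neither "a blob is visible" nor "the
        # brightest blob" carries label signal; only the fine structure
        # of a malignant complex does
        for _ in range(int(rng.integers(2, 6))):
            dy = rng.uniform(0.15, 0.80) * (height - 1)
            dx_f = rng.uniform(0.05, 0.60)
            dx = dx_f * (width - 1) if side == "left" else (1 - dx_f) * (width - 1)
            img = img + _benign_structure(rng, height, width, dy, dx, amp)
        if label == "malignant" and side == affected:
            for _ in range(n_lesions):
                field = _lesion_complex(rng, height, width, view, amp)
                img = img + field
                mask |= field > field.max() / 2  # half-peak contour
            present = True
        elif label == "benign" and side == affected:
            # a benign finding comes from the same smooth family as the
            # dense-tissue islands: visible, but carrying none of the
            # speck detail that marks malignancy
            for _ in range(n_lesions):
                cy, cx = _lesion_center(rng, height, width, view)
                img = img + _benign_structure(rng, height, width, cy, cx, amp)
            # benign findings are not annotated: mask stays absent

        views[view] = ViewImage(np.clip(img, 0, MAX_I).astype(np.uint16), view)
        masks[view] = LesionMask(mask, present)

    if birads is None:
        birads = {"normal": 1,
                  "benign": int(rng.choice([2, 3])),
                  "malignant": int(rng.choice([4, 5]))}[label]
    if exam_date is None:
        exam_date = pd.Timestamp("2013-01-01") + pd.Timedelta(
            days=int(rng.integers(0, 6 * 365)))
    return StudyRecord(subject_id, views, masks, label,
                       pd.Timestamp(exam_date), birads)


def generate_cohort(rng_seed: int, n_subjects: int,
                    class_weights=(0.62, 0.18, 0.20), width: int = 256,
                    height: int = 320, separability: float = 0.8):
    """Generate ``n_subjects`` studies plus a subject manifest.

    ``class_weights`` are the (normal, benign, malignant) proportions; the
    default approximates the roughly 4:1 non-malignant:malignant case mix
    of a screening population enriched for cancer. Label counts are a
    single seeded multinomial draw, so the cohort size is conserved
    exactly.
    """
    w = np.asarray(class_weights, dtype=float)
    if (w < 0).any():
        raise ValueError("class weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("class weights must sum to 1")
    if n_subjects < 10:
        raise ValueError("cohort needs at least 10 subjects")

    rng = np.random.default_rng(rng_seed)
    counts = rng.multinomial(n_subjects, w)
    labels = np.repeat(LABELS, counts)
    rng.shuffle(labels)
    child_seeds = np.random.SeedSequence(rng_seed).spawn(n_subjects)

    studies, rows = [], []
    for i, (label, seed) in enumerate(zip(labels, child_seeds)):
        study = generate_study(seed.generate_state(1)[0] % (2 ** 31),
                               str(label), width, height, separability,
                               subject_id=f"S{i:05d}")
        studies.append(study)
        rows.append({"subject_id": study.subject_id,
                     "exam_date": study.exam_date,
                     "birads": study.birads,
                     "label": study.label,
                     "had_surgery": study.label == "malignant"})
    manifest = pd.DataFrame(rows)
    return studies, manifest


def cohort_filter(manifest: pd.DataFrame) -> list[tuple[str, pd.Timestamp]]:
    """Select at most one exam per subject from a longitudinal manifest.

    Non-malignant subjects qualify when their two most recent exams are at
    least 365 days apart and carry the same BI-RADS score; the most recent
    exam is returned. Malignant subjects qualify when they underwent
    surgery; their latest (preoperative) exam is returned. Unqualifying
    subjects are dropped silently (logged at DEBUG).
    """
    m = manifest.copy()
    m["exam_date"] = pd.to_datetime(m["exam_date"])
    selected: list[tuple[str, pd.Timestamp]] = []
    for sid, grp in m.groupby("subject_id", sort=True):
        grp = grp.sort_values("exam_date")
        if (grp["label"] == "malignant").any():
            if grp["had_surgery"].any():
                selected.append((sid, grp["exam_date"].iloc[-1]))
            else:
                logger.debug("dropping malignant subject %s: no surgery", sid)
            continue
        if len(grp) < 2:
            logger.debug("dropping subject %s: single exam", sid)
            continue
        last, prev = grp.iloc[-1], grp.iloc[-2]
        gap = (last["exam_date"] - prev["exam_date"]).days
        if gap >= 365 and last["birads"] == prev["birads"]:
            selected.append((sid, last["exam_date"]))
        else:
            logger.debug("dropping subject %s: gap %d d or BI-RADS change",
                         sid, gap)
    return selected


# ---------------------------------------------------------------------------
# on-disk layout: 16-bit TIFF views, 8-bit PNG masks, CSV manifest


def save_cohort(studies: list[StudyRecord], manifest: pd.DataFrame,
                outdir) -> Path:
    import tifffile
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for study in studies:
        row = {"subject_id": study.subject_id,
               "exam_date": study.exam_date.date().isoformat(),
               "birads": study.birads, "label": study.label,
               "had_surgery": study.label == "malignant"}
        for view in VIEWS:
            img_path = outdir / "images" / f"{study.subject_id}_{view}.tif"
            tifffile.imwrite(img_path, study.views[view].pixels)
            row[f"path_{view}"] = str(img_path.relative_to(outdir))
            mask = study.masks[view]
            if mask.present:
                mask_path = outdir / "images" / f"{study.subject_id}_{view}_mask.png"
                Image.fromarray(mask.mask.astype(np.uint8) * 255).save(mask_path)
                row[f"mask_{view}"] = str(mask_path.relative_to(outdir))
            else:
                row[f"mask_{view}"] = ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    return outdir / "manifest.csv"


def load_cohort(indir) -> tuple[list[StudyRecord], pd.DataFrame]:
    import tifffile
    from PIL import Image

    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv",
                           dtype={"subject_id": str}, keep_default_na=False)
    studies = []
    for _, row in manifest.iterrows():
        views, masks = {}, {}
        for view in VIEWS:
            pixels = tifffile.imread(indir / row[f"path_{view}"])
            views[view] = ViewImage(pixels.astype(np.uint16), view)
            mp = row[f"mask_{view}"]
            if mp:
                mask = np.array(Image.open(indir / mp)) > 0
                masks[view] = LesionMask(mask, True)
            else:
                masks[view] = LesionMask(np.zeros_like(pixels, dtype=bool), False)
        studies.append(StudyRecord(row["subject_id"], views, masks,
                                   row["label"], pd.Timestamp(row["exam_date"]),
                                   int(row["birads"])))
    cols = ["subject_id", "exam_date", "birads", "label", "had_surgery"]
    return studies, manifest[cols].assign(
        exam_date=pd.to_datetime(manifest["exam_date"]))
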