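"""JPEG 2000 compression to a target compression ratio, with CR and PSNR
accounting.

The compression ratio is defined on the raw pixel buffer: CR =
(width x height x bytes-per-sample) / codestream bytes, which is
container-independent. Encoding goes through Pillow's OpenJPEG binding in
"rates" quality mode; because the encoder honours a requested rate only
approximately, :func:`compress_to_target_cr` bisects the requested rate on
a log scale until the achieved CR lands within a relative tolerance of the
target.

PSNR follows the 16-bit convention 10*log10((2^b - 1)^2 / MSE); an exact
reconstruction, whose PSNR is infinite, is reported with the conventional
label 100.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image

PSNR_PERFECT_LABEL = 100.0


class CompressionError(RuntimeError):
    """Raised when a target CR cannot be reached for an image."""


@dataclass
class RateControlConfig:
    tolerance: float = 0.10      # relative CR tolerance
    max_iterations: int = 20     # bisection budget
    bit_depth: int = 16

    def __post_init__(self):
        if not 0 < self.tolerance <= 0.5:
            raise ValueError("tolerance must lie in (0, 0.5]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")


@dataclass
class CompressionResult:
    codestream: bytes
    target_cr: float
    achieved_cr: float
    psnr_db: float
    original_bytes: int
    compressed_bytes: int


def compute_psnr(source: np.ndarray, reconstruction: np.ndarray,
                 bit_depth: int = 16) -> float:
    """Peak signal-to-noise ratio in dB; 100.0 labels the exact case."""
    source = np.asarray(source)
    reconstruction = np.asarray(reconstruction)
    if source.shape != reconstruction.shape:
        raise ValueError("source and reconstruction shapes differ")
    if source.size == 0:
        raise ValueError("empty image")
    mse = np.mean((source.astype(np.float64)
                   - reconstruction.astype(np.float64)) ** 2)
    if mse == 0:
        return PSNR_PERFECT_LABEL
    max_i = 2 ** bit_depth - 1
    return float(10.0 * np.log10(max_i ** 2 / mse))


def compute_cr(original_bytes: int, compressed_bytes: int) -> float:
    """CR = original size / compressed size (e.g. 30 MB -> 3 MB is CR 10)."""
    if original_bytes <= 0 or compressed_bytes <= 0:
        raise ValueError("byte counts must be positive")
    return original_bytes / compressed_bytes


def _to_pil(pixels: np.ndarray) -> Image.Image:
    if pixels.dtype == np.uint16:
        return Image.fromarray(pixels)  # mode I;16
    if pixels.dtype == np.uint8:
        return Image.fromarray(pixels, mode="L")
    raise ValueError("pixels must be uint8 or uint16")


def _encode(pixels: np.ndarray, rate: float | None, jp2: bool = False) -> bytes:
    """One OpenJPEG encode. ``rate=None`` means lossless (reversible 5/3).

    Raw J2K codestreams (no JP2 container) keep the byte count free of
    container metadata; ``jp2=True`` switches the wrapper on.
    """
    buf = io.BytesIO()
    kwargs: dict = {"format": "JPEG2000", "no_jp2": not jp2}
    if rate is None:
        kwargs["irreversible"] = False
    else:
        kwargs.update(irreversible=True, quality_mode="rates",
                      quality_layers=[float(rate)])
    _to_pil(pixels).save(buf, **kwargs)
    return buf.getvalue()


def encode_lossless(pixels: np.ndarray) -> bytes:
    return _encode(pixels, rate=None)


def decode(codestream: bytes) -> np.ndarray:
    """Decode a JP2/J2K codestream back to its pixel array."""
    try:
        img = Image.open(io.BytesIO(codestream))
        arr = np.array(img)
    except Exception as exc:  # corrupt/truncated stream
        raise CompressionError(f"cannot decode codestream: {exc}") from exc
    if arr.dtype == np.int32:  # Pillow may promote 16-bit to I
        arr = arr.astype(np.uint16)
    return arr


def probe_max_cr(pixels: np.ndarray) -> float:
    """Largest CR the encoder can reach for this image (codestream floor)."""
    floor_bytes = len(_encode(pixels, rate=1e9))
    return pixels.nbytes / floor_bytes


def compress_to_target_cr(pixels: np.ndarray, target_cr: float,
                          config: RateControlConfig | None = None
                          ) -> CompressionResult:
    """Encode ``pixels`` so the achieved CR lands within ``config.tolerance``
    of ``target_cr``.

    ``target_cr == 1`` is the uncompressed condition: the image is stored
    losslessly, the decode is bit-exact and PSNR carries the exact-case
    label. For lossy targets the requested encoder rate is bisected in log
    space; if even the encoder's smallest possible codestream cannot reach
    the target, a :class:`CompressionError` names the best achievable CR.
    """
    config = config or RateControlConfig()
    if target_cr < 1:
        raise ValueError("target CR must be >= 1")
    pixels = np.asarray(pixels)
    original_bytes = pixels.nbytes

    if target_cr == 1:
        stream = encode_lossless(pixels)
        return CompressionResult(stream, 1.0, compute_cr(original_bytes, len(stream)),
                                 PSNR_PERFECT_LABEL, original_bytes, len(stream))

    tol = config.tolerance
    max_cr = probe_max_cr(pixels)
    if max_cr < target_cr * (1 - tol):
        raise CompressionError(
            f"target CR {target_cr:g} unreachable for a "
            f"{pixels.shape[0]}x{pixels.shape[1]} image; best achievable "
            f"CR is {max_cr:.1f}")

    def achieved(rate):
        stream = _encode(pixels, rate)
        return stream, compute_cr(original_bytes, len(stream))

    # first shot: ask for the target directly — OpenJPEG is usually close
    rate = float(target_cr)
    stream, cr = achieved(rate)
    lo, hi = None, None  # rates bracketing the target from below/above
    best = (stream, cr, rate)
    for _ in range(config.max_iterations):
        if abs(cr / target_cr - 1) <= tol:
            break
        if abs(cr / target_cr - 1) < abs(best[1] / target_cr - 1):
            best = (stream, cr, rate)
        if cr < target_cr:
            lo = rate
            rate = np.sqrt(rate * hi) if hi is not None else rate * 2.0
        else:
            hi = rate
            rate = np.sqrt(rate * lo) if lo is not None else rate / 2.0
        stream, cr = achieved(rate)
    else:
        stream, cr, rate = best

    recon = decode(stream)
    psnr = compute_psnr(pixels, recon, config.bit_depth)
    return CompressionResult(stream, float(target_cr), cr, psnr,
                             original_bytes, len(stream))


def compress_study_views(study, target_cr: float,
                         config: RateControlConfig | None = None) -> dict:
    """Compress all four views of a study; returns view -> CompressionResult."""
    return {view: compress_to_target_cr(vi.pixels, target_cr, config)
            for view, vi in study.views.items()}
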