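"""Binary cross-entropy on logits, numerically stable, with its gradient."""

from __future__ import annotations

import numpy as np


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean BCE loss and d(loss)/d(logits).

    Uses the log-sum-exp form ``max(z,0) - z*y + log(1+exp(-|z|))`` so large
    logits of either sign do not overflow.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad.astype(logits.dtype)
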