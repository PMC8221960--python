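"""DoReFa-style uniform quantizers for low-bit-width network weights/activations.

The forward pass maps values onto a ``2^k``-level uniform grid; during
training the backward pass treats every quantizer as the identity (the
straight-through estimator), so the latent full-precision parameters receive
the gradients computed at the quantized point.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["quantize_value", "quantize_weights", "quantize_activations", "FULL_PRECISION"]

FULL_PRECISION = "full"


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest with ties away from zero (inputs here are >= 0)."""
    return np.floor(x + 0.5)


def quantize_value(r: np.ndarray | float, k: int) -> np.ndarray | float:
    """k-bit uniform quantization ``Q(r, k) = round((2^k - 1) r) / (2^k - 1)``.

    Both input and output live in [0, 1]; out-of-range inputs are clipped with
    a warning (callers are expected to guarantee the range).
    """
    if k < 1:
        raise ValueError(f"bit width must be >= 1, got {k}")
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        warnings.warn("quantize_value input outside [0, 1]; clipping")
        arr = np.clip(arr, 0.0, 1.0)
    levels = float(2**k - 1)
    out = _round_half_away(levels * arr) / levels
    return out if np.ndim(r) else float(out)


def quantize_weights(w: np.ndarray, k: int | str) -> np.ndarray:
    """k-bit weight quantization onto [-1, 1] (DoReFa scheme).

    For ``k > 1``: ``W_k = 2 Q(tanh(W) / (2 max|tanh(W)|) + 1/2, k) - 1``.
    For ``k = 1`` the binarised form ``sign(W) * E(|W|)`` is used, with the
    layer-wide mean absolute weight as the scale and ``sign(0) = 0``.
    ``k='full'`` returns the weights unchanged.
    """
    w = np.asarray(w, dtype=w.dtype if isinstance(w, np.ndarray) else float)
    if k == FULL_PRECISION:
        return w
    if k < 1:
        raise ValueError(f"bit width must be >= 1, got {k}")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    if k == 1:
        return np.sign(w) * np.abs(w).mean()
    th = np.tanh(w)
    scale = np.max(np.abs(th))
    if scale == 0:
        return np.zeros_like(w)
    q = quantize_value(th / (2.0 * scale) + 0.5, k)
    return (2.0 * q - 1.0).astype(w.dtype)


def quantize_activations(a: np.ndarray, k: int | str) -> np.ndarray:
    """k-bit activation quantization: clamp to [0, 1], then ``Q(., k)``.

    Upstream batch-normalisation and ReLU keep activations mostly within
    [0, 1]; the clamp enforces the quantizer's domain on the remainder.
    """
    a = np.asarray(a)
    if k == FULL_PRECISION:
        return a
    if k < 1:
        raise ValueError(f"bit width must be >= 1, got {k}")
    clipped = np.clip(a, 0.0, 1.0)
    levels = float(2**k - 1)
    return (_round_half_away(levels * clipped) / levels).astype(a.dtype)
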