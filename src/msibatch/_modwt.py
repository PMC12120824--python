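"""Maximal-overlap discrete wavelet transform (MODWT) with circular boundary.

The MODWT is the shift-invariant, non-decimated variant of the DWT: it is
defined for any series length (no power-of-2 requirement), every level has
one coefficient per time point, and the transform conserves energy
(sum of squared coefficients over all detail levels plus the final smooth
equals the squared norm of the input).  Wavelet filter coefficients are
taken from PyWavelets and rescaled by 1/sqrt(2) as the transform requires.

All routines operate column-wise on a (n_times, n_series) matrix so a whole
feature table can be decomposed in one call.
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["modwt", "imodwt", "max_level"]


def _filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    g = np.asarray(w.dec_lo, dtype=float) / np.sqrt(2.0)  # scaling
    h = np.asarray(w.dec_hi, dtype=float) / np.sqrt(2.0)  # wavelet
    return g, h


def max_level(n: int) -> int:
    """Default decomposition depth: floor(log2 n)."""
    if n < 2:
        raise ValueError("need at least 2 time points")
    return int(np.floor(np.log2(n)))


def modwt(x: np.ndarray, wavelet: str = "haar", level: int | None = None):
    """Decompose each column of ``x`` into MODWT detail and smooth coefficients.

    Returns ``(details, smooth)`` where ``details`` is a list of J arrays,
    each the same shape as ``x`` (level 1 first), and ``smooth`` is the
    final-level scaling coefficient array.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    squeeze = False
    if x.shape[0] == 1 and x.ndim == 2 and x.size == max(x.shape):
        # a 1-D input arrives as a row; treat it as a single series
        x = x.T
        squeeze = True
    n = x.shape[0]
    j_max = max_level(n)
    level = j_max if level is None else level
    if not 1 <= level <= j_max:
        raise ValueError(f"level must be in [1, {j_max}] for n={n}")
    g, h = _filters(wavelet)
    v = x
    details = []
    for j in range(1, level + 1):
        shift = 2 ** (j - 1)
        w_j = np.zeros_like(v)
        v_j = np.zeros_like(v)
        for l, (gl, hl) in enumerate(zip(g, h)):
            rolled = np.roll(v, shift * l, axis=0)  # v[(t - 2^{j-1} l) mod n]
            w_j += hl * rolled
            v_j += gl * rolled
        details.append(w_j)
        v = v_j
    if squeeze:
        details = [d[:, 0] for d in details]
        v = v[:, 0]
    return details, v


def imodwt(details, smooth, wavelet: str = "haar") -> np.ndarray:
    """Invert :func:`modwt`; exact to floating-point roundoff."""
    g, h = _filters(wavelet)
    one_d = np.asarray(smooth).ndim == 1
    as2d = (lambda a: np.asarray(a, dtype=float)[:, None]) if one_d else (
        lambda a: np.asarray(a, dtype=float)
    )
    v = as2d(smooth)
    for j in range(len(details), 0, -1):
        shift = 2 ** (j - 1)
        w_j = as2d(details[j - 1])
        v_prev = np.zeros_like(v)
        for l, (gl, hl) in enumerate(zip(g, h)):
            v_prev += hl * np.roll(w_j, -shift * l, axis=0)
            v_prev += gl * np.roll(v, -shift * l, axis=0)
        v = v_prev
    return v[:, 0] if one_d else v
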