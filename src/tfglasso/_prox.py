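"""Proximal operators used by the operator-splitting solver.

The fused penalty decomposes along each block-position's time chain, so its
proximal step is an exact 1-D total-variation denoising (Condat's direct
algorithm) followed by soft thresholding -- the prox of ``l1 + TV`` equals
soft thresholding composed with the TV prox.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tv1d_rows", "soft_threshold"]


@njit(cache=True)
def _tv1d(y, lam, x):
    # Condat's direct total-variation denoising algorithm (exact for chains).
    n = y.shape[0]
    if n == 1 or lam <= 0.0:
        for i in range(n):
            x[i] = y[i]
        return
    k = 0
    k0 = 0
    km = 0
    kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            if umin < 0.0:
                for i in range(k0, km + 1):
                    x[i] = vmin
                km += 1
                k = km
                k0 = km
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
            elif umax > 0.0:
                for i in range(k0, kp + 1):
                    x[i] = vmax
                kp += 1
                k = kp
                k0 = kp
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
            else:
                vmin += umin / (k - k0 + 1)
                for i in range(k0, n):
                    x[i] = vmin
                return
            if k == n:
                x[n - 1] = vmin - umin
                return
            continue
        if y[k + 1] + umin < vmin - lam:
            for i in range(k0, km + 1):
                x[i] = vmin
            km += 1
            k = km
            k0 = km
            kp = km
            vmin = y[k]
            vmax = y[k] + 2.0 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:
            for i in range(k0, kp + 1):
                x[i] = vmax
            kp += 1
            k = kp
            k0 = kp
            km = kp
            vmin = y[k] - 2.0 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                km = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kp = k


@njit(cache=True)
def tv1d_rows(A, lam):
    """Row-wise exact 1-D total-variation prox of a (chains x length) array."""
    out = np.empty_like(A)
    for r in range(A.shape[0]):
        _tv1d(A[r], lam, out[r])
    return out


def soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    """Element-wise soft thresholding; exact zeros for |x| <= t."""
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)
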