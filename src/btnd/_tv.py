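"""Exact 1-D total-variation proximal operator (taut-string, Condat's
direct algorithm) and the fused-lasso prox built on top of it.

These are the inner primitives of the activation-profile update: the
penalized form of the sparsity+compactness budget is solved by composing
the TV prox, soft-thresholding, and non-negativity clipping.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _tv1d_denoise(y: np.ndarray, lam: float, out: np.ndarray) -> None:
    # Direct non-iterative taut-string algorithm; O(N) typical case.
    width = y.shape[0]
    if width == 0:
        return
    if lam <= 0.0:
        out[:] = y
        return
    k = 0
    k0 = 0
    umin = lam
    umax = -lam
    vmin = y[0] - lam
    vmax = y[0] + lam
    kplus = 0
    kminus = 0
    twolam = 2.0 * lam
    while True:
        while k == width - 1:
            if umin < 0.0:
                while k0 <= kminus:
                    out[k0] = vmin
                    k0 += 1
                k = k0
                kminus = k
                vmin = y[k]
                umin = lam
                umax = vmin + umin - vmax
            elif umax > 0.0:
                while k0 <= kplus:
                    out[k0] = vmax
                    k0 += 1
                k = k0
                kplus = k
                vmax = y[k]
                umax = -lam
                umin = vmax + umax - vmin
            else:
                vmin += umin / (k - k0 + 1)
                while k0 <= k:
                    out[k0] = vmin
                    k0 += 1
                return
        if y[k + 1] + umin < vmin - lam:
            while k0 <= kminus:
                out[k0] = vmin
                k0 += 1
            k = k0
            kminus = k
            kplus = k
            vmin = y[k]
            vmax = vmin + twolam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:
            while k0 <= kplus:
                out[k0] = vmax
                k0 += 1
            k = k0
            kminus = k
            kplus = k
            vmax = y[k]
            vmin = vmax - twolam
            umin = lam
            umax = -lam
        else:
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                kminus = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kplus = k


def tv_prox(y: np.ndarray, lam: float) -> np.ndarray:
    """argmin_x 0.5*||x - y||^2 + lam * sum_t |x_{t+1} - x_t|."""
    y = np.ascontiguousarray(y, dtype=np.float64)
    out = np.empty_like(y)
    _tv1d_denoise(y, float(lam), out)
    return out


def fused_lasso_nonneg_prox(y: np.ndarray, l1: float, tv: float) -> np.ndarray:
    """argmin_{x >= 0} 0.5*||x - y||^2 + l1*sum|x_t| + tv*sum|x_{t+1}-x_t|.

    Computed as TV prox, then soft-threshold, then clip at zero; the
    soft-threshold of a TV-prox solution is the exact prox of the combined
    penalty, and clipping realizes the non-negativity constraint.
    """
    x = tv_prox(y, tv)
    # soft-threshold composed with the nonneg clip collapses to max(x - l1, 0)
    return np.maximum(x - l1, 0.0)
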