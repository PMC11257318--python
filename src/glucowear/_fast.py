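"""Numba-compiled inner loops.

Two hot paths live here: the 1 s Euler integration of the glucose ODE and the
application of random convolutional kernels to observation windows. Both are
plain nested loops; numba turns them into machine code while the surrounding
modules stay vectorised numpy/pandas.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def euler_glucose(
    g0: float,
    baseline: float,
    k_clear: float,
    k_meal: float,
    k_ex: float,
    g_floor: float,
    meal_rate: np.ndarray,
    smoothed_activity: np.ndarray,
    noise: np.ndarray,
) -> np.ndarray:
    """Integrate dG/dt at 1 s steps; rates are per minute, arrays per second.

    dG/dt = -k_clear (G - G_b) + k_meal M(t) - k_ex E(t) (G - G_floor) + noise
    """
    n = meal_rate.shape[0]
    dt = 1.0 / 60.0  # minutes per step
    sdt = np.sqrt(dt)
    out = np.empty(n, dtype=np.float64)
    g = g0
    for t in range(n):
        out[t] = g
        drift = (
            -k_clear * (g - baseline)
            + k_meal * meal_rate[t]
            - k_ex * smoothed_activity[t] * (g - g_floor)
        )
        g = g + drift * dt + noise[t] * sdt
        if g < 1.0:
            g = 1.0
    return out


@njit(cache=True)
def recursive_filter(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """First-order recursion y[t] = a*y[t-1] + b*x[t], y[-1] = 0."""
    n = x.shape[0]
    y = np.empty(n, dtype=np.float64)
    acc = 0.0
    for t in range(n):
        acc = a * acc + b * x[t]
        y[t] = acc
    return y


@njit(cache=True)
def apply_kernels_nb(
    X: np.ndarray,  # (n_windows, n_channels, T)
    lengths: np.ndarray,  # (K,) int64
    dilations: np.ndarray,  # (K,) int64
    paddings: np.ndarray,  # (K,) int64
    biases: np.ndarray,  # (K,) float64
    ch_offsets: np.ndarray,  # (K+1,) int64 into channel_idx
    channel_idx: np.ndarray,  # flat int64
    w_offsets: np.ndarray,  # (K+1,) int64 into weights
    weights: np.ndarray,  # flat float64
) -> np.ndarray:
    """PPV and max pooling of every kernel's dilated convolution output."""
    n_windows = X.shape[0]
    T = X.shape[2]
    K = lengths.shape[0]
    F = np.zeros((n_windows, 2 * K), dtype=np.float64)
    buf = np.empty(2 * T, dtype=np.float64)
    for w in range(n_windows):
        for k in range(K):
            l = lengths[k]
            d = dilations[k]
            pad = paddings[k]
            b = biases[k]
            c0 = ch_offsets[k]
            c1 = ch_offsets[k + 1]
            wbase = w_offsets[k]
            start = -pad
            end = T - (l - 1) * d + pad  # exclusive
            n_out = end - start
            for i in range(n_out):
                buf[i] = b
            # tap-outer, position-inner: contiguous streaming accumulation
            for ci in range(c0, c1):
                xc = X[w, channel_idx[ci]]
                wk = wbase + (ci - c0) * l
                for j in range(l):
                    wj = weights[wk + j]
                    # positions i with 0 <= i + j*d < T (zero padding outside)
                    lo = start
                    if lo < -j * d:
                        lo = -j * d
                    hi = end
                    if hi > T - j * d:
                        hi = T - j * d
                    off = j * d + start
                    for i in range(lo - start, hi - start):
                        buf[i] += wj * xc[i + off]
            ppv = 0
            mx = -np.inf
            for i in range(n_out):
                z = buf[i]
                if z > 0.0:
                    ppv += 1
                if z > mx:
                    mx = z
            F[w, 2 * k] = ppv / n_out
            F[w, 2 * k + 1] = mx
    return F
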