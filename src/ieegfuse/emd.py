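"""Empirical mode decomposition by envelope sifting.

Implements the classic sifting scheme: local extrema are interpolated
with cubic splines to form upper and lower envelopes, the envelope mean
is subtracted, and sifting stops when the normalized squared change
between iterations (Huang's SD criterion) falls below a threshold.
Extraction stops when the requested number of intrinsic mode functions
(IMFs) is reached or the residual has too few extrema to oscillate.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["emd", "fuzzy_entropy"]


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    # collapse flat runs so plateaus register a single extremum
    d_sign = np.sign(d)
    nz = d_sign != 0
    if not nz.any():
        return np.array([], int), np.array([], int)
    filled = d_sign.copy()
    # forward-fill zero signs with the previous non-zero sign
    idx = np.where(nz, np.arange(filled.size), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = d_sign[idx]
    turns = np.diff(filled)
    maxima = np.where(turns < 0)[0] + 1
    minima = np.where(turns > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    n = x.size
    # anchor the envelope at the signal endpoints to limit edge swings
    xs = np.concatenate(([0], idx, [n - 1]))
    ys = np.concatenate(([x[0]], x[idx], [x[-1]]))
    xs, keep = np.unique(xs, return_index=True)
    return CubicSpline(xs, ys[keep])(np.arange(n))


def emd(
    x: np.ndarray,
    max_imfs: int = 5,
    sd_thresh: float = 0.2,
    max_siftings: int = 50,
) -> list[np.ndarray]:
    """Decompose ``x`` into up to ``max_imfs`` IMFs (residual excluded)."""
    x = np.asarray(x, dtype=float)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residual.copy()
        for _ in range(max_siftings):
            maxima, minima = _local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            m = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
            h_new = h - m
            denom = np.sum(h**2)
            if denom == 0:
                h = h_new
                break
            sd = np.sum((h - h_new) ** 2) / denom
            h = h_new
            if sd < sd_thresh:
                break
        imfs.append(h)
        residual = residual - h
    return imfs


def fuzzy_entropy(
    x: np.ndarray, m: int = 2, r_factor: float = 0.2, power: float = 2.0
) -> float:
    """Fuzzy entropy ``FE = ln O^m - ln O^{m+1}``.

    Template vectors of lengths ``m`` and ``m+1`` are baseline-removed
    (their own mean subtracted), compared under the Chebyshev distance,
    and similarity is graded with the fuzzy membership
    ``exp(-(d/r)^power)`` with ``r = r_factor * SD(x)``.
    """
    x = np.asarray(x, dtype=float)
    r = r_factor * x.std()
    if r == 0 or x.size < m + 2:
        return 0.0

    def phi(mm: int) -> float:
        n_tpl = x.size - m  # same template count for both lengths
        X = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_tpl]
        X = X - X.mean(axis=1, keepdims=True)
        d = np.zeros((n_tpl, n_tpl))
        for k in range(mm):
            np.maximum(d, np.abs(X[:, k, None] - X[None, :, k]), out=d)
        mu = np.exp(-((d / r) ** power))
        np.fill_diagonal(mu, 0.0)
        return float(mu.sum() / (n_tpl * (n_tpl - 1)))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return 0.0
    return float(np.log(p_m) - np.log(p_m1))
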