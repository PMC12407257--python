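"""Periodized orthonormal discrete wavelet transform (Daubechies db4).

A small self-contained filter-bank implementation: the analysis operator is
built from circularly shifted rows of the decomposition filters, which for
an orthonormal wavelet makes the synthesis step the exact transpose, giving
perfect reconstruction on even-length signals.  Signals are padded (edge
replication) up to a multiple of 2**levels and trimmed after reconstruction.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

# db4 scaling (low-pass) decomposition filter, orthonormal: sum h^2 = 1.
DB4_LO = np.array([
    0.23037781330885523, 0.7148465705525415, 0.6308807679295904,
    -0.02798376941698385, -0.18703481171888114, 0.030841381835986965,
    0.032883011666982945, -0.010597401784997278,
])
# high-pass via the quadrature-mirror relation g[k] = (-1)^k h[L-1-k]
DB4_HI = ((-1.0) ** np.arange(len(DB4_LO))) * DB4_LO[::-1]

_FILTERS = {"db4": (DB4_LO, DB4_HI)}


def _dwt_step(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    n = x.size
    if n % 2:
        raise InputError("periodized DWT step needs even length")
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(lo.size)[None, :]) % n
    windows = x[idx]
    return windows @ lo, windows @ hi


def _idwt_step(ca: np.ndarray, cd: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    n = 2 * ca.size
    x = np.zeros(n)
    idx = (2 * np.arange(ca.size)[:, None] + np.arange(lo.size)[None, :]) % n
    np.add.at(x, idx, ca[:, None] * lo[None, :] + cd[:, None] * hi[None, :])
    return x


def wavedec(x: np.ndarray, wavelet: str = "db4", levels: int = 4):
    """Multilevel periodized DWT; returns [cA_L, cD_L, ..., cD_1]."""
    lo, hi = _filters(wavelet)
    coeffs = []
    approx = np.asarray(x, dtype=float)
    for _ in range(levels):
        approx, detail = _dwt_step(approx, lo, hi)
        coeffs.append(detail)
    coeffs.append(approx)
    return coeffs[::-1]


def waverec(coeffs, wavelet: str = "db4"):
    lo, hi = _filters(wavelet)
    approx = coeffs[0]
    for detail in coeffs[1:]:
        approx = _idwt_step(approx, detail, lo, hi)
    return approx


def _filters(wavelet: str):
    if wavelet not in _FILTERS:
        raise InputError(f"unknown wavelet {wavelet!r} (available: db4)")
    return _FILTERS[wavelet]


def denoise(x: np.ndarray, wavelet: str = "db4", levels: int = 4) -> np.ndarray:
    """Soft-threshold wavelet shrinkage at the universal threshold.

    The noise scale is the median absolute deviation of the finest detail
    level divided by 0.6745; the threshold is sigma * sqrt(2 ln n).
    Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 ** levels:
        raise InputError(f"signal too short for {levels} wavelet levels")
    block = 2 ** levels
    pad = (-n) % block
    xp = np.concatenate([x, np.full(pad, x[-1])]) if pad else x
    coeffs = wavedec(xp, wavelet, levels)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    shrunk = [coeffs[0]]
    for d in coeffs[1:]:
        shrunk.append(np.sign(d) * np.maximum(np.abs(d) - thr, 0.0))
    return waverec(shrunk, wavelet)[:n]
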