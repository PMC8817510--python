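"""Empirical Mode Decomposition (EMD) by classical sifting.

EMD decomposes a signal into intrinsic mode functions (IMFs) ordered
fast to slow plus a residual trend.  Each IMF is obtained by repeatedly
subtracting the mean of the upper and lower cubic-spline envelopes of
the running component ("sifting") until the Cauchy-style stopping
criterion SD = sum((h_prev - h)^2) / sum(h_prev^2) falls below a
threshold or a sifting cap is reached.  Envelope end effects are
suppressed by mirroring the two outermost extrema beyond each end of
the record.  Decomposition stops when the residual has too few extrema
to sift (it is then monotone or trivially oscillating) or when
``max_imfs`` is reached.

By construction the IMFs plus the residual reconstruct the input to
floating-point accuracy: the residual is the input minus the extracted
IMFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core import Recording

__all__ = ["IMFSet", "emd_decompose"]


@dataclass
class IMFSet:
    """Ordered IMFs (fast to slow) and the residual of one decomposition."""

    imfs: np.ndarray  # shape (n_imfs, L)
    residual: np.ndarray  # shape (L,)

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs plus the residual."""
        if self.n_imfs == 0:
            return self.residual.copy()
        return self.imfs.sum(axis=0) + self.residual


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local minima and maxima (first sample of a
    plateau run counts as the extremum)."""
    d = np.diff(x)
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return np.array([], int), np.array([], int)
    # carry the following non-zero slope backwards over plateaus
    idx = np.where(nz, np.arange(s.size), s.size)
    idx = np.minimum.accumulate(idx[::-1])[::-1]
    s = np.where(idx < s.size, s[np.minimum(idx, s.size - 1)], s[nz][-1])
    ds = np.diff(s)
    maxima = np.where(ds < 0)[0] + 1
    minima = np.where(ds > 0)[0] + 1
    return minima, maxima


def _envelope(n: int, idx: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through (idx, vals), mirror-extended by the
    two outermost extrema on each side."""
    if idx.size >= 2:
        ti = np.concatenate(([-idx[1]], idx, [2 * (n - 1) - idx[-2]]))
        vi = np.concatenate(([vals[1]], vals, [vals[-2]]))
    else:  # pragma: no cover - callers require >= 2 extrema
        ti, vi = idx, vals
    # mirrored knots must stay strictly increasing
    keep = np.concatenate(([True], np.diff(ti) > 0))
    return CubicSpline(ti[keep], vi[keep])(np.arange(n))


def _sift(x: np.ndarray, sd_threshold: float, max_siftings: int) -> np.ndarray | None:
    """Extract one IMF from ``x``; None when x has too few extrema."""
    h = x
    n = x.size
    for _ in range(max_siftings):
        mn, mx = _extrema_indices(h)
        if mn.size < 2 or mx.size < 2:
            return None if h is x else h
        upper = _envelope(n, mx, h[mx])
        lower = _envelope(n, mn, h[mn])
        m = 0.5 * (upper + lower)
        denom = float(np.sum(h * h))
        h = h - m
        if denom > 0 and float(np.sum(m * m)) / denom < sd_threshold:
            break
    return h


def emd_decompose(
    recording: Recording | np.ndarray,
    max_imfs: int = 16,
    sd_threshold: float = 0.2,
    max_siftings: int = 10,
) -> IMFSet:
    """Decompose a recording into intrinsic mode functions.

    Parameters
    ----------
    recording : Recording or ndarray
        Input signal; at least 16 samples.
    max_imfs : int
        Maximum number of IMFs to extract (>= 4).  Sifting stops earlier
        once the residual is monotone.
    sd_threshold : float
        Cauchy stopping criterion for the inner sifting loop.
    max_siftings : int
        Cap on sifting iterations per IMF.

    Returns
    -------
    IMFSet
        IMFs ordered fast to slow; ``imfs.sum(0) + residual`` equals the
        input to floating-point accuracy.
    """
    x = recording.samples if isinstance(recording, Recording) else np.asarray(recording, float)
    if x.size < 16:
        raise ValueError(f"signal too short to sift: {x.size} samples (need >= 16)")
    if max_imfs < 4:
        raise ValueError(f"max_imfs must be >= 4, got {max_imfs}")

    residual = x.astype(float).copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        imf = _sift(residual, sd_threshold, max_siftings)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
        mn, mx = _extrema_indices(residual)
        if mn.size < 2 or mx.size < 2:
            break
    arr = np.asarray(imfs) if imfs else np.empty((0, x.size))
    return IMFSet(imfs=arr, residual=residual)
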