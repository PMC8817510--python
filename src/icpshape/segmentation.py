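"""Minima-anchored segmentation of the artifact-removed signal.

The AR signal is lowpass filtered (linear-phase FIR, group-delay
compensated) purely to locate segmentation anchors: cardiac and
respiratory oscillations are removed so the remaining extrema reflect
macro-pattern structure.  Minima of the smoothed signal become candidate
subsequence boundaries; a minimum is discarded when its nearest
neighboring maximum is closer than ``eta_dur`` in time or ``eta_mag`` in
magnitude (such minima separate wiggles, not patterns).  Subsequences
are cut from the *unfiltered* AR signal between surviving minima,
sharing boundary samples, and each is z-normalized (zero mean, unit
population standard deviation) so that clustering and matching see
shape, not scale or offset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .core import Recording, Subsequence

__all__ = [
    "FilterSpec",
    "SegmentationParams",
    "Extremum",
    "design_lowpass",
    "smooth",
    "find_extrema",
    "prune_minima",
    "segment",
    "znormalize",
    "zscore",
    "segment_recording",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Lowpass smoothing filter band for anchor extraction.

    Defaults keep sub-0.05 Hz macro structure and reject everything
    above 0.1 Hz (respiration ~0.25 Hz, cardiac ~1 Hz).  ``a_pass`` is
    the maximum passband ripple and ``a_stop`` the minimum stopband
    attenuation, both in dB.
    """

    f_pass: float = 0.05  # Hz, passband edge
    f_stop: float = 0.1  # Hz, stopband edge
    a_pass: float = 0.001  # dB
    a_stop: float = 60.0  # dB

    def validate(self, fs: float) -> None:
        if not 0 < self.f_pass < self.f_stop < fs / 2:
            raise ValueError(
                f"need 0 < f_pass < f_stop < fs/2; got f_pass={self.f_pass}, "
                f"f_stop={self.f_stop}, fs={fs}"
            )
        if self.a_pass <= 0 or self.a_stop <= 0:
            raise ValueError("a_pass and a_stop must be positive")


@dataclass(frozen=True)
class SegmentationParams:
    """Minima-pruning thresholds.

    ``eta_dur`` is in minutes (typical range 0.5-2) and ``eta_mag`` in
    mmHg (typical range 0.5-1.5); defaults are the midpoints.  Both can
    be adapted per recording.
    """

    eta_dur: float = 1.0  # minutes
    eta_mag: float = 1.0  # mmHg

    def __post_init__(self) -> None:
        if self.eta_dur <= 0 or self.eta_mag <= 0:
            raise ValueError("eta_dur and eta_mag must be > 0")


class Extremum(NamedTuple):
    index: int
    value: float
    kind: str  # "min" | "max"


@lru_cache(maxsize=16)
def _design(fs: float, f_pass: float, f_stop: float, a_pass: float, a_stop: float) -> np.ndarray:
    # Kaiser-window minimum-order design.  delta is halved for margin so
    # the realized passband ripple stays within a_pass even though the
    # Kaiser approximation is single-ripple.
    delta_p = 10 ** (a_pass / 20.0) - 1.0
    delta_s = 10 ** (-a_stop / 20.0)
    delta = min(delta_p, delta_s) / 2.0
    atten = -20.0 * np.log10(delta)
    width = (f_stop - f_pass) / (fs / 2.0)
    numtaps, beta = sps.kaiserord(atten, width)
    if numtaps % 2 == 0:
        numtaps += 1  # odd length -> integer group delay, type-I linear phase
    return sps.firwin(numtaps, (f_pass + f_stop) / 2.0, window=("kaiser", beta), fs=fs)


def design_lowpass(fs: float, spec: FilterSpec) -> np.ndarray:
    """Design the linear-phase FIR lowpass for ``fs``; returns its taps."""
    spec.validate(fs)
    return _design(fs, spec.f_pass, spec.f_stop, spec.a_pass, spec.a_stop)


def smooth(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Lowpass filter with group-delay compensation (ARLP signal).

    The input is reflect-padded by half the filter length on each side
    and convolved in 'valid' mode, so the output is time-aligned with
    the input and has the same length.
    """
    taps = design_lowpass(recording.fs, spec)
    half = taps.size // 2
    if recording.n_samples <= half:
        raise ValueError(
            f"recording ({recording.n_samples} samples) shorter than half the "
            f"designed filter ({taps.size} taps, order {taps.size - 1}); "
            f"widen the transition band or use a longer recording"
        )
    padded = np.pad(recording.samples, half, mode="reflect")
    out = sps.fftconvolve(padded, taps, mode="valid")
    assert out.size == recording.n_samples
    return recording.copy(samples=out, id=recording.id)


def find_extrema(smoothed: Recording | np.ndarray) -> list[Extremum]:
    """Interior local extrema of the smoothed signal, strictly alternating.

    The first sample of an equal-valued plateau run is taken as the
    extremum.  A monotone (or constant) signal yields an empty list with
    a warning.
    """
    x = smoothed.samples if isinstance(smoothed, Recording) else np.asarray(smoothed, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    d = np.diff(x)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        warnings.warn("constant signal: no extrema", stacklevel=2)
        return []
    # backward-fill zero slopes with the next non-zero slope so the first
    # sample of a plateau carries the sign change
    pos = np.full(s.size, s.size)
    pos[nz] = nz
    pos = np.minimum.accumulate(pos[::-1])[::-1]
    filled = np.where(pos < s.size, s[np.clip(pos, 0, s.size - 1)], s[nz[-1]])
    ds = np.diff(filled)
    out: list[Extremum] = []
    for i in np.flatnonzero(ds != 0):
        kind = "max" if ds[i] < 0 else "min"
        out.append(Extremum(int(i + 1), float(x[i + 1]), kind))
    if not out:
        warnings.warn("monotone signal: no extrema", stacklevel=2)
    return out


def prune_minima(
    extrema: list[Extremum],
    params: SegmentationParams,
    fs: float,
    *,
    n_samples: int,
) -> np.ndarray:
    """Select boundary minima by the duration/magnitude rules.

    A minimum is removed when, against its nearest neighboring maximum
    (nearest in time among its flanks in the evolving list), the time
    gap is below ``eta_dur`` *or* the magnitude gap is below
    ``eta_mag``.  Minima are visited in time order; after a removal the
    flanking maxima are merged keeping the larger, so subsequent
    candidates see the merged landscape.  The first and last sample of
    the recording are always appended as boundaries.
    """
    eta_dur_samples = params.eta_dur * 60.0 * fs
    work = list(extrema)
    # sanity: alternation
    for a, b in zip(work, work[1:]):
        if a.kind == b.kind:
            raise ValueError("extrema list must strictly alternate min/max")

    i = 0
    while i < len(work):
        e = work[i]
        if e.kind != "min":
            i += 1
            continue
        flanks = [w for w in (work[i - 1] if i > 0 else None,
                              work[i + 1] if i + 1 < len(work) else None)
                  if w is not None and w.kind == "max"]
        if not flanks:
            i += 1
            continue
        nearest = min(flanks, key=lambda m: abs(m.index - e.index))
        dt = abs(nearest.index - e.index)
        dg = abs(nearest.value - e.value)
        if dt < eta_dur_samples or dg < params.eta_mag:
            del work[i]
            # merge now-adjacent maxima, keeping the larger (tie: earlier)
            if 0 < i < len(work) and work[i - 1].kind == "max" and work[i].kind == "max":
                if work[i].value > work[i - 1].value:
                    del work[i - 1]
                else:
                    del work[i]
            i = max(i - 1, 0)
            # re-examine from the previous position: the merged maximum
            # may change the nearest flank of the prior surviving minimum
            # only for later candidates; earlier survivors are final.
            while i < len(work) and work[i].kind != "min":
                i += 1
        else:
            i += 1

    # minima within eta_dur of the forced endpoint boundaries would cut
    # sliver subsequences the duration rule forbids everywhere else
    minima = [
        e.index for e in work
        if e.kind == "min"
        and e.index >= eta_dur_samples
        and n_samples - 1 - e.index >= eta_dur_samples
    ]
    if not minima:
        warnings.warn("no surviving minima: whole recording is one subsequence", stacklevel=2)
    bounds = sorted(set([0] + minima + [n_samples - 1]))
    return np.asarray(bounds, dtype=int)


def segment(recording: Recording, boundaries: np.ndarray | list[int]) -> list[Subsequence]:
    """Cut subsequences from the raw AR signal between boundary pairs.

    Consecutive boundaries (i, j) give inclusive windows sharing their
    boundary sample; the windows tile the recording exactly.
    """
    b = np.asarray(boundaries, dtype=int)
    if b.size < 2:
        raise ValueError("need at least 2 boundaries")
    if np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    if b[0] < 0 or b[-1] > recording.n_samples - 1:
        raise ValueError("boundaries out of range")
    out = []
    for i, j in zip(b[:-1], b[1:]):
        sub = Subsequence(
            parent_id=recording.id,
            i=int(i),
            j=int(j),
            raw=recording.samples[i : j + 1].copy(),
            fs=recording.fs,
        )
        out.append(znormalize(sub))
    return out


def zscore(x: np.ndarray) -> np.ndarray:
    """Z-normalize with the population (divide-by-n) standard deviation."""
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        raise ValueError("constant vector cannot be z-normalized")
    return (x - mu) / sigma


def znormalize(subseq: Subsequence) -> Subsequence:
    """Fill mu, sigma and z on a subsequence (population convention).

    A constant window has sigma = 0; it is flagged degenerate (z stays
    None) and must be excluded from clustering and matching.
    """
    subseq.mu = float(subseq.raw.mean())
    subseq.sigma = float(subseq.raw.std())
    if subseq.sigma == 0.0:
        log.warning(
            "degenerate (constant) subsequence %s[%d:%d] excluded from shape analysis",
            subseq.parent_id, subseq.i, subseq.j,
        )
        subseq.z = None
    else:
        subseq.z = (subseq.raw - subseq.mu) / subseq.sigma
    return subseq


def segment_recording(
    recording: Recording,
    filter_spec: FilterSpec = FilterSpec(),
    params: SegmentationParams = SegmentationParams(),
) -> tuple[list[Subsequence], np.ndarray, Recording]:
    """Smooth, locate pruned minima, and cut z-normalized subsequences.

    Returns ``(subsequences, boundaries, smoothed_recording)``.
    """
    smoothed = smooth(recording, filter_spec)
    extrema = find_extrema(smoothed)
    boundaries = prune_minima(extrema, params, recording.fs, n_samples=recording.n_samples)
    subs = segment(recording, boundaries)
    log.info("segmentation: %d subsequences from %.1f s", len(subs), recording.duration_s)
    return subs, boundaries, smoothed
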