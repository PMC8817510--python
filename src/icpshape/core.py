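"""Shared containers for the pipeline.

The package works on single-channel intracranial-pressure (ICP) recordings:
uniformly sampled pressure series in mmHg, typically 100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """A uniformly sampled pressure time series.

    Parameters
    ----------
    samples : ndarray
        Pressure values in mmHg.
    fs : float
        Sampling rate in Hz. Must be positive.
    id : str
        Free-text label identifying the recording (used as ``parent_id``
        on subsequences derived from it).
    """

    samples: np.ndarray
    fs: float
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def copy(self, samples: np.ndarray | None = None, id: str | None = None) -> "Recording":
        return Recording(
            samples=self.samples.copy() if samples is None else np.asarray(samples, float),
            fs=self.fs,
            id=self.id if id is None else id,
        )


@dataclass
class Subsequence:
    """One segmented window ``g[i, j]`` of a recording.

    ``i`` and ``j`` are inclusive 0-based sample indices into the parent
    recording; adjacent subsequences share their boundary sample.  ``z``
    is the z-normalized form (zero mean, unit population standard
    deviation); it is ``None`` when the window is constant (degenerate).
    """

    parent_id: str
    i: int
    j: int
    raw: np.ndarray
    fs: float
    mu: float = field(default=np.nan)
    sigma: float = field(default=np.nan)
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if not self.i < self.j:
            raise ValueError(f"need i < j, got i={self.i}, j={self.j}")
        if self.raw.size != self.j - self.i + 1:
            raise ValueError(
                f"raw length {self.raw.size} != j - i + 1 = {self.j - self.i + 1}"
            )

    @property
    def n_samples(self) -> int:
        return self.raw.size

    @property
    def duration_s(self) -> float:
        """Duration in seconds, counting the shared boundary sample once."""
        return (self.j - self.i) / self.fs

    @property
    def degenerate(self) -> bool:
        """True when the raw window is constant so z-normalization is undefined."""
        return bool(np.isfinite(self.sigma) and self.sigma == 0.0)
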