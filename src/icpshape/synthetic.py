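"""Synthetic ICP-like recordings with known ground truth.

Real overnight ICP recordings carry a slowly varying baseline on which
macro-patterns (ramps, waves, plateaus, peaks lasting roughly half a
minute to tens of minutes, 0.5-20 mmHg) ride, together with cardiac
(~1 Hz) and respiratory (~0.2-0.3 Hz) oscillations, measurement noise,
and sparse unphysiological spikes shorter than one second.  This module
emulates those features with full bookkeeping (segment boundaries,
per-segment shape labels, spike locations) so every downstream stage of
the pipeline can be tested without patient data.

Macro-pattern segments are concatenated at equal boundary values: every
shape used for a recording starts and ends at its minimum, so ground-truth
boundaries are true local minima, mirroring the minima-anchored
segmentation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Recording

#: All shape kinds known to :func:`template_shape`.
SHAPE_KINDS = (
    "ramp_asym",
    "sinusoid",
    "plateau_wave",
    "ascend",
    "descend",
    "peak",
    "flat_drift",
)

#: Kinds that start and end at their minimum, usable in recordings.
ANCHORED_KINDS = ("ramp_asym", "sinusoid", "plateau_wave", "peak")


def template_shape(kind: str, n: int) -> np.ndarray:
    """Return a unit-amplitude prototype shape of length ``n``.

    Every shape has minimum 0 and maximum 1 (``flat_drift``: maximum
    <= 1) and is deterministic in ``(kind, n)``.

    Kinds
    -----
    ramp_asym
        Asymmetric wave whose ascending phase is longer than its
        descending phase (apex at 80% of the duration).
    sinusoid
        Half-sine arch, symmetric, endpoints at 0.
    plateau_wave
        Rapid smooth rise, sustained plateau, rapid smooth fall -- the
        classical plateau (Lundberg-A-like) morphology.
    ascend / descend
        Monotone ramps 0 -> 1 and 1 -> 0.
    peak
        Narrow Gaussian bump centered in the window.
    flat_drift
        Gentle linear drift of small relative amplitude (max 0.3).
    """
    if n < 8:
        raise ValueError(f"n must be >= 8, got {n}")
    u = np.linspace(0.0, 1.0, n)
    if kind == "sinusoid":
        v = np.sin(np.pi * u)
    elif kind == "ramp_asym":
        # markedly asymmetric: slow build-up over 80% of the duration,
        # fast release -- distinct from the symmetric arch in shape space
        apex = 0.8
        v = np.where(u <= apex, u / apex, (1.0 - u) / (1.0 - apex))
    elif kind == "plateau_wave":
        edge = 0.10
        v = np.ones(n)
        rise = u < edge
        fall = u > 1.0 - edge
        s = u[rise] / edge
        v[rise] = 3 * s**2 - 2 * s**3  # smoothstep
        s = (1.0 - u[fall]) / edge
        v[fall] = 3 * s**2 - 2 * s**3
    elif kind == "ascend":
        v = u.copy()
    elif kind == "descend":
        v = 1.0 - u
    elif kind == "peak":
        # narrow bump riding a low arch: isolated pressure peaks rise
        # from a slow elevation, so the tails slope into the boundaries
        # instead of sitting flat at baseline
        v = np.exp(-0.5 * ((u - 0.5) / 0.08) ** 2) + 0.2 * np.sin(np.pi * u)
    elif kind == "flat_drift":
        return 0.3 * u
    else:
        raise ValueError(
            f"unknown shape kind {kind!r}; valid kinds: {', '.join(SHAPE_KINDS)}"
        )
    v = v - v.min()
    return v / v.max()


@dataclass
class PatternSpec:
    """One entry of the pattern menu: a shape kind with its scale ranges."""

    kind: str
    amp_range: tuple[float, float] = (0.5, 20.0)  # mmHg
    dur_range: tuple[float, float] = (30.0, 1200.0)  # seconds (0.5-20 min)

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(
                f"unknown shape kind {self.kind!r}; valid kinds: {', '.join(SHAPE_KINDS)}"
            )
        if self.amp_range[0] < 0 or self.amp_range[1] < self.amp_range[0]:
            raise ValueError(f"bad amplitude range {self.amp_range}")
        if self.dur_range[0] <= 0 or self.dur_range[1] < self.dur_range[0]:
            raise ValueError(f"bad duration range {self.dur_range}")


def _default_menu() -> list[PatternSpec]:
    # Plausible overnight macro-pattern mix: wave-like and plateau shapes,
    # a few mmHg in amplitude, a few minutes long.
    return [
        PatternSpec("sinusoid", (2.0, 8.0), (240.0, 600.0)),
        PatternSpec("ramp_asym", (2.0, 8.0), (240.0, 600.0)),
        PatternSpec("plateau_wave", (3.0, 10.0), (240.0, 600.0)),
        PatternSpec("peak", (2.0, 8.0), (240.0, 600.0)),
    ]


@dataclass
class SyntheticSpec:
    """Full description of one synthetic recording.

    The seed fully determines the output.  Defaults reflect plausible ICP
    physiology at 100 Hz: an hour of recording, 10 mmHg baseline, cardiac
    oscillation 1.1 Hz / 1.5 mmHg, respiratory 0.25 Hz / 1 mmHg,
    measurement noise 0.3 mmHg (sd), macro-patterns of 4-10 min, and rare
    large spikes (tens of mmHg, under one second, ~2 per hour).
    """

    duration_s: float = 3600.0
    fs: float = 100.0
    baseline_mmHg: float = 10.0
    pattern_menu: list[PatternSpec] = field(default_factory=_default_menu)
    cardiac_hz: float = 1.1
    cardiac_amp_mmHg: float = 1.5
    resp_hz: float = 0.25
    resp_amp_mmHg: float = 1.0
    noise_sd_mmHg: float = 0.3
    n_spikes: int = 2
    spike_amp_mmHg: float = 50.0
    spike_max_width: int = 50  # samples; paper-scale spikes are < 1 s
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if self.noise_sd_mmHg < 0 or self.cardiac_amp_mmHg < 0 or self.resp_amp_mmHg < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")
        if not 1 <= self.spike_max_width:
            raise ValueError("spike_max_width must be >= 1")
        for p in self.pattern_menu:
            if p.kind not in ANCHORED_KINDS:
                raise ValueError(
                    f"shape kind {p.kind!r} does not start and end at its minimum "
                    f"and cannot anchor minima-to-minima joins in a recording; "
                    f"usable kinds: {', '.join(ANCHORED_KINDS)}"
                )


@dataclass
class GroundTruth:
    """Bookkeeping emitted alongside a synthetic recording.

    ``boundaries`` are strictly increasing sample indices (first and last
    sample included); segment ``k`` spans ``boundaries[k]..boundaries[k+1]``
    inclusive and carries ``labels[k]``.  ``spike_indices`` holds the start
    sample of each injected spike; ``spike_spans`` the (start, width) pairs.
    """

    boundaries: np.ndarray
    labels: list[str]
    spike_indices: np.ndarray
    spike_spans: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(self.boundaries) - 1:
            raise ValueError("need one label per consecutive boundary pair")

    def spike_mask(self, n: int, margin: int = 0) -> np.ndarray:
        """Boolean mask of samples covered by spikes, optionally dilated."""
        m = np.zeros(n, dtype=bool)
        for start, width in self.spike_spans:
            m[max(0, start - margin) : min(n, start + width + margin)] = True
        return m


def generate_recording(spec: SyntheticSpec) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic recording with its ground truth.

    Macro-pattern segments are drawn from the pattern menu until the
    requested duration is filled (the final segment absorbs the
    remainder), joined at shared boundary samples where every shape sits
    at its minimum (value 0 before baseline offset).  Cardiac and
    respiratory sinusoids, white Gaussian noise and rectangular spikes of
    1..spike_max_width samples are then superimposed.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    if n < 16:
        raise ValueError("recording too short")

    # --- macro-pattern scaffold -------------------------------------------
    boundaries = [0]
    labels: list[str] = []
    seg_amp: list[float] = []
    min_seg = 8  # samples
    while boundaries[-1] < n - 1:
        p = spec.pattern_menu[rng.integers(len(spec.pattern_menu))]
        dur = rng.uniform(*p.dur_range)
        amp = rng.uniform(*p.amp_range)
        end = boundaries[-1] + max(min_seg, int(round(dur * spec.fs)))
        if end >= n - 1 - min_seg:
            end = n - 1  # final segment absorbs the remainder
        boundaries.append(end)
        labels.append(p.kind)
        seg_amp.append(amp)

    macro = np.zeros(n)
    for k, kind in enumerate(labels):
        i, j = boundaries[k], boundaries[k + 1]
        macro[i : j + 1] = seg_amp[k] * template_shape(kind, j - i + 1)

    # --- oscillations and noise -------------------------------------------
    t = np.arange(n) / spec.fs
    x = spec.baseline_mmHg + macro
    if spec.cardiac_amp_mmHg > 0:
        x = x + spec.cardiac_amp_mmHg * np.sin(2 * np.pi * spec.cardiac_hz * t)
    if spec.resp_amp_mmHg > 0:
        x = x + spec.resp_amp_mmHg * np.sin(2 * np.pi * spec.resp_hz * t)
    if spec.noise_sd_mmHg > 0:
        x = x + rng.normal(0.0, spec.noise_sd_mmHg, n)

    # --- spikes ------------------------------------------------------------
    spike_starts: list[int] = []
    spike_spans: list[tuple[int, int]] = []
    if spec.n_spikes > 0:
        guard = int(2 * spec.fs)  # keep spikes away from the very edges
        lo, hi = guard, max(guard + 1, n - guard - spec.spike_max_width)
        # separate spikes by >= 2 s so flagged episodes stay distinct
        slot = int(2 * spec.fs) + spec.spike_max_width
        n_slots = max(1, (hi - lo) // slot)
        if spec.n_spikes > n_slots:
            raise ValueError(
                f"cannot place {spec.n_spikes} separated spikes in "
                f"{spec.duration_s:g} s at fs={spec.fs:g}"
            )
        slots = np.sort(rng.choice(n_slots, size=spec.n_spikes, replace=False))
        starts = lo + slots * slot + rng.integers(0, max(1, slot - spec.spike_max_width), size=spec.n_spikes)
        for s in starts:
            # log-uniform width: most spikes are a few samples, rarely ~0.5 s
            w = int(np.exp(rng.uniform(0.0, np.log(spec.spike_max_width + 1e-12))))
            w = max(1, min(spec.spike_max_width, w))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            x[s : s + w] += sign * spec.spike_amp_mmHg
            spike_starts.append(int(s))
            spike_spans.append((int(s), w))

    rec = Recording(samples=x, fs=spec.fs, id=f"synthetic-{spec.seed}")
    gt = GroundTruth(
        boundaries=np.asarray(boundaries, int),
        labels=labels,
        spike_indices=np.asarray(spike_starts, int),
        spike_spans=spike_spans,
    )
    return rec, gt


def generate_shape_set(
    kinds: list[str],
    n_per_kind: int,
    m: int = 128,
    noise_sd: float = 0.05,
    length_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw z-normalized shape vectors directly in shape space.

    Emulates what the segmentation + resampling stages hand to the
    clusterer: each vector is a unit-amplitude prototype rendered at a
    random native length, corrupted with white noise of standard
    deviation ``noise_sd`` (relative to unit amplitude), resampled to the
    common length ``m`` and re-z-normalized.

    Returns ``(Z, labels)`` where ``Z`` has shape ``(len(kinds) * n_per_kind, m)``
    and ``labels[i]`` is the index into ``kinds`` of the generating shape.
    """
    from .kshape import resample_to_length

    rng = np.random.default_rng(seed)
    if length_range is None:
        length_range = (m // 2, 2 * m)
    Z = np.empty((len(kinds) * n_per_kind, m))
    labels = np.empty(len(kinds) * n_per_kind, dtype=int)
    row = 0
    for ki, kind in enumerate(kinds):
        for _ in range(n_per_kind):
            n = int(rng.integers(length_range[0], length_range[1] + 1))
            v = template_shape(kind, n) + rng.normal(0.0, noise_sd, n)
            Z[row] = resample_to_length(v, m)
            labels[row] = ki
            row += 1
    return Z, labels
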