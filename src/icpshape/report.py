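"""Reduced box-glyph visualization of a labeled recording.

Each labeled subsequence collapses to a colored box: width = duration,
height = raw max - min, vertical center = raw median, color = template
label (black for UNCLASSIFIED).  A two-panel figure shows the raw trace
above the glyph track on a shared time axis, turning hours of signal
into a strip a clinician can scan.  Geometry always comes from the raw
(non-normalized) subsequence values.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Patch, Rectangle
import numpy as np

from .core import Recording, Subsequence
from .matching import UNCLASSIFIED, MatchResult

__all__ = ["BoxGlyph", "PALETTE", "label_color", "make_glyphs", "render"]

#: Colorblind-safe palette (Okabe-Ito), assigned to labels in sorted
#: order; UNCLASSIFIED is always black.  Stable across figures.
PALETTE = (
    "#E69F00", "#56B4E9", "#009E73", "#F0E442",
    "#0072B2", "#D55E00", "#CC79A7", "#999999",
)


def label_color(label: str) -> str:
    """Deterministic label -> color mapping, stable across figures.

    Labels with a trailing integer (L1..L7) map to palette slots by that
    number; other labels hash to a slot.
    """
    if label == UNCLASSIFIED:
        return "#000000"
    m = re.fullmatch(r"\D*(\d+)", label)
    idx = int(m.group(1)) - 1 if m else zlib.crc32(label.encode())
    return PALETTE[idx % len(PALETTE)]


@dataclass
class BoxGlyph:
    """Reduced representation of one labeled subsequence."""

    x_start: float  # s
    x_end: float  # s
    y_center: float  # mmHg, median of raw window
    height: float  # mmHg, raw max - min
    label: str
    color: str

    def __post_init__(self) -> None:
        if not self.x_start < self.x_end:
            raise ValueError("x_start must be < x_end")
        if self.height < 0:
            raise ValueError("height must be >= 0")


def make_glyphs(
    subsequences: list[Subsequence],
    matches: list[MatchResult],
) -> list[BoxGlyph]:
    """One glyph per subsequence, geometry from the raw signal."""
    if len(subsequences) != len(matches):
        raise ValueError(
            f"{len(subsequences)} subsequences but {len(matches)} matches"
        )
    out = []
    for s, r in zip(subsequences, matches):
        if (s.i, s.j) != (r.i, r.j):
            raise ValueError(
                f"subsequence ({s.i}, {s.j}) does not match result ({r.i}, {r.j})"
            )
        out.append(
            BoxGlyph(
                x_start=s.i / s.fs,
                x_end=s.j / s.fs,
                y_center=float(np.median(s.raw)),
                height=float(np.ptp(s.raw)),
                label=r.best_label,
                color=label_color(r.best_label),
            )
        )
    return out


def render(
    recording: Recording,
    glyphs: list[BoxGlyph],
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Write the two-panel raw + reduced figure (SVG by default).

    Every glyph rectangle carries a ``gid`` (``glyph-<index>``) so the
    vector output remains machine-checkable.
    """
    path = Path(path)
    span = recording.duration_s
    for g in glyphs:
        if g.x_start < 0 or g.x_end > span + 1e-9:
            raise ValueError(f"glyph [{g.x_start}, {g.x_end}] outside recording span")
    fig, (ax_raw, ax_box) = plt.subplots(
        2, 1, sharex=True, figsize=(12, 6),
        gridspec_kw={"height_ratios": [2, 1]},
    )
    ax_raw.plot(recording.time, recording.samples, lw=0.4, color="#333333")
    ax_raw.set_ylabel("ICP (mmHg)")
    ax_raw.set_title(title or recording.id or "recording")
    for k, g in enumerate(glyphs):
        rect = Rectangle(
            (g.x_start, g.y_center - g.height / 2.0),
            g.x_end - g.x_start,
            max(g.height, 1e-6),  # zero-height boxes still visible/parsable
            facecolor=g.color,
            edgecolor="white",
            linewidth=0.3,
        )
        rect.set_gid(f"glyph-{k}")
        ax_box.add_patch(rect)
    if glyphs:
        ax_box.set_xlim(0, span)
        lo = min(g.y_center - g.height / 2 for g in glyphs)
        hi = max(g.y_center + g.height / 2 for g in glyphs)
        pad = 0.05 * max(hi - lo, 1.0)
        ax_box.set_ylim(lo - pad, hi + pad)
        seen: dict[str, str] = {}
        for g in glyphs:
            seen.setdefault(g.label, g.color)
        handles = [Patch(facecolor=c, label=lab) for lab, c in sorted(seen.items())]
        ax_box.legend(handles=handles, loc="upper right", fontsize=7, ncol=4)
    ax_box.set_xlabel("time (s)")
    ax_box.set_ylabel("ICP (mmHg)")
    fig.tight_layout()
    try:
        fig.savefig(path)
    except OSError as exc:
        plt.close(fig)
        raise OSError(f"cannot write figure to {path}: {exc}") from exc
    plt.close(fig)
    return path
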