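"""Template library and correlation-gated shape matching.

Cluster centroids become labeled templates (L1..LK by default) stored in
a versioned, human-readable JSON container.  A new subsequence is
z-normalized, resampled to the library's common length (time rescaling
absorbs duration differences; SBD absorbs residual shift), and compared
to every template by SBD.  The best match's correlation coefficient
CC = 1 - SBD must exceed a threshold (default 0.50) for the label to be
assigned; otherwise the subsequence stays UNCLASSIFIED.  The gate keeps
weak matches from diluting the labeled output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Recording, Subsequence
from .kshape import ClusterModel, resample_to_length, sbd
from .segmentation import FilterSpec, SegmentationParams, segment_recording

__all__ = [
    "UNCLASSIFIED",
    "TemplateLibrary",
    "MatchResult",
    "build_library",
    "match_subsequence",
    "characterize_recording",
    "summarize_matches",
]

log = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"

_FORMAT = "icpshape-template-library"
_VERSION = 1


@dataclass
class TemplateLibrary:
    """Labeled centroid shapes at a common length ``m``."""

    labels: list[str]
    shapes: np.ndarray  # (K, m), each z-normalized
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shapes = np.atleast_2d(np.asarray(self.shapes, float))
        if len(self.labels) != self.shapes.shape[0]:
            raise ValueError("one label per shape required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate template labels: {self.labels}")

    @property
    def m(self) -> int:
        return self.shapes.shape[1]

    @property
    def n_templates(self) -> int:
        return self.shapes.shape[0]

    def relabel(self, labels: list[str]) -> "TemplateLibrary":
        return TemplateLibrary(labels=list(labels), shapes=self.shapes.copy(),
                               provenance=dict(self.provenance))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "format": _FORMAT,
            "version": _VERSION,
            "m": self.m,
            "labels": self.labels,
            "shapes": [list(map(float, row)) for row in self.shapes],
            "provenance": self.provenance,
        }
        path.write_text(json.dumps(doc, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TemplateLibrary":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != _FORMAT:
            raise ValueError(f"{path}: not a template library file")
        if doc.get("version") != _VERSION:
            raise ValueError(
                f"{path}: unsupported library version {doc.get('version')!r} "
                f"(supported: {_VERSION})"
            )
        return cls(labels=list(doc["labels"]),
                   shapes=np.asarray(doc["shapes"], float),
                   provenance=dict(doc.get("provenance", {})))


def build_library(
    model: ClusterModel,
    labels: list[str] | None = None,
    provenance: dict | None = None,
) -> TemplateLibrary:
    """Turn a cluster model's centroids into labeled templates.

    Default labels are L1..LK.  Custom labels must be unique.
    """
    if labels is None:
        labels = [f"L{k}" for k in range(1, model.K + 1)]
    if len(labels) != model.K:
        raise ValueError(f"need {model.K} labels, got {len(labels)}")
    prov = {
        "K": model.K,
        "m": model.m,
        "seed": model.seed,
        "n_iter": model.n_iter,
        "converged": model.converged,
    }
    if provenance:
        prov.update(provenance)
    return TemplateLibrary(labels=list(labels), shapes=model.centroids.copy(),
                           provenance=prov)


@dataclass
class MatchResult:
    """Closest-template result for one subsequence."""

    parent_id: str
    i: int
    j: int
    best_label: str
    sbd: float
    cc: float
    all_distances: dict[str, float] = field(default_factory=dict)
    reason: str | None = None

    @property
    def classified(self) -> bool:
        return self.best_label != UNCLASSIFIED


def match_subsequence(
    subseq: Subsequence | np.ndarray,
    lib: TemplateLibrary,
    cc_threshold: float = 0.50,
    *,
    parent_id: str = "",
    i: int = 0,
    j: int | None = None,
) -> MatchResult:
    """Classify one subsequence against the library.

    Accepts a :class:`Subsequence` (its z-normalized form is used; a
    degenerate one returns UNCLASSIFIED with reason ``degenerate``) or a
    bare vector.  The query is resampled to the library length, SBD to
    every template is computed, and the best label is assigned iff
    ``cc = 1 - min_sbd`` strictly exceeds ``cc_threshold``.
    """
    if isinstance(subseq, Subsequence):
        parent_id, i, j = subseq.parent_id, subseq.i, subseq.j
        if subseq.z is None or subseq.degenerate:
            return MatchResult(parent_id, i, j, UNCLASSIFIED,
                               float("nan"), float("nan"), {}, reason="degenerate")
        z = subseq.z
    else:
        z = np.asarray(subseq, float)
        if j is None:
            j = i + z.size - 1
        if np.ptp(z) == 0:
            return MatchResult(parent_id, i, j, UNCLASSIFIED,
                               float("nan"), float("nan"), {}, reason="degenerate")
    if lib.n_templates == 0:
        return MatchResult(parent_id, i, j, UNCLASSIFIED,
                           float("nan"), float("nan"), {}, reason="empty-library")
    q = resample_to_length(z, lib.m)
    dists = {lab: sbd(q, shape)[0] for lab, shape in zip(lib.labels, lib.shapes)}
    best_label = min(dists, key=lambda lab: (dists[lab], lib.labels.index(lab)))
    best = dists[best_label]
    cc = 1.0 - best
    if not cc > cc_threshold:
        best_label = UNCLASSIFIED
    return MatchResult(parent_id, i, j, best_label, float(best), float(cc), dists)


def summarize_matches(
    subsequences: list[Subsequence],
    matches: list[MatchResult],
) -> dict:
    """Coverage and per-label statistics for a matched recording.

    Percent classified counts each subsequence's duration as ``j - i``
    samples, so shared boundary samples are counted once; the total is
    the span from first to last boundary.
    """
    if len(subsequences) != len(matches):
        raise ValueError("one match per subsequence required")
    total = sum(s.j - s.i for s in subsequences)
    per_label: dict[str, dict] = {}
    classified = 0
    for s, r in zip(subsequences, matches):
        if r.classified:
            classified += s.j - s.i
            d = per_label.setdefault(
                r.best_label, {"count": 0, "amplitude_sum": 0.0, "duration_sum": 0.0}
            )
            d["count"] += 1
            d["amplitude_sum"] += float(np.ptp(s.raw))
            d["duration_sum"] += s.duration_s
    stats = {
        lab: {
            "count": d["count"],
            "mean_amplitude_mmHg": d["amplitude_sum"] / d["count"],
            "mean_duration_s": d["duration_sum"] / d["count"],
        }
        for lab, d in sorted(per_label.items())
    }
    return {
        "n_subsequences": len(subsequences),
        "n_classified": sum(r.classified for r in matches),
        "percent_classified": 100.0 * classified / total if total else 0.0,
        "per_label": stats,
    }


def characterize_recording(
    recording: Recording,
    lib: TemplateLibrary,
    filter_spec: FilterSpec = FilterSpec(),
    params: SegmentationParams = SegmentationParams(),
    cc_threshold: float = 0.50,
) -> tuple[list[Subsequence], list[MatchResult], dict]:
    """Segment a preprocessed recording and label every subsequence.

    Returns the subsequences, their match results, and the coverage
    summary (percent of monitoring duration classified, per-label
    counts, mean raw amplitude in mmHg and mean duration in seconds).
    """
    subs, _, _ = segment_recording(recording, filter_spec, params)
    matches = [match_subsequence(s, lib, cc_threshold) for s in subs]
    summary = summarize_matches(subs, matches)
    log.info(
        "characterization: %.1f%% of %s classified (%d/%d subsequences)",
        summary["percent_classified"], recording.id or "recording",
        summary["n_classified"], summary["n_subsequences"],
    )
    return subs, matches, summary
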