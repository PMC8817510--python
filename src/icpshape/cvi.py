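"""Internal cluster-validity indices with pluggable distance.

Three indices score a clustering without ground truth:

* Silhouette: per-sample (b - a) / max(a, b), where a is the mean
  distance to same-cluster members and b the smallest mean distance to
  another cluster; in [-1, 1], higher is better.
* Davies-Bouldin (DBI): mean over clusters of the worst ratio
  (d_a + d_b) / d(c_a, c_b) of within-cluster scatter to centroid
  separation; lower is better.  The pipeline reports 1 - DBI so that
  all three indices read "higher is better" (1 - DBI can be negative).
* Calinski-Harabasz (CHI): trace(between-scatter) / trace(within-scatter)
  scaled by (n_p - K) / (K - 1); higher is better.  Scatter is Euclidean
  in the fixed-length resampled space (trace-of-scatter has no SBD
  analogue).

Silhouette and DBI default to SBD, the pipeline's own metric; both also
accept Euclidean or any callable/precomputed distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .kshape import pairwise_sbd

__all__ = [
    "CVIReport",
    "silhouette",
    "davies_bouldin",
    "calinski_harabasz",
    "cvi_report",
    "cvi_compare",
]

Distance = Callable[[np.ndarray, np.ndarray | None], np.ndarray]


def _euclidean_pairwise(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, float))
    B = A if B is None else np.atleast_2d(np.asarray(B, float))
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    return np.sqrt(np.maximum(d2, 0.0))


def _resolve_distance(distance: str | Distance) -> tuple[Distance, str]:
    if callable(distance):
        return distance, getattr(distance, "__name__", "custom")
    if distance == "sbd":
        return (lambda A, B=None: pairwise_sbd(A, B)), "sbd"
    if distance == "euclidean":
        return _euclidean_pairwise, "euclidean"
    raise ValueError(f"unknown distance {distance!r}; use 'sbd', 'euclidean', "
                     f"'precomputed' or a callable")


def _labels_1d(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    return lab


def silhouette(
    Z: np.ndarray,
    labels,
    distance: str | Distance = "sbd",
) -> tuple[np.ndarray, float]:
    """Per-sample silhouette values and their mean.

    ``Z`` is either the data matrix or, with ``distance='precomputed'``,
    a square distance matrix.  Singleton clusters score 0; a sample
    equidistant to its own and the nearest other cluster scores 0.
    Requires at least two non-empty clusters.
    """
    lab = _labels_1d(labels)
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("silhouette is undefined for K = 1")
    if distance == "precomputed":
        D = np.asarray(Z, float)
        if D.shape[0] != D.shape[1]:
            raise ValueError("precomputed distance must be square")
    else:
        fn, _ = _resolve_distance(distance)
        D = fn(np.asarray(Z, float), None)
    n = D.shape[0]
    if lab.size != n:
        raise ValueError("labels length must match data")
    s = np.zeros(n)
    masks = {u: lab == u for u in uniq}
    for i in range(n):
        own = masks[lab[i]].copy()
        if own.sum() == 1:
            s[i] = 0.0  # singleton convention
            continue
        own[i] = False
        a = D[i, own].mean()
        b = min(D[i, masks[u]].mean() for u in uniq if u != lab[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def davies_bouldin(
    Z: np.ndarray,
    labels,
    centroids: np.ndarray,
    distance: str | Distance = "sbd",
) -> tuple[float, float]:
    """Davies-Bouldin index and its 1 - DBI complement.

    ``d_a`` is the mean distance of cluster-a members to centroid a;
    pairwise ratios use the distance between centroids.  Coincident
    centroids (zero separation) are an error naming the pair.
    """
    lab = _labels_1d(labels)
    uniq = np.unique(lab)
    K = uniq.size
    if K < 2:
        raise ValueError("DBI is undefined for K = 1")
    C = np.atleast_2d(np.asarray(centroids, float))
    if C.shape[0] != K:
        raise ValueError(f"need one centroid per cluster ({K}), got {C.shape[0]}")
    fn, _ = _resolve_distance(distance)
    Zf = np.asarray(Z, float)
    scatter = np.empty(K)
    for ki, u in enumerate(uniq):
        scatter[ki] = fn(Zf[lab == u], C[ki][None, :]).mean()
    sep = fn(C, C)
    dbi = 0.0
    for a in range(K):
        worst = -np.inf
        for b in range(K):
            if a == b:
                continue
            if sep[a, b] == 0:
                raise ValueError(
                    f"coincident centroids for clusters {uniq[a]!r} and {uniq[b]!r}"
                )
            worst = max(worst, (scatter[a] + scatter[b]) / sep[a, b])
        dbi += worst
    dbi /= K
    return float(dbi), float(1.0 - dbi)


def calinski_harabasz(
    Z: np.ndarray,
    labels,
    centroids: np.ndarray | None = None,
    legacy_correction: bool = False,
) -> float:
    """Calinski-Harabasz index in the fixed-length resampled space.

    CHI = [tr(S_B) / tr(S_W)] * [(n_p - K) / (K - 1)] with Euclidean
    scatter about cluster means (or the given centroids).  Zero
    within-cluster scatter yields +inf.  ``legacy_correction`` applies
    the alternative factor (n_p - 1) / (n_p - K) seen in some writeups.
    """
    lab = _labels_1d(labels)
    Zf = np.atleast_2d(np.asarray(Z, float))
    if Zf.shape[0] == lab.size and Zf.ndim == 1:
        Zf = Zf[:, None]
    uniq = np.unique(lab)
    K = uniq.size
    n_p = lab.size
    if K < 2:
        raise ValueError("CHI is undefined for K = 1")
    if n_p <= K:
        raise ValueError("CHI requires more samples than clusters")
    global_mean = Zf.mean(axis=0)
    between = 0.0
    within = 0.0
    for ki, u in enumerate(uniq):
        members = Zf[lab == u]
        center = members.mean(axis=0) if centroids is None else np.asarray(centroids, float)[ki]
        between += members.shape[0] * float(np.sum((center - global_mean) ** 2))
        within += float(np.sum((members - center) ** 2))
    if within == 0:
        return float("inf")
    factor = (n_p - 1) / (n_p - K) if legacy_correction else (n_p - K) / (K - 1)
    return float(between / within * factor)


@dataclass
class CVIReport:
    """All three indices for one clustering."""

    silhouette_mean: float
    silhouette_per_sample: np.ndarray
    dbi: float
    one_minus_dbi: float
    chi: float
    distance_name: str
    n_p: int
    K: int

    def as_dict(self) -> dict:
        return {
            "silhouette": self.silhouette_mean,
            "one_minus_dbi": self.one_minus_dbi,
            "chi": self.chi,
            "n_p": self.n_p,
            "K": self.K,
            "distance": self.distance_name,
        }


def cvi_report(
    Z: np.ndarray,
    labels,
    centroids: np.ndarray,
    distance: str | Distance = "sbd",
) -> CVIReport:
    """Compute silhouette (mean + per sample), 1 - DBI and CHI."""
    if distance == "precomputed":
        raise ValueError("cvi_report needs the data matrix, not a precomputed distance")
    lab = _labels_1d(labels)
    per, mean_s = silhouette(Z, lab, distance=distance)
    dbi, omd = davies_bouldin(Z, lab, centroids, distance=distance)
    chi = calinski_harabasz(Z, lab)
    _, name = _resolve_distance(distance)
    return CVIReport(
        silhouette_mean=mean_s,
        silhouette_per_sample=per,
        dbi=dbi,
        one_minus_dbi=omd,
        chi=chi,
        distance_name=name,
        n_p=lab.size,
        K=np.unique(lab).size,
    )


def cvi_compare(
    Z: np.ndarray,
    labels_without_rule,
    labels_with_rule,
    centroids: np.ndarray,
    distance: str | Distance = "sbd",
) -> dict:
    """CVIs without and with the correlation gate, plus deltas.

    ``labels_with_rule`` marks gated-out subsequences with a
    non-positive label (<= 0); those are dropped before scoring, along
    with any centroid whose cluster is emptied.  Both labelings must
    cover the same ``Z``.
    """
    lab_a = _labels_1d(labels_without_rule)
    lab_b = _labels_1d(labels_with_rule)
    if lab_a.size != lab_b.size:
        raise ValueError("both labelings must cover the same subsequences")
    Zf = np.asarray(Z, float)
    keep = lab_b > 0
    if not keep.any():
        raise ValueError("correlation rule retained no subsequences")
    C = np.atleast_2d(np.asarray(centroids, float))
    rep_a = cvi_report(Zf, lab_a, C, distance=distance)
    kept_labels = np.unique(lab_b[keep])
    C_b = C[[int(u) - 1 for u in kept_labels]] if C.shape[0] >= kept_labels.max() else C
    rep_b = cvi_report(Zf[keep], lab_b[keep], C_b, distance=distance)
    return {
        "without_rule": rep_a,
        "with_rule": rep_b,
        "delta": {
            "silhouette": rep_b.silhouette_mean - rep_a.silhouette_mean,
            "one_minus_dbi": rep_b.one_minus_dbi - rep_a.one_minus_dbi,
            "chi": rep_b.chi - rep_a.chi,
        },
    }
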