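"""k-Shape clustering with the Shape-Based Distance (SBD).

SBD between two z-normalized vectors is 1 minus the maximum over all
shifts w of the coefficient-normalized cross-correlation
CC_w(x, y) / (||x|| * ||y||); it lies in [0, 2], is 0 for identical
shapes, and is invariant to amplitude scaling, offset (after
z-normalization) and alignment.  k-Shape alternates an assignment step
(each vector joins the centroid with minimum SBD) and a refinement step
(each centroid becomes the principal eigenvector of the centered
alignment matrix of its members -- the shape maximizing the summed
squared normalized correlation), until labels stop changing or an
iteration cap is hit.

Variable-duration subsequences enter shape space through
:func:`resample_to_length`: linear interpolation onto a fixed common
length (default 128) followed by re-z-normalization.  Resampling was
chosen over zero-padding because subsequence durations span two orders
of magnitude and padding would dominate the correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterModel",
    "resample_to_length",
    "ncc_c",
    "sbd",
    "pairwise_sbd",
    "shape_extraction",
    "kshape_cluster",
    "select_k",
]

log = logging.getLogger(__name__)


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        raise ValueError("constant vector cannot be z-normalized")
    return (x - mu) / sigma


def resample_to_length(z: np.ndarray, m: int) -> np.ndarray:
    """Resample a vector to length ``m`` and re-z-normalize.

    Linear interpolation onto ``m`` equally spaced points over the
    original support.  Inputs much longer than ``m`` (full-rate
    subsequences spanning minutes) are first block-averaged to about
    ``4 m`` samples: without this anti-aliasing step the point
    interpolation folds the full cardiac/respiratory/noise power into
    shape space, where it would dominate the macro-pattern.  Constant
    (degenerate) input is rejected.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 samples")
    if m < 2:
        raise ValueError("m must be >= 2")
    if np.ptp(z) == 0:
        raise ValueError("constant vector cannot be resampled into shape space")
    if z.size > 4 * m:
        k = z.size // (4 * m)
        if k > 1:
            z = z[: (z.size // k) * k].reshape(-1, k).mean(axis=1)
    xs = np.linspace(0.0, z.size - 1.0, m)
    v = np.interp(xs, np.arange(z.size), z)
    return _zscore(v)


def _nfft(n: int) -> int:
    return 1 << int(np.ceil(np.log2(max(2, n))))


def ncc_c(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficient-normalized cross-correlation over all shifts.

    Returns a vector of length ``2m - 1`` holding
    ``CC_w(x, y) / (||x|| ||y||)`` for shifts w = -(m-1) .. (m-1), where
    ``CC_w(x, y) = sum_t x[t - w] * y[t]`` with zero padding (positive w
    displaces x to the right over y).  All values lie in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("ncc_c requires equal-length vectors")
    m = x.size
    den = float(np.linalg.norm(x) * np.linalg.norm(y))
    if den == 0:
        raise ValueError("zero-norm input")
    n = _nfft(2 * m - 1)
    cc = np.fft.irfft(np.fft.rfft(x, n) * np.conj(np.fft.rfft(y, n)), n)
    # circular cc[k] = sum_t x[t + k] y[t], so shift w = -k sits at cc[k]
    # (k = 0..m-1) and w = +k at the wrap cc[n - k] (k = 1..m-1)
    neg = cc[1:m][::-1]  # w = -(m-1) .. -1
    pos = cc[n - m + 1 : n][::-1]  # w = +1 .. +(m-1)
    full = np.concatenate((neg, cc[:1], pos))
    return full / den


def sbd(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Shape-Based Distance and the maximizing shift.

    ``distance = 1 - max_w ncc_c(x, y)``, in [0, 2].  Ties in the argmax
    go to the smallest |w| (and to the negative shift between +/-w).
    """
    ncc = ncc_c(x, y)
    m = (ncc.size + 1) // 2
    shifts = np.arange(-(m - 1), m)
    best = ncc.max()
    tied = np.flatnonzero(ncc >= best - 1e-12)
    w = int(shifts[tied[np.lexsort((shifts[tied], np.abs(shifts[tied])))[0]]])
    return float(1.0 - best), w


def _cross_spectra_dist(Z: np.ndarray, C: np.ndarray) -> np.ndarray:
    """SBD matrix between rows of Z (N, m) and rows of C (K, m)."""
    N, m = Z.shape
    n = _nfft(2 * m - 1)
    FZ = np.fft.rfft(Z, n, axis=1)
    FC = np.fft.rfft(C, n, axis=1)
    nz = np.linalg.norm(Z, axis=1)
    nc = np.linalg.norm(C, axis=1)
    if np.any(nz == 0) or np.any(nc == 0):
        raise ValueError("zero-norm input")
    D = np.empty((N, C.shape[0]))
    for k in range(C.shape[0]):
        cc = np.fft.irfft(FZ * np.conj(FC[k]), n, axis=1)
        # max over valid lags only: indices 0..m-1 and n-m+1..n-1
        valid = np.concatenate((cc[:, : m], cc[:, n - m + 1 :]), axis=1)
        D[:, k] = 1.0 - valid.max(axis=1) / (nz * nc[k])
    return D


def pairwise_sbd(Z: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Full SBD matrix between rows of ``Z`` and rows of ``Y`` (or ``Z``)."""
    Z = np.asarray(Z, dtype=float)
    Y = Z if Y is None else np.asarray(Y, dtype=float)
    D = _cross_spectra_dist(Z, Y)
    if Y is Z:
        np.fill_diagonal(D, 0.0)
        D = np.minimum(D, D.T)  # enforce exact symmetry against fp jitter
    return np.maximum(D, 0.0)


def _align_to(y: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Shift ``y`` (zero-padded) to its best SBD alignment with reference."""
    _, w = sbd(y, reference)
    out = np.zeros_like(y)
    if w >= 0:
        out[w:] = y[: y.size - w] if w else y
    else:
        out[:w] = y[-w:]
    return out


def shape_extraction(members: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Centroid of a cluster: the shape maximizing summed squared
    normalized correlation with the (aligned) members.

    Members are first aligned to ``reference`` by their SBD-maximizing
    shift (no alignment when reference is None).  The centroid is the
    principal eigenvector of the centered alignment matrix, z-normalized,
    with its sign chosen so the summed correlation with members is
    positive.
    """
    S = np.atleast_2d(np.asarray(members, dtype=float))
    if S.shape[0] == 0:
        raise ValueError("empty cluster")
    m = S.shape[1]
    if reference is not None and np.linalg.norm(reference) > 0:
        S = np.vstack([_align_to(row, reference) for row in S])
    M = S.T @ S
    Q = np.eye(m) - np.full((m, m), 1.0 / m)
    Mc = Q @ M @ Q
    vals, vecs = np.linalg.eigh(Mc)
    centroid = vecs[:, -1]
    if S.sum(axis=0) @ centroid < 0:
        centroid = -centroid
    return _zscore(centroid)


@dataclass
class ClusterModel:
    """Result of one k-Shape run.  Labels are 1-based (1..K)."""

    K: int
    centroids: np.ndarray  # (K, m)
    labels: np.ndarray  # (N,), values in 1..K
    n_iter: int
    converged: bool
    seed: int
    objective_history: list[float] = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.centroids.shape[1]


def _plusplus_seed(Z: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Pick K initial centroids from the data, greedy k-means++-style in SBD.

    Each step draws several candidates with probability proportional to
    squared distance from the chosen set and keeps the one minimizing
    the total potential; the greedy step stops lone outliers from
    grabbing seeds.
    """
    N = Z.shape[0]
    n_candidates = 2 + int(np.log(max(K, 2)))
    first = int(rng.integers(N))
    chosen = [first]
    d = _cross_spectra_dist(Z, Z[first][None, :]).ravel()
    for _ in range(K - 1):
        p = d**2
        total = p.sum()
        if total == 0:  # all remaining points coincide with a centroid
            p = np.ones(N)
            total = float(N)
        cand = rng.choice(N, size=n_candidates, p=p / total)
        best_idx, best_pot, best_d = -1, np.inf, None
        for c in cand:
            dc = np.minimum(d, _cross_spectra_dist(Z, Z[int(c)][None, :]).ravel())
            pot = float((dc**2).sum())
            if pot < best_pot:
                best_idx, best_pot, best_d = int(c), pot, dc
        chosen.append(best_idx)
        d = best_d
    return Z[chosen].copy()


def kshape_cluster(
    Z: np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 100,
    n_init: int = 3,
) -> ClusterModel:
    """Cluster z-normalized shape vectors into K groups by k-Shape.

    Initial centroids are data vectors chosen by greedy k-means++-style
    sampling in SBD space, drawn from ``seed``.  ``n_init`` independent
    restarts are run (per-restart seeds derived deterministically) and
    the partition with the highest mean SBD silhouette is kept -- the
    alternating optimization can stall in local optima that merge two
    shape families, and silhouette reliably exposes such merges.  A
    cluster left empty after an assignment step is re-seeded with the
    vector farthest (max SBD) from its assigned centroid.  Assignment
    ties go to the lowest cluster index.  Deterministic given
    ``(Z, K, seed, n_init)``.
    """
    Z = np.asarray(Z, dtype=float)
    N = Z.shape[0]
    if not 1 <= K <= N:
        raise ValueError(f"need 1 <= K <= n_vectors; got K={K}, n={N}")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if n_init > 1 and K >= 2:
        from .cvi import silhouette

        D = pairwise_sbd(Z)
        best_model, best_score = None, -np.inf
        for r in range(n_init):
            model = kshape_cluster(Z, K, seed=(seed * 7919 + r) % (2**31),
                                   max_iter=max_iter, n_init=1)
            if np.unique(model.labels).size < 2:
                score = -np.inf
            else:
                _, score = silhouette(D, model.labels, distance="precomputed")
            if score > best_score:
                best_model, best_score = model, score
        best_model.seed = seed
        return best_model
    rng = np.random.default_rng(seed)
    centroids = _plusplus_seed(Z, K, rng)
    labels = np.full(N, -1)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # assignment
        D = _cross_spectra_dist(Z, centroids)
        new_labels = D.argmin(axis=1)  # argmin takes lowest index on ties
        # re-seed empty clusters with the worst-fitting vector
        for k in range(K):
            if not np.any(new_labels == k):
                own = D[np.arange(N), new_labels]
                far = int(np.argmax(own))
                new_labels[far] = k
                own[far] = -np.inf
        history.append(float(D[np.arange(N), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        # refinement
        for k in range(K):
            members = Z[labels == k]
            centroids[k] = shape_extraction(members, centroids[k])
    model = ClusterModel(
        K=K,
        centroids=centroids.copy(),
        labels=labels + 1,
        n_iter=it,
        converged=converged,
        seed=seed,
        objective_history=history,
    )
    log.info("k-Shape: K=%d, %d iterations, converged=%s", K, it, converged)
    return model


def select_k(
    Z: np.ndarray,
    k_min: int = 5,
    k_max: int = 20,
    seed: int = 0,
    max_iter: int = 100,
) -> tuple[int, dict[int, float]]:
    """Scan K over [k_min, k_max] and pick the silhouette maximizer.

    The mean silhouette uses SBD as its distance.  Per-K seeds are
    derived deterministically from the base seed; ties in the maximum go
    to the smallest K.
    """
    from .cvi import silhouette

    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] <= k_max:
        raise ValueError(
            f"need more vectors than k_max; got n={Z.shape[0]}, k_max={k_max}"
        )
    if not 2 <= k_min <= k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    D = pairwise_sbd(Z)
    scores: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        sub_seed = (seed * 1_000_003 + k) % (2**31)
        model = kshape_cluster(Z, k, seed=sub_seed, max_iter=max_iter)
        _, mean_s = silhouette(D, model.labels, distance="precomputed")
        scores[k] = mean_s
    best = max(scores, key=lambda k: (scores[k], -k))
    log.info("select_k: K_opt=%d (silhouette %.4f)", best, scores[best])
    return best, scores
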