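"""Affinity-propagation clustering of detected LTS patch centers and
cluster-shape features.

Affinity propagation (Frey & Dueck) finds exemplars by exchanging
responsibility and availability messages on a similarity matrix — here the
negative squared Euclidean distance between patch-cell centers — without a
preset cluster count.  The per-slide features are descriptive statistics
of the resulting partition (cluster sizes, dispersion, extent,
between-cluster scatter) and six classical cluster validity indices
(Ball-Hall, Banfeld-Raftery, log SS ratio, Davies-Bouldin,
Calinski-Harabasz, C-index).

Notation used throughout: n points x_i in the plane, clusters k = 1..K
with sizes n_k, centroids μ_k and global centroid μ;
WGSS_k = Σ_{i∈k} ‖x_i − μ_k‖², WGSS = Σ_k WGSS_k,
BGSS = Σ_k n_k‖μ_k − μ‖².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .errors import ValidationError

#: Guard for log(WGSS_k / n_k) on singleton or zero-variance clusters.
EPS_WITHIN = 1e-12


@dataclass
class Clustering:
    """A hard partition of a point set with exemplar indices."""

    labels: np.ndarray
    exemplars: np.ndarray
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def affinity_propagation(
    points: np.ndarray,
    preference: float | None = None,
    damping: float = 0.7,
    max_iter: int = 200,
    convergence_iter: int = 15,
    seed: int = 0,
) -> Clustering:
    """Exemplar-based clustering by responsibility/availability messages.

    Similarity is s(i, k) = −‖x_i − x_k‖²; the shared preference s(k, k)
    defaults to the median off-diagonal similarity.  Messages are damped
    by ``damping`` ∈ [0.5, 1) (default 0.7: damping 0.5 oscillates on
    symmetric well-separated patterns, while very heavy damping evolves
    too slowly for the stability-based stopping rule); iteration stops when the exemplar set is
    stable for ``convergence_iter`` sweeps.  A tiny seeded jitter breaks
    exact symmetry ties (duplicated points).  Exemplars are the points
    with positive self responsibility+availability; each point joins the
    exemplar of maximal similarity, and cluster exemplars are refined to
    the member maximizing within-cluster similarity.  Non-convergence is
    flagged on the result rather than raised.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2) if np.size(points) else np.empty((0, 2))
    n = len(pts)
    if not (0.5 <= damping < 1):
        raise ValidationError("damping must be in [0.5, 1)")
    if n == 0:
        return Clustering(np.empty(0, dtype=int), np.empty(0, dtype=int))
    if n == 1:
        return Clustering(np.zeros(1, dtype=int), np.zeros(1, dtype=int))

    S = -cdist(pts, pts, "sqeuclidean")
    if preference is None:
        off = S[~np.eye(n, dtype=bool)]
        preference = float(np.median(off))
    np.fill_diagonal(S, preference)
    rng = np.random.default_rng(seed)
    S = S + 1e-12 * (np.ptp(S) + 1) * rng.standard_normal((n, n))

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    last_exemplars = None
    stable = 0
    converged = False
    for _ in range(max_iter):
        # responsibilities
        AS = A + S
        first = AS.argmax(axis=1)
        first_val = AS[idx, first]
        AS[idx, first] = -np.inf
        second_val = AS.max(axis=1)
        Rnew = S - first_val[:, None]
        Rnew[idx, first] = S[idx, first] - second_val
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, np.diag(R))
        col = Rp.sum(axis=0)
        Anew = np.minimum(0, col[None, :] - Rp)
        np.fill_diagonal(Anew, col - np.diag(Rp))
        A = damping * A + (1 - damping) * Anew

        exemplars = np.flatnonzero(np.diag(A) + np.diag(R) > 0)
        if last_exemplars is not None and np.array_equal(exemplars, last_exemplars):
            stable += 1
            if stable >= convergence_iter and len(exemplars):
                converged = True
                break
        else:
            stable = 0
        last_exemplars = exemplars

    if len(exemplars) == 0:
        # degenerate: fall back to the single best self-evidence point
        exemplars = np.array([int(np.argmax(np.diag(A) + np.diag(R)))])
        converged = False

    labels = np.asarray(S[:, exemplars].argmax(axis=1))
    labels[exemplars] = np.arange(len(exemplars))
    # refine each exemplar to the member with maximal within-cluster similarity
    final = []
    for k in range(len(exemplars)):
        members = np.flatnonzero(labels == k)
        sub = S[np.ix_(members, members)]
        final.append(int(members[sub.sum(axis=0).argmax()]))
    final = np.array(final)
    labels = np.asarray(S[:, final].argmax(axis=1))
    labels[final] = np.arange(len(final))
    return Clustering(labels, final, converged)


# ---------------------------------------------------------------------------
# descriptors and validity indices


def _groups(clustering: Clustering, pts: np.ndarray):
    for k in range(clustering.n_clusters):
        yield pts[clustering.labels == k]


def cluster_descriptors(clustering: Clustering, points: np.ndarray) -> dict[str, float]:
    """Per-slide cluster shape statistics.

    size_k = n_k; dispersion_k = mean distance to the cluster centroid;
    extent_k = max within-cluster pairwise distance; between-cluster
    scatter = BGSS.  Means and SDs (population) are taken over clusters.
    Empty clusterings yield NaN everywhere.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2) if np.size(points) else np.empty((0, 2))
    if clustering.n_clusters == 0 or len(pts) == 0:
        keys = (
            "n_clusters cluster_size_mean cluster_size_sd dispersion_mean "
            "dispersion_sd extent_mean extent_sd between_cluster_scatter"
        ).split()
        return dict.fromkeys(keys, float("nan"))
    sizes, disp, extent, centroids = [], [], [], []
    for g in _groups(clustering, pts):
        sizes.append(len(g))
        c = g.mean(axis=0)
        centroids.append(c)
        disp.append(float(np.mean(np.linalg.norm(g - c, axis=1))))
        extent.append(float(pdist(g).max()) if len(g) > 1 else 0.0)
    sizes = np.array(sizes, dtype=float)
    centroids = np.array(centroids)
    mu = pts.mean(axis=0)
    bgss = float(np.sum(sizes * np.sum((centroids - mu) ** 2, axis=1)))
    return {
        "n_clusters": float(clustering.n_clusters),
        "cluster_size_mean": float(np.mean(sizes)),
        "cluster_size_sd": float(np.std(sizes)),
        "dispersion_mean": float(np.mean(disp)),
        "dispersion_sd": float(np.std(disp)),
        "extent_mean": float(np.mean(extent)),
        "extent_sd": float(np.std(extent)),
        "between_cluster_scatter": bgss,
    }


def validity_indices(clustering: Clustering, points: np.ndarray) -> dict[str, float]:
    """Six classical cluster validity indices of the partition.

    BallHall = (1/K) Σ_k WGSS_k/n_k
    BanfeldRaftery = Σ_k n_k log(WGSS_k/n_k)   (ratio floored at 1e-12)
    LogSSRatio = log(BGSS/WGSS)
    DaviesBouldin = (1/K) Σ_k max_{l≠k} (δ_k+δ_l)/‖μ_k−μ_l‖,
        δ = mean distance to centroid
    CalinskiHarabasz = (BGSS/(K−1)) / (WGSS/(n−K))
    CIndex = (S_W − S_min)/(S_max − S_min), S_W the sum of within-cluster
        pairwise distances and S_min/S_max the sums of the N_W smallest /
        largest of all pairwise distances.

    With K = 1, indices requiring between-cluster structure
    (Davies-Bouldin, Calinski-Harabasz, LogSSRatio, C-index) are NaN.
    WGSS = 0 (K = n or duplicated points) yields +inf for
    Calinski-Harabasz and −inf for LogSSRatio.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2:
        raise ValidationError("validity indices need at least 2 points")
    K = clustering.n_clusters
    nan = float("nan")

    sizes, wgss_k, delta, centroids = [], [], [], []
    s_w = 0.0
    n_w = 0
    for g in _groups(clustering, pts):
        c = g.mean(axis=0)
        centroids.append(c)
        sizes.append(len(g))
        wgss_k.append(float(np.sum((g - c) ** 2)))
        delta.append(float(np.mean(np.linalg.norm(g - c, axis=1))))
        if len(g) > 1:
            dists = pdist(g)
            s_w += float(dists.sum())
            n_w += len(dists)
    sizes = np.array(sizes, dtype=float)
    wgss_k = np.array(wgss_k)
    centroids = np.array(centroids)
    wgss = float(wgss_k.sum())
    mu = pts.mean(axis=0)
    bgss = float(np.sum(sizes * np.sum((centroids - mu) ** 2, axis=1)))

    ball_hall = float(np.mean(wgss_k / sizes))
    banfeld = float(np.sum(sizes * np.log(np.maximum(wgss_k / sizes, EPS_WITHIN))))

    if K < 2:
        return {
            "ball_hall": ball_hall,
            "banfeld_raftery": banfeld,
            "log_ss_ratio": nan,
            "davies_bouldin": nan,
            "calinski_harabasz": nan,
            "c_index": nan,
        }

    log_ss = float(np.log(bgss / wgss)) if wgss > 0 else float("-inf") if bgss > 0 else nan

    cd = cdist(centroids, centroids)
    db_terms = []
    for k in range(K):
        with np.errstate(divide="ignore"):
            ratios = [
                (delta[k] + delta[l]) / cd[k, l] if cd[k, l] > 0 else np.inf
                for l in range(K)
                if l != k
            ]
        db_terms.append(max(ratios))
    davies_bouldin = float(np.mean(db_terms))

    if wgss > 0 and n > K:
        calinski = float((bgss / (K - 1)) / (wgss / (n - K)))
    else:
        calinski = float("inf") if bgss > 0 else nan

    all_d = np.sort(pdist(pts))
    if n_w == 0:
        c_index = nan
    else:
        s_min = float(all_d[:n_w].sum())
        s_max = float(all_d[-n_w:].sum())
        c_index = 0.0 if s_max == s_min else float((s_w - s_min) / (s_max - s_min))

    return {
        "ball_hall": ball_hall,
        "banfeld_raftery": banfeld,
        "log_ss_ratio": log_ss,
        "davies_bouldin": davies_bouldin,
        "calinski_harabasz": calinski,
        "c_index": c_index,
    }
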