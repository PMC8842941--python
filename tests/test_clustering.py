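"""Affinity propagation and cluster features against independent oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

from ltsq.clustering import (
    Clustering,
    affinity_propagation,
    cluster_descriptors,
    validity_indices,
)
from ltsq.errors import ValidationError


def blobs(rng, centers, n=30, sd=2.0):
    return np.vstack([rng.normal(c, sd, (n, 2)) for c in centers])


def test_empty_and_singleton_point_sets():
    c0 = affinity_propagation(np.empty((0, 2)))
    assert c0.n_clusters == 0
    c1 = affinity_propagation(np.array([[3.0, 4.0]]))
    assert c1.n_clusters == 1 and c1.exemplars[0] == 0


def test_duplicated_pairs_form_two_clusters():
    pts = np.array([[0, 0], [0, 0], [100, 0], [100, 0]], dtype=float)
    c = affinity_propagation(pts, seed=0)
    assert c.n_clusters == 2
    assert c.labels[0] == c.labels[1] and c.labels[2] == c.labels[3]


def test_planted_blobs_recovered():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(0)
    pts = blobs(rng, [(0, 0), (100, 0), (50, 90)])
    truth = np.repeat([0, 1, 2], 30)
    c = affinity_propagation(pts, seed=0)
    assert c.converged
    assert adjusted_rand_score(truth, c.labels) >= 0.9


def test_agreement_with_reference_implementation():
    from sklearn.cluster import AffinityPropagation
    from sklearn.metrics import adjusted_rand_score

    for seed in range(5):
        rng = np.random.default_rng(seed)
        pts = blobs(rng, [(0, 0), (60, 0), (30, 50)], n=15, sd=3.0)
        mine = affinity_propagation(pts, preference=-800.0, damping=0.7, seed=0)
        ref = AffinityPropagation(
            preference=-800.0, damping=0.7, random_state=0
        ).fit(pts)
        assert adjusted_rand_score(mine.labels, ref.labels_) == pytest.approx(1.0)


def test_very_negative_preference_yields_single_cluster():
    rng = np.random.default_rng(1)
    c = affinity_propagation(rng.uniform(0, 10, (20, 2)), preference=-1e9)
    assert c.n_clusters == 1


def test_invalid_damping_rejected():
    with pytest.raises(ValidationError):
        affinity_propagation(np.zeros((3, 2)), damping=0.4)


def test_exemplars_belong_to_their_clusters():
    rng = np.random.default_rng(2)
    pts = blobs(rng, [(0, 0), (80, 80)], n=20)
    c = affinity_propagation(pts, seed=0)
    for k, e in enumerate(c.exemplars):
        assert c.labels[e] == k
    assert len(np.unique(c.labels)) == c.n_clusters


# --- descriptors -----------------------------------------------------------


def test_singleton_cluster_descriptors_are_zero():
    pts = np.array([[5.0, 5.0]])
    c = Clustering(np.array([0]), np.array([0]))
    d = cluster_descriptors(c, pts)
    assert d["dispersion_mean"] == 0.0
    assert d["extent_mean"] == 0.0
    assert d["between_cluster_scatter"] == 0.0


def test_two_singletons_scatter_is_half_squared_distance():
    # centroids sit d/2 from the global mean: BGSS = 2 * (d/2)^2 = d^2/2
    d = 8.0
    pts = np.array([[0.0, 0.0], [d, 0.0]])
    c = Clustering(np.array([0, 1]), np.array([0, 1]))
    desc = cluster_descriptors(c, pts)
    assert desc["between_cluster_scatter"] == pytest.approx(d**2 / 2)


def naive_descriptors(labels, pts):
    ks = np.unique(labels)
    sizes, disp, ext = [], [], []
    cents = []
    for k in ks:
        g = pts[labels == k]
        cent = g.mean(axis=0)
        cents.append(cent)
        sizes.append(len(g))
        disp.append(np.mean([np.hypot(*(p - cent)) for p in g]))
        m = 0.0
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                m = max(m, np.hypot(*(g[i] - g[j])))
        ext.append(m)
    mu = pts.mean(axis=0)
    bgss = sum(s * np.sum((c - mu) ** 2) for s, c in zip(sizes, cents))
    return sizes, disp, ext, bgss


@pytest.mark.parametrize("seed", range(5))
def test_descriptors_match_naive_loops(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 100, (30, 2))
    labels = rng.integers(0, 4, 30)
    labels = np.unique(labels, return_inverse=True)[1]  # compact ids
    k = labels.max() + 1
    c = Clustering(labels, np.array([np.flatnonzero(labels == i)[0] for i in range(k)]))
    d = cluster_descriptors(c, pts)
    sizes, disp, ext, bgss = naive_descriptors(labels, pts)
    assert d["cluster_size_mean"] == pytest.approx(np.mean(sizes), abs=1e-12)
    assert d["dispersion_mean"] == pytest.approx(np.mean(disp), abs=1e-9)
    assert d["extent_mean"] == pytest.approx(np.mean(ext), abs=1e-9)
    assert d["between_cluster_scatter"] == pytest.approx(bgss, abs=1e-9)


# --- validity indices ------------------------------------------------------


def brute_force_indices(labels, pts):
    """Definition-level double-loop implementations."""
    n = len(pts)
    ks = np.unique(labels)
    K = len(ks)
    cents = {k: pts[labels == k].mean(axis=0) for k in ks}
    mu = pts.mean(axis=0)
    wgss_k = {k: sum(np.sum((p - cents[k]) ** 2) for p in pts[labels == k]) for k in ks}
    nk = {k: int(np.sum(labels == k)) for k in ks}
    wgss = sum(wgss_k.values())
    bgss = sum(nk[k] * np.sum((cents[k] - mu) ** 2) for k in ks)
    ball_hall = np.mean([wgss_k[k] / nk[k] for k in ks])
    banfeld = sum(nk[k] * np.log(max(wgss_k[k] / nk[k], 1e-12)) for k in ks)
    log_ss = np.log(bgss / wgss)
    delta = {
        k: np.mean([np.hypot(*(p - cents[k])) for p in pts[labels == k]]) for k in ks
    }
    db = np.mean(
        [
            max(
                (delta[k] + delta[l]) / np.hypot(*(cents[k] - cents[l]))
                for l in ks
                if l != k
            )
            for k in ks
        ]
    )
    ch = (bgss / (K - 1)) / (wgss / (n - K))
    s_w, n_w = 0.0, 0
    all_d = []
    for i in range(n):
        for j in range(i + 1, n):
            dij = np.hypot(*(pts[i] - pts[j]))
            all_d.append(dij)
            if labels[i] == labels[j]:
                s_w += dij
                n_w += 1
    all_d.sort()
    c_index = (s_w - sum(all_d[:n_w])) / (sum(all_d[-n_w:]) - sum(all_d[:n_w]))
    return {
        "ball_hall": ball_hall,
        "banfeld_raftery": banfeld,
        "log_ss_ratio": log_ss,
        "davies_bouldin": db,
        "calinski_harabasz": ch,
        "c_index": c_index,
    }


@pytest.mark.parametrize("seed", range(8))
def test_indices_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 50, (30, 2))
    K = int(rng.integers(2, 6))
    labels = np.unique(rng.integers(0, K, 30), return_inverse=True)[1]
    k = labels.max() + 1
    c = Clustering(labels, np.array([np.flatnonzero(labels == i)[0] for i in range(k)]))
    mine = validity_indices(c, pts)
    ref = brute_force_indices(labels, pts)
    for key, v in ref.items():
        assert mine[key] == pytest.approx(v, abs=1e-9), key


def test_tight_clusters_give_zero_c_index_and_ball_hall():
    pts = np.array([[0, 0], [0, 0], [10, 0], [10, 0]], dtype=float)
    c = Clustering(np.array([0, 0, 1, 1]), np.array([0, 2]))
    v = validity_indices(c, pts)
    assert v["ball_hall"] == 0.0
    assert v["c_index"] == 0.0
    assert v["calinski_harabasz"] == np.inf


def test_k1_indices_flagged_missing():
    pts = np.random.default_rng(0).uniform(0, 1, (10, 2))
    c = Clustering(np.zeros(10, dtype=int), np.array([0]))
    v = validity_indices(c, pts)
    for key in ("davies_bouldin", "calinski_harabasz", "log_ss_ratio", "c_index"):
        assert np.isnan(v[key])
    assert np.isfinite(v["ball_hall"])


def test_indices_invariant_under_rigid_motion(rng):
    pts = rng.uniform(0, 50, (25, 2))
    labels = rng.integers(0, 3, 25)
    labels = np.unique(labels, return_inverse=True)[1]
    k = labels.max() + 1
    c = Clustering(labels, np.array([np.flatnonzero(labels == i)[0] for i in range(k)]))
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = pts @ rot.T + np.array([13.0, -4.0])
    a, b = validity_indices(c, pts), validity_indices(c, moved)
    for key in a:
        assert a[key] == pytest.approx(b[key], rel=1e-9), key


def test_c_index_bounded(rng):
    for _ in range(10):
        pts = rng.uniform(0, 10, (20, 2))
        labels = rng.integers(0, 3, 20)
        labels = np.unique(labels, return_inverse=True)[1]
        k = labels.max() + 1
        c = Clustering(
            labels, np.array([np.flatnonzero(labels == i)[0] for i in range(k)])
        )
        v = validity_indices(c, pts)
        if not np.isnan(v["c_index"]):
            assert 0.0 <= v["c_index"] <= 1.0
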