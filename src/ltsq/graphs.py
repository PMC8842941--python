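"""Spatial object graphs and distribution-homogeneity features (graph_v1).

A graph is built over detected LTS patch centers — radius rule (edges
between pairs within r), symmetrized k-nearest-neighbors, or Delaunay
triangulation — and summarized through node-degree statistics.  A second
family of features measures how homogeneously the detections are spread
in tissue: nearest-neighbor distances, the Clark–Evans ratio
R = mean NN distance / (0.5·sqrt(area/n)) (R ≈ 1 for complete spatial
randomness, < 1 clustered, > 1 regular), and the quadrat-count dispersion
index (variance/mean of counts over a grid of quadrats).

This open, versioned feature set (``graph_v1``) fills the pipeline's
object-graph feature slots with documented definitions.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .errors import ValidationError

log = logging.getLogger(__name__)

#: Default neighborhood radius: three 40-px grid cells.
DEFAULT_RADIUS = 120.0


def build_object_graph(
    points: np.ndarray, rule: str = "radius", parameter: float = DEFAULT_RADIUS
) -> nx.Graph:
    """Build an undirected simple graph over points by the named rule.

    ``radius``: connect pairs with Euclidean distance ≤ parameter.
    ``knn``: connect each node to its k nearest neighbors, symmetrized
    (k clamped to n−1 when too large, logged).
    ``delaunay``: edges of the Delaunay triangulation.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2) if np.size(points) else np.empty((0, 2))
    n = len(pts)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, p in enumerate(pts):
        g.nodes[i]["pos"] = tuple(p)
    if n < 2:
        return g
    if rule == "radius":
        tree = cKDTree(pts)
        g.add_edges_from(tree.query_pairs(float(parameter)))
    elif rule == "knn":
        k = int(parameter)
        if k < 1:
            raise ValidationError("knn parameter must be >= 1")
        if k >= n:
            log.debug("knn k=%d clamped to %d", k, n - 1)
            k = n - 1
        tree = cKDTree(pts)
        _, nbrs = tree.query(pts, k=k + 1)
        for i, row in enumerate(np.atleast_2d(nbrs)):
            for j in row[1:]:
                g.add_edge(i, int(j))
    elif rule == "delaunay":
        if n < 3:
            g.add_edge(0, 1)
            return g
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for a in range(3):
                g.add_edge(int(simplex[a]), int(simplex[(a + 1) % 3]))
    else:
        raise ValidationError(f"unknown graph rule {rule!r}")
    return g


def degree_features(graph: nx.Graph) -> dict[str, float]:
    """Degree-based summaries of an object graph.

    Entropy is in bits over the empirical degree distribution.
    Assortativity and mean local clustering are NaN when degenerate
    (e.g. constant degrees or no edges).  An empty graph yields NaN
    everywhere.
    """
    nan = float("nan")
    keys = (
        "degree_mean degree_sd degree_max fraction_isolated degree_entropy "
        "degree_assortativity mean_clustering"
    ).split()
    if graph.number_of_nodes() == 0:
        return dict.fromkeys(keys, nan)
    deg = np.array([d for _, d in graph.degree()], dtype=float)
    vals, counts = np.unique(deg, return_counts=True)
    p = counts / counts.sum()
    entropy = float(-np.sum(p * np.log2(p)))
    if graph.number_of_edges() > 0 and len(vals) > 1:
        try:
            assort = float(nx.degree_assortativity_coefficient(graph))
        except (ValueError, ZeroDivisionError):
            assort = nan
    else:
        assort = nan
    clustering = float(np.mean(list(nx.clustering(graph).values())))
    return {
        "degree_mean": float(deg.mean()),
        "degree_sd": float(deg.std()),
        "degree_max": float(deg.max()),
        "fraction_isolated": float(np.mean(deg == 0)),
        "degree_entropy": entropy,
        "degree_assortativity": assort,
        "mean_clustering": clustering,
    }


def homogeneity_features(
    points: np.ndarray, tissue_area: float, quadrat_grid: int = 4
) -> dict[str, float]:
    """Spatial homogeneity of the detections within the tissue.

    Clark–Evans R compares the observed mean nearest-neighbor distance to
    the expectation 0.5·sqrt(area/n) under complete spatial randomness.
    The quadrat dispersion index is variance/mean (sample variance) of
    counts over a ``quadrat_grid × quadrat_grid`` partition of the point
    bounding box; ≈ 1 for Poisson scatter, > 1 for clustering.
    """
    if tissue_area <= 0:
        raise ValidationError("tissue area must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2) if np.size(points) else np.empty((0, 2))
    n = len(pts)
    nan = float("nan")
    out = {
        "nn_distance_mean": nan,
        "nn_distance_sd": nan,
        "clark_evans": nan,
        "quadrat_dispersion": nan,
    }
    if n < 2:
        return out
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    nn = d[:, 1]
    out["nn_distance_mean"] = float(nn.mean())
    out["nn_distance_sd"] = float(nn.std())
    expected = 0.5 * math.sqrt(tissue_area / n)
    out["clark_evans"] = float(nn.mean() / expected)

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    ix = np.minimum((quadrat_grid * (pts - lo) / span).astype(int), quadrat_grid - 1)
    counts = np.zeros((quadrat_grid, quadrat_grid))
    for a, b in ix:
        counts[a, b] += 1
    m = counts.mean()
    out["quadrat_dispersion"] = float(counts.var(ddof=1) / m) if m > 0 else nan
    return out
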