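"""Per-slide image feature vector assembly.

One slide yields a named numeric feature vector combining:

* LTS load: number of detected 40×40 LTS patches, their fraction of the
  tissue cells, and the positive-pixel fraction of the tissue area;
* stain statistics: pooled sum/mean/median/SD of the hematoxylin and DAB
  concentrations within the detected patches (when channel maps are
  available);
* affinity-propagation cluster descriptors and the six validity indices;
* ``graph_v1`` object-graph degree features and spatial homogeneity
  features.

Slides with no detections leave geometry-dependent features as NaN; the
subject-level aggregation skips missing values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import affinity_propagation, cluster_descriptors, validity_indices
from .detector import CELL, PatchGrid
from .graphs import DEFAULT_RADIUS, build_object_graph, degree_features, homogeneity_features
from .stain import StainChannels, stain_statistics


def compute_slide_features(
    grid: PatchGrid,
    tissue_pixels: int | None = None,
    channels: StainChannels | None = None,
    graph_rule: str = "radius",
    graph_parameter: float = DEFAULT_RADIUS,
    quadrat_grid: int = 4,
    ap_seed: int = 0,
) -> dict[str, float]:
    """Compute the named feature vector for one slide.

    ``tissue_pixels`` defaults to the whole slide area when no tissue
    segmentation is supplied.  ``channels`` enables the eight stain
    statistics; without them those columns are omitted.
    """
    h, w = grid.slide_shape
    if tissue_pixels is None:
        tissue_pixels = h * w
    n_cells = grid.positive.size
    tissue_cells = max(1.0, tissue_pixels / (CELL * CELL))

    feats: dict[str, float] = {
        "n_lts_patches": float(grid.n_positive),
        "lts_patch_fraction": float(grid.n_positive / min(tissue_cells, n_cells)),
        "lts_pixel_fraction": float(grid.n_positive * CELL * CELL / tissue_pixels),
    }

    if channels is not None:
        feats.update(stain_statistics(channels, grid))

    points = grid.cell_centers()
    if len(points) >= 1:
        clust = affinity_propagation(points, seed=ap_seed)
        feats.update(cluster_descriptors(clust, points))
        if len(points) >= 2:
            feats.update(validity_indices(clust, points))
        else:
            feats.update(
                dict.fromkeys(
                    (
                        "ball_hall",
                        "banfeld_raftery",
                        "log_ss_ratio",
                        "davies_bouldin",
                        "calinski_harabasz",
                        "c_index",
                    ),
                    float("nan"),
                )
            )
    else:
        feats.update(cluster_descriptors(affinity_propagation(points), points))
        feats.update(
            dict.fromkeys(
                (
                    "ball_hall",
                    "banfeld_raftery",
                    "log_ss_ratio",
                    "davies_bouldin",
                    "calinski_harabasz",
                    "c_index",
                ),
                float("nan"),
            )
        )

    graph = build_object_graph(points, graph_rule, graph_parameter)
    feats.update(degree_features(graph))
    feats.update(
        homogeneity_features(points, float(tissue_pixels), quadrat_grid=quadrat_grid)
    )
    return feats


def cohort_oracle_features(cohort, ap_seed: int = 0) -> pd.DataFrame:
    """Per-slide features for a synthetic cohort via the geometry oracle.

    Each slide's patch grid is produced by the strided-window inference
    rule applied to the ground-truth annotation geometry (probability 1
    for any window touching a foreground object), so the feature stage is
    exercised without detector error.  Returns the tidy per-slide frame.
    """
    from .detector import OracleWindowScorer, infer_slide

    rows, ids = [], []
    for sample in cohort.slides:
        fg = [a.geometry for a in sample.annotations if a.is_foreground]
        _, grid = infer_slide(
            OracleWindowScorer(fg),
            None,
            slide_shape=(sample.spec.height, sample.spec.width),
        )
        rows.append(compute_slide_features(grid, ap_seed=ap_seed))
        ids.append((sample.slide_id, sample.subject_id))
    return features_to_frame(rows, ids)


def features_to_frame(rows: list[dict], ids: list[tuple[str, str]]) -> pd.DataFrame:
    """Stack per-slide feature dicts into a tidy DataFrame.

    ``ids`` supplies (slide_id, subject_id) per row.
    """
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", [s for _, s in ids])
    df.insert(0, "slide_id", [sl for sl, _ in ids])
    return df
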