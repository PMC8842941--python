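"""Patch building, the weighted-loss contract, inference geometry, metrics."""

import numpy as np
import pytest
from shapely.geometry import Point

from ltsq.annotations import AnnotationObject, FOREGROUND, Rank
from ltsq.detector import (
    CELL,
    PATCH,
    LabeledPatch,
    OracleWindowScorer,
    PatchGrid,
    TrainConfig,
    detection_metrics,
    extract_patches,
    f1_score,
    infer_slide,
    train_patch_classifier,
    weighted_cross_entropy,
)
from ltsq.errors import ValidationError


def _blank(h=400, w=400):
    return np.full((h, w, 3), 255.0)


def _obj(x, y, rank, r=5.0):
    return AnnotationObject(Point(x, y).buffer(r), FOREGROUND, rank)


# --- extraction ------------------------------------------------------------


def test_one_definite_object_and_one_negative():
    img = _blank()
    patches = extract_patches(img, [_obj(200, 200, Rank.DEFINITE)], n_negatives=1, seed=0)
    assert len(patches) == 2
    assert sorted(p.loss_weight for p in patches) == [1, 5]
    assert sorted(p.label for p in patches) == [0, 1]


def test_overlapping_objects_take_max_weight():
    img = _blank()
    anns = [_obj(200, 200, Rank.PROBABLE), _obj(210, 205, Rank.DEFINITE)]
    patches = extract_patches(img, anns, n_negatives=0)
    assert all(p.loss_weight == 5 for p in patches)
    assert all(p.label == 1 for p in patches)


def test_empty_annotations_give_weight_one_negatives():
    patches = extract_patches(_blank(), [], n_negatives=10, seed=1)
    assert len(patches) == 10
    assert all(p.label == 0 and p.loss_weight == 1 for p in patches)


def test_border_object_center_clamped_inward():
    img = _blank()
    patches = extract_patches(img, [_obj(5, 5, Rank.POSSIBLE)], n_negatives=0)
    (p,) = patches
    assert p.window.shape[:2] == (PATCH, PATCH)
    assert p.loss_weight == 3 and p.label == 1


# --- weighted loss ---------------------------------------------------------


def test_definite_patch_loss_is_exactly_five_times_weight_one():
    p = np.array([0.2, 0.2])  # same mispredicted probability for a positive
    y = np.array([1, 1])
    per, _ = weighted_cross_entropy(p, y, np.array([5, 1]))
    assert per[0] == pytest.approx(5 * per[1], rel=1e-15)


def test_unit_weights_equal_unweighted_cross_entropy(rng):
    p = rng.uniform(0.01, 0.99, 50)
    y = rng.integers(0, 2, 50)
    _, mean_w = weighted_cross_entropy(p, y, np.ones(50))
    plain = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert mean_w == pytest.approx(plain, abs=1e-12)


def test_single_class_training_rejected():
    win = np.full((PATCH, PATCH, 3), 255.0)
    patches = [LabeledPatch((75, 75), win, 0, 1) for _ in range(4)]
    with pytest.raises(ValidationError):
        train_patch_classifier(patches, TrainConfig(epochs=1))


def test_classifier_learns_separable_patches(training_patches):
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(training_patches))
    tr = [training_patches[i] for i in idx[:160]]
    te = [training_patches[i] for i in idx[160:]]
    model = train_patch_classifier(
        tr, TrainConfig(learning_rate=3e-3, epochs=30, seed=0)
    )
    probs = model.predict_proba(np.stack([p.window for p in te]))
    acc = np.mean((probs > 0.5) == np.array([p.label for p in te]))
    assert acc >= 0.95


# --- inference geometry ----------------------------------------------------


def test_window_starts_at_stride_40_on_311_wide_slide():
    starts = list(range(0, 311 - PATCH + 1, 40))
    assert starts == [0, 40, 80, 120, 160]


def test_constant_zero_model_gives_empty_grid():
    class Zero:
        def score_window(self, r, c):
            return 0.0

    mask, grid = infer_slide(Zero(), None, slide_shape=(400, 400))
    assert grid.n_positive == 0
    assert mask.max() == 0.0


def test_nonpositive_stride_rejected():
    class Zero:
        def score_window(self, r, c):
            return 0.0

    with pytest.raises(ValidationError):
        infer_slide(Zero(), None, stride=0, slide_shape=(400, 400))


def brute_force_positive_cells(geom, shape, stride=40, threshold=0.5):
    """Independent enumeration: a cell is positive iff some full window
    intersecting the object also overlaps the cell footprint."""
    from shapely.geometry import box

    gh, gw = -(-shape[0] // CELL), -(-shape[1] // CELL)
    positive = np.zeros((gh, gw), dtype=bool)
    for r0 in range(0, shape[0] - PATCH + 1, stride):
        for c0 in range(0, shape[1] - PATCH + 1, stride):
            if not box(c0, r0, c0 + PATCH, r0 + PATCH).intersects(geom):
                continue
            for i in range(r0 // CELL, min(gh, -(-(r0 + PATCH) // CELL))):
                for j in range(c0 // CELL, min(gw, -(-(c0 + PATCH) // CELL))):
                    positive[i, j] = True
    return positive


def test_oracle_inference_matches_window_geometry_enumeration():
    shape = (420, 460)
    geom = Point(230, 190).buffer(6)
    _, grid = infer_slide(OracleWindowScorer([geom]), None, slide_shape=shape)
    assert np.array_equal(grid.positive, brute_force_positive_cells(geom, shape))


def test_positive_count_monotone_in_threshold(rng):
    class Noisy:
        def __init__(self):
            self.r = np.random.default_rng(5)

        def score_window(self, r, c):
            return float(np.random.default_rng(r * 1000 + c).uniform())

    counts = []
    for thr in (0.2, 0.5, 0.8):
        _, grid = infer_slide(Noisy(), None, threshold=thr, slide_shape=(351, 351))
        counts.append(grid.n_positive)
    assert counts[0] >= counts[1] >= counts[2]


# --- grid container --------------------------------------------------------


def test_grid_shape_validation():
    with pytest.raises(ValidationError):
        PatchGrid(np.zeros((2, 2), dtype=bool), (400, 400))
    g = PatchGrid(np.zeros((10, 10), dtype=bool), (400, 400))
    assert g.pixel_mask().shape == (400, 400)


# --- metrics ---------------------------------------------------------------


def test_perfect_prediction_scores_one():
    t = np.array([0, 1, 0, 1, 1])
    m = detection_metrics(t, t, scores=t.astype(float))
    for k in ("sensitivity", "specificity", "precision", "f1", "accuracy", "auc"):
        assert m[k] == pytest.approx(1.0)


def test_no_positives_in_truth_flags_sensitivity():
    m = detection_metrics(np.array([0, 1]), np.array([0, 0]))
    assert np.isnan(m["sensitivity"])
    assert np.isnan(m["auc"])


def test_f1_from_printed_precision_recall():
    assert round(f1_score(0.81, 0.99), 2) == 0.89


def pair_count_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_matches_pair_counting_oracle(rng):
    labels = np.array([0] * 50 + [1] * 50)
    scores = labels.astype(float).copy()
    scores[3] = 1.0  # one flipped score among balanced items
    m = detection_metrics((scores > 0.5).astype(int), labels, scores=scores)
    assert m["auc"] == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)


def test_metrics_invariant_under_item_permutation(rng):
    yp = rng.integers(0, 2, 60)
    yt = rng.integers(0, 2, 60)
    perm = rng.permutation(60)
    a = detection_metrics(yp, yt)
    b = detection_metrics(yp[perm], yt[perm])
    for k in ("sensitivity", "specificity", "precision", "f1", "accuracy"):
        assert a[k] == pytest.approx(b[k], abs=1e-12)
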