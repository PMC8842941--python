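"""End-to-end pipeline: simulate → detect → features → predict → stats.

Stages write their artifacts under a run directory and a manifest records
the configuration hash, the seeds of every stochastic stage and SHA-256
hashes of the outputs, so a rerun with the same configuration reproduces
identical CSV outputs.

Detection supports two modes.  ``oracle`` marks grid cells from the
ground-truth annotation geometry through the same strided-window rule the
learned detector uses — the right default for feature/prediction studies
where detector error is not the question.  ``trained`` fits the reference
patch classifier on extracted patches from rendered slides and runs real
inference; it is intended for small cohorts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .detector import OracleWindowScorer, infer_slide
from .errors import StageDependencyError, ValidationError
from .features import compute_slide_features, features_to_frame
from .prediction import (
    aggregate_subject,
    expert_score_baseline,
    fit_predict_elasticnet,
    predict_stage,
    repeated_lasso_selection,
)
from .stats import kruskal_wallis, mann_whitney_u, spearman_rho

log = logging.getLogger(__name__)

REQUIRED_SEEDS = ("cohort", "detector", "prediction")


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    out_dir: str
    seeds: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    detector_mode: str = "oracle"
    detection_threshold: float = 0.5
    n_repeats: int = 200
    train_frac: float = 0.8
    l1_ratio: float = 0.01
    n_status_features: int = 13
    n_stage_features: int = 5
    run_stats: bool = True

    def __post_init__(self) -> None:
        for name in REQUIRED_SEEDS:
            if name not in self.seeds:
                raise ValidationError(f"config missing seed for stage {name!r}")
        if self.detector_mode not in ("oracle", "trained"):
            raise ValidationError(f"unknown detector mode {self.detector_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=True, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    # --- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    cohort_spec = synthetic.CohortSpec(**{**config.cohort, "seed": config.seeds["cohort"]})
    cohort = synthetic.generate_cohort(cohort_spec)
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    cohort.scores.to_csv(out / "scores.csv", index=False)
    timings["simulate"] = time.perf_counter() - t0

    # --- detect + features -------------------------------------------------
    t0 = time.perf_counter()
    rows, ids = [], []
    model = None
    if config.detector_mode == "trained":
        model = _train_detector(cohort, config)
    for sample in cohort.slides:
        shape = (sample.spec.height, sample.spec.width)
        if config.detector_mode == "oracle":
            fg = [a.geometry for a in sample.annotations if a.is_foreground]
            scorer = OracleWindowScorer(fg)
            _, grid = infer_slide(
                scorer, None, threshold=config.detection_threshold, slide_shape=shape
            )
            channels = None
            tissue_pixels = None
        else:
            render = synthetic.generate_slide(sample.spec)
            _, grid = infer_slide(
                model, render.image, threshold=config.detection_threshold
            )
            from .stain import StainModel, deconvolve, od_transform, tissue_mask

            sm = StainModel()
            channels = deconvolve(od_transform(render.image), sm)
            _, tissue_pixels = tissue_mask(render.image, sm)
        feats = compute_slide_features(
            grid,
            tissue_pixels=tissue_pixels,
            channels=channels,
            ap_seed=config.seeds["detector"],
        )
        log.debug("slide %s: %d positive cells", sample.slide_id, grid.n_positive)
        rows.append(feats)
        ids.append((sample.slide_id, sample.subject_id))
    slide_features = features_to_frame(rows, ids)
    slide_features.to_csv(out / "slide_features.csv", index=False)
    timings["features"] = time.perf_counter() - t0

    # --- aggregate + predict -----------------------------------------------
    t0 = time.perf_counter()
    X = aggregate_subject(slide_features)
    subjects = cohort.subjects.set_index("subject_id").loc[X.index]
    y_status = subjects["status"].to_numpy()
    stages = subjects["stage"].to_numpy()
    seed = config.seeds["prediction"]

    selection = repeated_lasso_selection(
        X, y_status, n_repeats=config.n_repeats, train_frac=config.train_frac, seed=seed
    )
    _write_csv(selection, out / "selection_status.csv")
    top_status = list(selection.index[: config.n_status_features])
    status = fit_predict_elasticnet(
        X[top_status],
        y_status,
        l1_ratio=config.l1_ratio,
        n_repeats=config.n_repeats,
        train_frac=config.train_frac,
        seed=seed,
    )

    selection_stage = repeated_lasso_selection(
        X, stages, n_repeats=config.n_repeats, train_frac=config.train_frac, seed=seed
    )
    top_stage = list(selection_stage.index[: config.n_stage_features])
    stage = predict_stage(
        X[top_stage],
        stages,
        l1_ratio=config.l1_ratio,
        n_repeats=config.n_repeats,
        train_frac=config.train_frac,
        seed=seed,
    )
    baseline = expert_score_baseline(cohort.scores)
    baseline_res = fit_predict_elasticnet(
        baseline.loc[X.index],
        y_status,
        l1_ratio=config.l1_ratio,
        n_repeats=config.n_repeats,
        train_frac=config.train_frac,
        seed=seed,
    )
    report = {
        "status": {"features": top_status, "metrics": status["summary"]},
        "status_expert_baseline": baseline_res["summary"],
        "stage": {
            "features": top_stage,
            "accuracy": {
                v: {k: r[k] for k in ("mean", "sd", "n")} for v, r in stage.items()
            },
        },
    }
    (out / "prediction.json").write_text(json.dumps(report, indent=2))
    timings["predict"] = time.perf_counter() - t0

    # --- stats -------------------------------------------------------------
    if config.run_stats:
        t0 = time.perf_counter()
        score_max = cohort.scores.groupby("subject_id")["score"].max().loc[X.index]
        stat_rows = []
        for feat in top_status:
            vals = X[feat].to_numpy()
            ok = np.isfinite(vals)
            if ok.sum() < 3:
                continue
            rho, p_rho = spearman_rho(vals[ok], score_max.to_numpy()[ok])
            u, p_u = mann_whitney_u(vals[ok & (y_status == 1)], vals[ok & (y_status == 0)])
            groups = [vals[ok & (stages == s)] for s in (1, 2, 3)]
            if all(len(g) for g in groups):
                h, p_h = kruskal_wallis(groups)
            else:
                h, p_h = float("nan"), float("nan")
            stat_rows.append(
                {
                    "feature": feat,
                    "spearman_rho_vs_score": rho,
                    "spearman_p": p_rho,
                    "mannwhitney_u": u,
                    "mannwhitney_p": p_u,
                    "kruskal_h": h,
                    "kruskal_p": p_h,
                }
            )
        pd.DataFrame(stat_rows).to_csv(out / "stats.csv", index=False)
        timings["stats"] = time.perf_counter() - t0

    manifest = {
        "config_digest": config.digest(),
        "config": asdict(config),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _train_detector(cohort, config):
    """Fit the reference classifier on patches from the cohort's slides."""
    from .detector import TrainConfig, extract_patches, train_patch_classifier

    patches = []
    for sample in cohort.slides[: min(6, len(cohort.slides))]:
        render = synthetic.generate_slide(sample.spec)
        patches.extend(
            extract_patches(
                render.image,
                sample.annotations,
                n_negatives=max(2, sample.spec.n_foreground),
                seed=config.seeds["detector"],
            )
        )
    labels = {p.label for p in patches}
    if len(labels) < 2:
        raise StageDependencyError("training slides do not cover both classes")
    tc = TrainConfig(
        learning_rate=3e-3, epochs=30, seed=config.seeds["detector"]
    )
    return train_patch_classifier(patches, tc)
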