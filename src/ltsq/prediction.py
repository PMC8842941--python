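"""Subject-level aggregation, repeated-LASSO feature selection, and
elastic-net prediction of disease status and stage.

With only 56 subjects against ~60 slide features, any single train/test
split is unstable.  The protocol therefore repeats a stratified 80/20
split many times (1000 by default): per repeat an L1-penalized logistic
model is fit on the standardized training subjects and a feature counts
as *selected* when its coefficient is nonzero.  Features are ranked by
selection frequency; the top 13 (status) or 5 (stage) features then feed
an elastic-net logistic model (``l1_ratio = 0.01``) evaluated on each
repeat's held-out subjects, reported as mean ± SD of sensitivity,
specificity, precision, F1 and accuracy (PD is the positive class).

Standardization and median imputation are fit on the training subjects of
each repeat only, so no information leaks from the held-out split.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ValidationError

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = (
    "stage",
    "status",
    "stage_name",
    "true_burden",
    "updrs3",
    "updrs_total",
    "dat_sbr",
    "csf_asyn",
)


def aggregate_subject(
    slide_features: pd.DataFrame, statistic: str = "max"
) -> pd.DataFrame:
    """Collapse per-slide features to one row per subject.

    The per-feature maximum over a subject's slides is the default (it
    out-performs mean/median/min for this burden-like signal); other
    statistics are available behind the flag.  Missing values are skipped;
    a feature missing on every slide stays missing.
    """
    if statistic not in ("max", "mean", "median", "min"):
        raise ValidationError(f"unknown aggregation statistic {statistic!r}")
    if "subject_id" not in slide_features.columns:
        raise ValidationError("slide features need a subject_id column")
    value_cols = [
        c for c in slide_features.columns if c not in ("slide_id", "subject_id")
    ]
    if slide_features.groupby("subject_id").size().min() < 1:
        raise ValidationError("every subject needs at least one slide")
    grouped = slide_features.groupby("subject_id")[value_cols]
    return getattr(grouped, statistic)()


def _prepare(X: pd.DataFrame, y: np.ndarray):
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    if counts.min() < 2:
        raise ValidationError("need at least 2 subjects per class")
    return Xv, y


def _standardize_impute(train: np.ndarray, test: np.ndarray):
    """Median-impute and z-score using training statistics only."""
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)

    def fill(a):
        a = a.copy()
        mask = ~np.isfinite(a)
        a[mask] = np.broadcast_to(med, a.shape)[mask]
        return a

    tr, te = fill(train), fill(test)
    mu = tr.mean(axis=0)
    sd = tr.std(axis=0)
    sd[sd == 0] = 1.0
    return (tr - mu) / sd, (te - mu) / sd


def _pick_C(Xtr, ytr, Cs, cv, penalty, l1_ratio, rng, n_classes=2):
    """Small internal cross-validation on the training split only.

    Candidates are scored by validation log-loss (deviance), and the
    one-standard-error rule keeps the sparsest (smallest C) strength
    whose mean deviance is within one standard error of the best — the
    conventional guard against keeping a weak penalty on uninformative
    data.
    """
    from sklearn.metrics import log_loss

    if len(Cs) == 1:
        return Cs[0]
    Cs = sorted(Cs)
    n_splits = min(cv, np.bincount(pd.factorize(ytr)[0]).min())
    if n_splits < 2:
        return Cs[len(Cs) // 2]
    skf = StratifiedKFold(
        n_splits=n_splits, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    classes = np.unique(ytr)
    means, ses = [], []
    for C in Cs:
        losses = []
        for tr, va in skf.split(Xtr, ytr):
            m = _make_model(penalty, C, l1_ratio, n_classes)
            m.fit(Xtr[tr], ytr[tr])
            losses.append(
                log_loss(ytr[va], m.predict_proba(Xtr[va]), labels=classes)
            )
        means.append(float(np.mean(losses)))
        ses.append(float(np.std(losses) / np.sqrt(len(losses))))
    best = int(np.argmin(means))
    cutoff = means[best] + ses[best]
    for i, C in enumerate(Cs):
        if means[i] <= cutoff:
            return C
    return Cs[best]


def _make_model(penalty, C, l1_ratio, n_classes=2):
    if penalty == "l1":
        solver = "liblinear" if n_classes == 2 else "saga"
        return LogisticRegression(
            l1_ratio=1.0, C=C, solver=solver, max_iter=2000, random_state=0
        )
    return LogisticRegression(
        C=C,
        l1_ratio=l1_ratio,
        solver="saga",
        max_iter=5000,
        random_state=0,
    )


def repeated_lasso_selection(
    X: pd.DataFrame,
    y,
    n_repeats: int = 1000,
    train_frac: float = 0.8,
    seed: int = 0,
    Cs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
    cv: int = 3,
) -> pd.DataFrame:
    """Selection frequency and mean importance from repeated LASSO fits.

    Per repeat: stratified ``train_frac`` split, L1-logistic fit on the
    standardized training subjects (penalty strength chosen by a small
    internal cross-validation), feature *selected* iff its coefficient is
    nonzero.  Returns a DataFrame indexed by feature with ``frequency``
    (fraction of repeats selecting it) and ``mean_importance`` (mean
    |coefficient| over selecting repeats), sorted by frequency.
    """
    Xv, y = _prepare(X, y)
    rng = np.random.default_rng(seed)
    nsel = np.zeros(Xv.shape[1])
    imp = np.zeros(Xv.shape[1])
    for _ in range(n_repeats):
        tr, te = _stratified_split(len(y), y, train_frac, rng)
        Xtr, _ = _standardize_impute(Xv[tr], Xv[te])
        k = len(np.unique(y))
        C = _pick_C(Xtr, y[tr], Cs, cv, "l1", None, rng, k)
        model = _make_model("l1", C, None, k)
        model.fit(Xtr, y[tr])
        coef = np.abs(model.coef_).max(axis=0)
        chosen = coef > 0
        nsel += chosen
        imp += np.where(chosen, coef, 0.0)
    freq = nsel / n_repeats
    with np.errstate(invalid="ignore"):
        mean_imp = np.where(nsel > 0, imp / np.maximum(nsel, 1), 0.0)
    out = pd.DataFrame(
        {"frequency": freq, "mean_importance": mean_imp}, index=list(X.columns)
    )
    return out.sort_values("frequency", ascending=False)


def _stratified_split(n, y, train_frac, rng):
    """Stratified split; falls back to a checked plain split when the test
    fold is too small to hold every class (tiny cohorts)."""
    for _ in range(100):
        state = int(rng.integers(2**31 - 1))
        try:
            tr, te = train_test_split(
                np.arange(n), train_size=train_frac, stratify=y, random_state=state
            )
        except ValueError:
            tr, te = train_test_split(
                np.arange(n), train_size=train_frac, random_state=state
            )
        if len(np.unique(y[tr])) == len(np.unique(y)):
            return tr, te
        log.debug("resampled split lacking a training class")
    raise ValidationError("could not produce a split containing every class")


def _binary_metrics(y_true, y_pred, positive=1):
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    tn = int(np.sum((y_pred != positive) & (y_true != positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))

    def ratio(a, b):
        return a / b if b else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = (
        2 * prec * sens / (prec + sens)
        if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
        else float("nan")
    )
    acc = ratio(tp + tn, len(y_true))
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "accuracy": acc,
    }


def fit_predict_elasticnet(
    X: pd.DataFrame,
    y,
    l1_ratio: float = 0.01,
    n_repeats: int = 1000,
    train_frac: float = 0.8,
    seed: int = 0,
    Cs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
    cv: int = 3,
) -> dict:
    """Repeated-split elastic-net logistic prediction of PD status.

    Returns per-repeat metric arrays and their mean ± population SD
    (the reporting convention for the protocol).  Repeats whose test
    split is degenerate for a metric leave that repeat NaN and are
    excluded from the mean/SD (count logged).
    """
    Xv, y = _prepare(X, y)
    rng = np.random.default_rng(seed)
    names = ("sensitivity", "specificity", "precision", "f1", "accuracy")
    per_repeat = {m: np.full(n_repeats, np.nan) for m in names}
    for i in range(n_repeats):
        tr, te = _stratified_split(len(y), y, train_frac, rng)
        Xtr, Xte = _standardize_impute(Xv[tr], Xv[te])
        C = _pick_C(Xtr, y[tr], Cs, cv, "elasticnet", l1_ratio, rng)
        model = _make_model("elasticnet", C, l1_ratio)
        model.fit(Xtr, y[tr])
        pred = model.predict(Xte)
        for m, v in _binary_metrics(y[te], pred).items():
            per_repeat[m][i] = v
    summary = {}
    for m in names:
        vals = per_repeat[m]
        ok = np.isfinite(vals)
        if ok.sum() < n_repeats:
            log.debug("%s: %d degenerate repeats excluded", m, n_repeats - ok.sum())
        summary[m] = {
            "mean": float(np.mean(vals[ok])) if ok.any() else float("nan"),
            "sd": float(np.std(vals[ok])) if ok.any() else float("nan"),
        }
    return {"per_repeat": per_repeat, "summary": summary}


def predict_stage(
    X: pd.DataFrame,
    stages,
    variants: tuple[str, ...] = ("0-3", "1-3"),
    l1_ratio: float = 0.01,
    n_repeats: int = 1000,
    train_frac: float = 0.8,
    seed: int = 0,
    Cs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
    cv: int = 3,
) -> dict:
    """Multinomial elastic-net stage prediction under the repeated protocol.

    Variant ``"0-3"`` uses all subjects; ``"1-3"`` drops controls and
    predicts among PD stages only.  Accuracy is the fraction of correct
    test-split assignments, reported mean ± SD over repeats.
    """
    stages = np.asarray(stages)
    out = {}
    for variant in variants:
        if variant == "0-3":
            keep = np.ones(len(stages), dtype=bool)
        elif variant == "1-3":
            keep = stages > 0
        else:
            raise ValidationError(f"unknown stage variant {variant!r}")
        Xv, yv = _prepare(X.loc[keep], stages[keep])
        rng = np.random.default_rng(seed)
        acc = np.full(n_repeats, np.nan)
        for i in range(n_repeats):
            tr, te = _stratified_split(len(yv), yv, train_frac, rng)
            Xtr, Xte = _standardize_impute(Xv[tr], Xv[te])
            C = _pick_C(Xtr, yv[tr], Cs, cv, "elasticnet", l1_ratio, rng)
            model = _make_model("elasticnet", C, l1_ratio)
            model.fit(Xtr, yv[tr])
            acc[i] = float(np.mean(model.predict(Xte) == yv[te]))
        out[variant] = {
            "mean": float(np.nanmean(acc)),
            "sd": float(np.nanstd(acc)),
            "n": int(keep.sum()),
            "per_repeat": acc,
        }
    return out


def expert_score_baseline(scores: pd.DataFrame) -> pd.DataFrame:
    """Subject-level derivatives of the per-slide 0–3 expert scores.

    Four documented derivative features mirror cumulative-positivity
    summaries: max score, mean score, count of positive (score > 0)
    slides, and an any-positive flag.
    """
    if not set(scores["score"]).issubset({0, 1, 2, 3}):
        raise ValidationError("scores must lie in {0, 1, 2, 3}")
    g = scores.groupby("subject_id")["score"]
    return pd.DataFrame(
        {
            "score_max": g.max().astype(float),
            "score_mean": g.mean(),
            "score_positive_count": g.apply(lambda s: float((s > 0).sum())),
            "score_any_positive": g.apply(lambda s: float((s > 0).any())),
        }
    )
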