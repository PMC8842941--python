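"""Synthetic slides, annotations, raters and cohorts.

Real submandibular-gland whole-slide images are not publicly available,
so the pipeline ships a physically grounded generator that every
downstream stage can be exercised against:

* **Slides** are composed in optical-density space: a smooth hematoxylin
  tissue field c_H plus a DAB field c_D painted along curvilinear
  neurite-like strokes (foreground LTS objects; ``possible``-rank objects
  are small dot-like discs matching their cross-sectional morphology) and
  blob artifacts (background objects).  The RGB image is the Beer–Lambert
  composition I_c = I0_c · 10^(−OD_c) with OD = c_H·v_H + c_D·v_D, so
  color deconvolution recovers the generating fields exactly when noise
  is off.
* **Placement** follows a Thomas-type parent–offspring process so the
  spatial clustering features have signal; dispersion 0 means uniform
  placement.
* **Cohorts** mirror the study design: control / early / moderate /
  advanced subjects with a monotone LTS burden gradient, 13 slides per
  subject, per-slide 0–3 expert scores assigned by thresholding true
  object counts, and clinical covariates (MDS-UPDRS up, DAT-SBR down)
  coupled to burden.
* **Raters** are simulated by pushing true object categories through a
  per-rank confusion matrix, for exercising the concordance statistics.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point, box

from .annotations import AnnotationObject, FOREGROUND, BACKGROUND, Rank
from .concordance import RatingTable
from .errors import ValidationError
from .stain import StainModel, od_inverse

#: Per-slide expert LTS score rubric: thresholds on the true object count.
#: 0 = negative, 1 = sparse (1–9), 2 = moderate (10–49), 3 = frequent (≥50).
SCORE_THRESHOLDS = (1, 10, 50)

_RANK_ORDER = (Rank.DEFINITE, Rank.PROBABLE, Rank.POSSIBLE)


def score_from_count(n_objects: int) -> int:
    """Map a slide's true LTS object count to the 0–3 density score."""
    s = 0
    for t in SCORE_THRESHOLDS:
        if n_objects >= t:
            s += 1
    return s


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic slide."""

    height: int = 605
    width: int = 605
    n_definite: int = 5
    n_probable: int = 3
    n_possible: int = 2
    n_background: int = 8
    spatial_clustering: float = 3.0
    dab_amount_range: tuple[float, float] = (0.4, 0.9)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 302 or self.width < 302:
            raise ValidationError("slide must be at least 302 px per side")
        counts = (self.n_definite, self.n_probable, self.n_possible, self.n_background)
        if any(c < 0 for c in counts):
            raise ValidationError("object counts must be non-negative")
        if self.spatial_clustering < 0:
            raise ValidationError("spatial_clustering must be >= 0")
        lo, hi = self.dab_amount_range
        if not (0 < lo <= hi):
            raise ValidationError("dab_amount_range must be a positive interval")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def n_foreground(self) -> int:
        return self.n_definite + self.n_probable + self.n_possible


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic study cohort.

    Defaults mirror the study's composition: 14 controls and 42 PD
    subjects (15 early / 13 moderate / 14 advanced) with 13 slides each,
    and a monotone mean-LTS-burden gradient over stages.  Score-0 slides
    are not forced empty: the control mean allows an occasional object,
    matching slides scored negative that still harbour rare LTS.
    """

    n_control: int = 14
    n_early: int = 15
    n_moderate: int = 13
    n_advanced: int = 14
    slides_per_subject: int = 13
    stage_burden_means: tuple[float, float, float, float] = (1.5, 8.0, 20.0, 40.0)
    burden_dispersion: float = 4.0  # negative-binomial shape; larger = closer to Poisson
    slide_height: int = 805
    slide_width: int = 805
    spatial_clustering: float = 3.0
    background_mean: float = 8.0
    dab_amount_range: tuple[float, float] = (0.4, 0.9)
    noise_sd: float = 0.0
    updrs3_noise: float = 6.0
    dat_sbr_noise: float = 0.25
    csf_noise: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slides_per_subject < 1:
            raise ValidationError("slides_per_subject must be >= 1")
        m = self.stage_burden_means
        if any(b > a for a, b in zip(m[1:], m[:-1])):
            raise ValidationError("stage_burden_means must be non-decreasing")
        if min(self.n_control, self.n_early, self.n_moderate, self.n_advanced) < 0:
            raise ValidationError("subject counts must be non-negative")


# ---------------------------------------------------------------------------
# slide generation


@dataclass
class SlideRender:
    """A rendered slide with its exact generating fields."""

    image: np.ndarray  # H×W×3 float RGB in (0, 255]
    annotations: list[AnnotationObject]
    c_hematoxylin: np.ndarray
    c_dab: np.ndarray
    tissue: np.ndarray  # boolean tissue field
    stain_model: StainModel


def _place_centers(n: int, spec: SlideSpec, rng: np.random.Generator) -> np.ndarray:
    """Thomas-type parent–offspring placement (x, y), inset from borders."""
    margin = 30
    lo = np.array([margin, margin])
    hi = np.array([spec.width - margin, spec.height - margin])
    if n == 0:
        return np.empty((0, 2))
    if spec.spatial_clustering == 0:
        return rng.uniform(lo, hi, size=(n, 2))
    sd = max(6.0, 150.0 / (1.0 + spec.spatial_clustering))
    n_parents = max(1, int(np.ceil(n / 6)))
    parents = rng.uniform(lo, hi, size=(n_parents, 2))
    assign = rng.integers(0, n_parents, size=n)
    pts = parents[assign] + rng.normal(0, sd, size=(n, 2))
    return np.clip(pts, lo, hi)


def _neurite_geometry(center, rng, n_steps, step, width):
    """Random-walk polyline dilated to a polygon (linear neurite)."""
    angle = rng.uniform(0, 2 * np.pi)
    pts = [np.asarray(center, dtype=float)]
    for _ in range(n_steps):
        angle += rng.normal(0, 0.5)
        pts.append(pts[-1] + step * np.array([np.cos(angle), np.sin(angle)]))
    return LineString(pts).buffer(width / 2, quad_segs=4)


def generate_objects(spec: SlideSpec) -> list[AnnotationObject]:
    """Sample the slide's annotation objects (geometry, class, rank).

    Deterministic given ``spec.seed`` and independent of the image
    rendering, so cohorts can carry exact annotations without
    rasterizing every slide.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])
    bounds = box(0, 0, spec.width - 1, spec.height - 1)
    out: list[AnnotationObject] = []

    n_fg = spec.n_foreground
    centers = _place_centers(n_fg, spec, rng)
    ranks = (
        [Rank.DEFINITE] * spec.n_definite
        + [Rank.PROBABLE] * spec.n_probable
        + [Rank.POSSIBLE] * spec.n_possible
    )
    for center, rank in zip(centers, ranks):
        if rank == Rank.POSSIBLE:
            geom = Point(center).buffer(rng.uniform(2, 4), quad_segs=6)
        elif rank == Rank.PROBABLE:
            geom = _neurite_geometry(center, rng, rng.integers(3, 6), 7.0, 4.0)
        else:
            geom = _neurite_geometry(center, rng, rng.integers(6, 11), 8.0, 5.0)
        geom = geom.intersection(bounds)
        out.append(AnnotationObject(geom, FOREGROUND, rank))

    bg_centers = _place_centers(spec.n_background, replace(spec, spatial_clustering=0.0), rng)
    for center in bg_centers:
        geom = Point(center).buffer(rng.uniform(3, 6), quad_segs=6).intersection(bounds)
        out.append(AnnotationObject(geom, BACKGROUND, None))
    return out


def _paint_geometry(canvas: np.ndarray, geom, amount: float) -> None:
    from skimage.draw import polygon as draw_polygon

    polys = getattr(geom, "geoms", [geom])
    for poly in polys:
        if poly.is_empty or not hasattr(poly, "exterior"):
            continue
        xs, ys = poly.exterior.xy
        rr, cc = draw_polygon(np.asarray(ys), np.asarray(xs), shape=canvas.shape)
        canvas[rr, cc] = np.maximum(canvas[rr, cc], amount)


def generate_slide(
    spec: SlideSpec, stain_model: StainModel | None = None
) -> SlideRender:
    """Render a synthetic H-DAB slide and return it with exact annotations.

    The hematoxylin field is a smooth random tissue blob (zero on glass);
    the DAB field is painted inside each object's geometry with an amount
    drawn from ``spec.dab_amount_range``.  With ``noise_sd = 0`` the RGB
    image is the exact Beer–Lambert composition of the returned fields.
    """
    stain_model = stain_model or StainModel()
    ss = np.random.SeedSequence(spec.seed)
    _, field_seed = ss.spawn(2)
    rng = np.random.default_rng(field_seed)
    h, w = spec.height, spec.width

    annotations = generate_objects(spec)

    # smooth tissue blob covering most of the slide
    g = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 6)
    tissue = g > np.quantile(g, 0.22)
    amp = 0.3 + 0.25 * (gaussian_filter(rng.standard_normal((h, w)), sigma=25) > 0)
    c_h = np.where(tissue, amp, 0.0)

    c_d = np.zeros((h, w))
    lo, hi = spec.dab_amount_range
    for a in annotations:
        _paint_geometry(c_d, a.geometry, rng.uniform(lo, hi))

    v_h = np.asarray(stain_model.od_vector_hematoxylin)
    v_d = np.asarray(stain_model.od_vector_dab)
    od = c_h[..., None] * v_h + c_d[..., None] * v_d
    image = od_inverse(od, stain_model.background_intensity)
    if spec.noise_sd > 0:
        image = image + rng.normal(0, spec.noise_sd, image.shape)
        image = np.clip(image, 1.0, np.asarray(stain_model.background_intensity))
    return SlideRender(image, annotations, c_h, c_d, tissue, stain_model)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class SlideSample:
    slide_id: str
    subject_id: str
    spec: SlideSpec
    annotations: list[AnnotationObject]
    n_lts_true: int
    score: int


@dataclass
class Cohort:
    """A simulated study cohort: subjects, slides and expert scores."""

    spec: CohortSpec
    subjects: pd.DataFrame
    slides: list[SlideSample]

    @property
    def scores(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"slide_id": s.slide_id, "subject_id": s.subject_id, "score": s.score}
                for s in self.slides
            ]
        )

    def render(self, slide_id: str) -> SlideRender:
        sample = next(s for s in self.slides if s.slide_id == slide_id)
        return generate_slide(sample.spec)


_STAGES = ("control", "early", "moderate", "advanced")


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the full cohort: slides, annotations, scores, clinical data.

    Per-slide LTS counts are negative-binomial around the subject stage's
    burden mean; rank composition is multinomial (45% definite / 30%
    probable / 25% possible).  MDS-UPDRS rises and DAT-SBR falls with the
    subject's true mean burden through saturating couplings, with
    Gaussian noise from the spec.  Slide images are not rasterized here;
    ``Cohort.render`` reproduces any slide exactly from its stored spec.
    """
    rng = np.random.default_rng(spec.seed)
    stage_counts = (spec.n_control, spec.n_early, spec.n_moderate, spec.n_advanced)

    subjects = []
    slides: list[SlideSample] = []
    sid = 0
    for stage, n_subj in enumerate(stage_counts):
        mean_burden = spec.stage_burden_means[stage]
        for _ in range(n_subj):
            subject_id = f"S{sid:03d}"
            sid += 1
            slide_counts = []
            for k in range(spec.slides_per_subject):
                if mean_burden == 0:
                    n_lts = 0
                else:
                    shape = spec.burden_dispersion
                    lam = rng.gamma(shape, mean_burden / shape)
                    n_lts = int(rng.poisson(lam))
                n_def, n_prob, n_poss = rng.multinomial(n_lts, (0.45, 0.30, 0.25))
                sspec = SlideSpec(
                    height=spec.slide_height,
                    width=spec.slide_width,
                    n_definite=int(n_def),
                    n_probable=int(n_prob),
                    n_possible=int(n_poss),
                    n_background=int(rng.poisson(spec.background_mean)),
                    spatial_clustering=spec.spatial_clustering,
                    dab_amount_range=spec.dab_amount_range,
                    noise_sd=spec.noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                slide_counts.append(n_lts)
                slides.append(
                    SlideSample(
                        slide_id=f"{subject_id}_W{k:02d}",
                        subject_id=subject_id,
                        spec=sspec,
                        annotations=generate_objects(sspec),
                        n_lts_true=n_lts,
                        score=score_from_count(n_lts),
                    )
                )
            burden = float(np.mean(slide_counts))
            sat = 1.0 - np.exp(-burden / 15.0)
            updrs3 = max(0.0, 1.0 + 28.0 * sat + rng.normal(0, spec.updrs3_noise))
            updrs_total = max(0.0, updrs3 * 1.65 + rng.normal(0, spec.updrs3_noise))
            dat_sbr = max(0.3, 2.8 - 1.5 * sat + rng.normal(0, spec.dat_sbr_noise))
            csf = max(200.0, 1800.0 - 6.0 * burden + rng.normal(0, spec.csf_noise))
            subjects.append(
                {
                    "subject_id": subject_id,
                    "stage": stage,
                    "status": int(stage > 0),
                    "stage_name": _STAGES[stage],
                    "true_burden": burden,
                    "updrs3": updrs3,
                    "updrs_total": updrs_total,
                    "dat_sbr": dat_sbr,
                    "csf_asyn": csf,
                }
            )
    return Cohort(spec, pd.DataFrame(subjects), slides)


# ---------------------------------------------------------------------------
# rater simulation


def truth_category(obj: AnnotationObject) -> str:
    """The rating category of an object: its rank name or 'background'."""
    return Rank(obj.rank).name.lower() if obj.is_foreground else "background"


def simulate_raters(
    objects: list[AnnotationObject],
    n_raters: int,
    confusion: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> RatingTable:
    """Simulate independent raters through a per-category confusion matrix.

    ``confusion[true][rated]`` is the probability a rater assigns
    ``rated`` to an object of true category ``true``; rows must be
    probability vectors.  The identity matrix reproduces the truth for
    every rater.
    """
    cats = ("definite", "probable", "possible", "background")
    if confusion is None:
        confusion = {c: {c: 1.0} for c in cats}
    rows = {}
    for true_cat, row in confusion.items():
        p = np.array([row.get(c, 0.0) for c in cats], dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"confusion row for {true_cat!r} is not stochastic")
        rows[true_cat] = p
    rng = np.random.default_rng(seed)
    table = np.empty((len(objects), n_raters), dtype=object)
    for i, obj in enumerate(objects):
        true_cat = truth_category(obj)
        if true_cat not in rows:
            raise ValidationError(f"no confusion row for category {true_cat!r}")
        draws = rng.choice(len(cats), size=n_raters, p=rows[true_cat])
        table[i] = [cats[d] for d in draws]
    return RatingTable(table)
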