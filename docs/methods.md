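# Methods

This note records the scientific model behind `ltsq`, the defaults that
matter, the open design choices we made, and what the synthetic testbed
does and does not establish about real slides.

## Imaging model and stain separation

Brightfield H-DAB immunohistochemistry is treated as Beer–Lambert
absorption. A pixel with background intensity I0_c (default 255 per RGB
channel) and optical density OD_c transmits I_c = I0_c·10^(−OD_c), and
OD is linear in stain concentrations: OD = c_H·v_H + c_D·v_D, with v_H
and v_D the unit optical-density vectors of hematoxylin and DAB. We use
the standard published H-DAB triplets, H ∝ (0.650, 0.704, 0.286) and
DAB ∝ (0.269, 0.568, 0.778), normalized; the third basis vector is
their normalized cross product and absorbs residual absorbance.
Deconvolution inverts the 3×3 basis per pixel; negative concentrations
are clamped to zero (count logged) because absorbance cannot be
negative. Per-slide basis estimation and cross-scanner stain
normalization are out of scope.

Zero intensities are clamped to 1 before the log, bounding OD at
log10(255) ≈ 2.41 per channel. Stain statistics (sum, mean, median, SD
of H and DAB) pool all pixels inside detected 40×40 cells; the SD uses
the population denominator n, fixed for reproducibility. Pooling (not
per-patch averaging) is the default; `per_patch` averaging would be the
natural alternative and pooling was chosen because the statistics then
depend only on the detected region, not its partition into cells.
Tissue is segmented as pixels whose OD magnitude after 3×3 median
smoothing exceeds 0.05 — on glass the OD is numerically zero, so the
threshold only needs to reject noise.

## Synthetic slides and cohorts

The generator exists so that every downstream stage has a testbed with
known ground truth; it emulates structure, not texture.

* **Tissue**: a smoothed Gaussian random field thresholded at its 22nd
  percentile gives a tissue blob covering ~78% of the slide; the
  hematoxylin field is 0.30 or 0.55 inside tissue (piecewise via a
  second smooth field) and exactly zero on glass.
* **LTS objects**: definite and probable objects are random-walk
  polylines (6–10 and 3–5 steps of 8 and 7 px, widths 5 and 4 px)
  dilated to polygons — the linear neurite morphology; possible-rank
  objects are 2–4 px discs, matching their dot-like cross-sections.
  Background objects are 3–6 px discs (immunopositive granules/
  macrophages). DAB amount per object is uniform in (0.4, 0.9) OD.
* **Placement**: a Thomas-type parent–offspring process (≈6 offspring
  per parent, offspring SD = max(6, 150/(1+κ)) px, κ the spec's
  dispersion parameter, κ=0 → uniform) so that the spatial clustering
  features carry real signal.
* **Cohort**: 14 controls and 42 PD subjects (15 early / 13 moderate /
  14 advanced), 13 slides per subject. Per-slide object counts are
  negative-binomial (gamma-Poisson, shape 4) around stage means
  (1.5, 8, 20, 40). The control mean is nonzero deliberately: slides
  scored negative can still harbour rare LTS objects, and the study
  context reports a small mean object count even in score-0 slides.
  Per-slide 0–3 scores threshold the true count at (1, 10, 50) —
  negative / sparse / moderate / frequent; the true count
  distribution per score class is not published, so these defaults are
  stated-once placeholders. Clinical covariates couple to the
  subject's mean burden B through a saturating term
  s = 1 − exp(−B/15): UPDRS-III = 1 + 28·s + N(0, 6), total =
  1.65×part III + N(0, 6), DAT-SBR = 2.8 − 1.5·s + N(0, 0.25) (floored
  at 0.3), CSF α-synuclein = 1800 − 6·B + N(0, 300). Magnitudes are
  chosen to bracket typical control/advanced group means; only the
  signs and monotonicity are load-bearing for the tests.
* **Raters**: true object categories pushed through a per-category
  confusion matrix, independently per rater.

Everything is a pure function of (spec, seed); slide rendering and
object placement use separate child streams of the same seed, so a
cohort can carry exact annotations without rasterizing images and any
slide can be rendered identically later.

What passing tests on this generator show: the pipeline's stages are
internally consistent, recover planted signal, and are exactly
reproducible. What they do not show: performance on real tissue, where
texture, staining variability, scanner artifacts, and annotator
disagreement are all harder than the emulation.

## Detector

The detector answers "does this 151×151 window contain any LTS object?"
rather than localizing objects. A patch is positive iff its window
geometrically intersects at least one foreground object — no area
cutoff — and its loss weight is the maximum over intersecting objects
of (definite 5, probable 4, possible 3), else 2 for replayed false
positives, else 1. The training objective is mean(weight × binary
cross-entropy); with unit weights this is exactly the unweighted loss,
and a weight-5 sample contributes exactly five times an identically
predicted weight-1 sample (tested to machine precision).

The backbone is pluggable. Production-scale work would use a deep CNN
(e.g. an InceptionV4 with its first-layer stride set to 1 to accept
151×151 inputs); that is GPU-scale and deliberately outside this
package. The shipped reference network projects the window's OD onto
the deconvolved DAB channel, mean-pools a centered 144×144 crop to
12×12 blocks, appends the window's DAB mean/SD/max, standardizes with
training statistics, and trains a 16-unit tanh hidden layer into a
logistic output with Adam (defaults lr 1e-5, weight decay 1e-3 on
weights only, batch 32, 80 epochs; the CPU-scale tests use lr 3e-3 and
30 epochs). It reaches ≥0.95 held-out accuracy on separable synthetic
patches in ~2 s.

Inference tiles the slide with full windows at a 40-px stride (partial
edge windows are skipped; boundary cells inherit coverage from the last
full windows), writes each window's probability onto its footprint with
max-aggregation (preserves recall; the aggregation is commutative, so
evaluation order is irrelevant), and marks a 40×40 cell positive iff
the mask maximum inside it reaches the threshold (default 0.5, exposed
in config since no canonical value exists).

## Clustering and validity indices

Detected-cell centers are clustered by affinity propagation on
s(i,k) = −‖x_i − x_k‖² with the preference defaulting to the median
off-diagonal similarity, max_iter 200 and convergence after 15 stable
sweeps. A tiny seeded jitter (1e-12 of the similarity range) breaks
exact ties from duplicated points. **Damping defaults to 0.7**: the
conventional 0.5 oscillates without converging on symmetric
well-separated patterns — precisely the clustered point sets this
pipeline produces (the reference sklearn implementation shows the
identical failure) — while very heavy damping (0.9) evolves so slowly
that the stability-based stopping rule fires before the messages
settle. 0.7 converges in every regime we test, including the
preference → −∞ limit where a single cluster must emerge. After message
passing, each cluster's exemplar is refined to the member maximizing
within-cluster similarity, matching the reference implementation's
final step.

Descriptors and indices follow the classical definitions (see the
module docstrings for formulas). Numerical guards: within-cluster
variance ratios inside logs are floored at 1e-12 (Banfeld-Raftery with
singleton clusters); K=1 leaves Davies-Bouldin, Calinski-Harabasz,
log-SS-ratio and C-index as NaN; WGSS=0 with K≥2 yields +inf
Calinski-Harabasz. All indices are checked against independent
brute-force double-loop implementations to 1e-9.

## Object graphs and homogeneity (graph_v1)

The study this pipeline models relied partly on proprietary,
unpublished object-graph features. Rather than guess their formulas,
the package ships an open, versioned set (`graph_v1`) over the same
graph idea: a radius graph on detected-cell centers (default r = 120 px
= 3 cell widths, capturing local neighborhoods at patch scale; k-NN and
Delaunay rules available), summarized by mean/SD/max degree, isolated
fraction, degree entropy (bits), degree assortativity, and mean local
clustering. Homogeneity features are mean/SD nearest-neighbor
distance, the Clark–Evans ratio R = mean NN distance / (0.5√(area/n))
(no edge correction; with n ≥ a few hundred the bias is a few percent),
and the quadrat variance/mean dispersion index over a 4×4 grid of the
point bounding box (sample variance). Numeric equality with the
original study's feature values is impossible by construction and not a
goal.

## Prediction protocol

Per-slide features aggregate to subjects by the per-feature **maximum**
over slides (mean/median/min behind a flag) — burden-like signals
concentrate in the worst slide. The repeated protocol then guards the
56-subject, ~40-feature regime against split instability:

* stratified 80/20 train/test splits (with 14 controls an unstratified
  20% test often lacks controls; tiny cohorts fall back to a checked
  plain split), 1000 repeats by default (200 in the shipped tests and
  acceptance run — large enough that frequency estimates move by only
  a few percent);
* per repeat, median imputation and z-scoring are fit on the training
  subjects only;
* LASSO logistic selection (liblinear; saga for multiclass) with the
  penalty chosen per repeat by 3-fold cross-validated log-loss on the
  training split over C ∈ {0.01, 0.1, 1, 10} under the one-standard-
  error rule — preferring the sparsest strength statistically
  indistinguishable from the best, which correctly collapses to the
  null model on label-independent features;
* elastic-net logistic evaluation (l1_ratio = 0.01) on the top-13
  (status) / top-5 (stage) features by selection frequency, metrics
  averaged over repeats with population-SD spread; degenerate test
  splits leave that repeat's metric missing and excluded.

Selection frequencies on resampled versions of one dataset are
correlated across repeats, so a chance-correlated noise feature can be
selected persistently if the penalty is weak; the deviance + one-SE
choice is what keeps the null case clean.

## Rank statistics

Mann–Whitney U is reported as min(U_a, U_b). For n_a+n_b ≤ 12 the
two-sided p-value enumerates all C(n, n_a) group assignments (valid
under ties); above that, the tie-corrected normal approximation with
continuity correction. Kruskal–Wallis is tie-corrected with a
chi-square (k−1 df) p-value; an all-ties sample returns H = 0 with a
NaN p as the degeneracy flag. Spearman uses mid-ranks. All tests are
two-sided. Exactness/tie conventions of the original study's software
are unknown; these defaults are documented and frozen.

## Pipeline and reproducibility

`run_pipeline` executes simulate → detect → features → predict → stats
under one config with named seeds for every stochastic stage
(validation rejects configs missing one). The default detection mode is
the geometry oracle — the strided-window rule applied to ground-truth
annotations — which is the right instrument when the question is about
features and prediction rather than detector error; `trained` mode fits
and applies the reference network. The manifest records the config
hash and SHA-256 of every output; identical configs reproduce identical
CSVs. Per-stage wall times are recorded in the manifest, never
asserted.

Problem sizes used in the shipped tests and acceptance script: slides
400–805 px per side, cohorts of 56 subjects × 13 slides (728 slides),
~200 training patches, 100–200 protocol repeats. These are the sizes at
which the full pipeline demonstrates its properties while remaining a
few minutes of CPU work.

## Known limitations

* Synthetic slides have no tissue texture, staining gradients, or
  scanner artifacts; detector results on them bound nothing about real
  tissue.
* The reference network's features are stain-specific (DAB projection);
  it is a contract-satisfying reference, not a competitive detector.
* Clark–Evans has no edge correction; quadrat counts use the point
  bounding box rather than the tissue polygon.
* The concordance κ of a simulated rater study depends entirely on the
  assumed confusion matrix; real inter-rater structure (correlated
  errors, item difficulty) is not modeled.
* Expert-score derivative features are documented analogues (max, mean,
  positive count, any-positive), not the original study's unpublished
  derivative definitions.
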