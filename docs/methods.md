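# Methods

This note documents the models, calibrations and numerical conventions
behind `mscmorph`, in the order data flows through the pipeline.

## Synthetic benchmark generator

No public image data exist for this problem, so the package defines a
generative model whose *only* constraints are the facts the study design
fixes: an 11-lot panel (7 Low-risk, 4 High-risk), 3 replicate wells per
lot, frames every 6 h from 12 h to 138 h (22 time points), a >5.8-fold
spread of lot growth rates that overlaps between classes, narrower and
less-expanding single-cell area distributions in High-risk lots
(top-quartile mean area 6000 vs 7000 μm², i.e. 86 %, at 78 h), and bimodal
CFSE fluorescence whose low-intensity mass encodes the proliferated T-cell
fraction. Every distributional form around those anchors is this package's
choice.

**Growth.** Well cell count at time t is
`round(n0 · G^((t−12)/126) · ε_well)` with `G` the lot's true fold-change
and `ε_well` lognormal with CV `well_cv` (default 0.03). Growth presets
are {1.5, 2.2, 2.8, 3.4, 4.2, 5.6, 6.1} for Low-risk and
{6.6, 7.2, 8.1, 9.0} for High-risk lots: a 6.0-fold spread, with the
fastest Low-risk lots overlapping the High-risk range so growth alone
cannot classify. `n0` defaults to 2000 cells per well (500 per
FOV-equivalent quadrant), keeping frames within the 200–10000 cells/image
range the profiling QC assumes.

**Cell areas.** Per-cell spread areas are lognormal(μ(t), σ(t)).
σ(t) ramps linearly from 12 h to 84 h and then plateaus: 0.45 → 0.65
(Low-risk) vs 0.35 → 0.45 (High-risk). μ(t) is calibrated, per time point,
so that the top-quartile mean area follows a linear ramp from 3000 μm² at
seeding to the class target at 78 h (7000 Low / 6000 High), using the
closed form

    E[X | X > q0.75] = exp(μ + σ²/2) · Φ(σ − z0.75) / 0.25,

inverted for μ (`calibrate_area_params`; verified against Monte-Carlo to
<0.5 %).

**Heterogeneity–growth coupling.** Within each class, σ(t) is shifted by
−0.02 per unit of growth-rate deviation from the class preset mean: cells
that divide faster spread less, so the population's morphological
heterogeneity genuinely encodes the growth rate. The class gap in σ
(0.10 at seeding) dominates the coupling (≤0.05 across the preset range),
so the classification signal survives. A per-lot σ jitter N(0, 0.005²) and
a top-quartile-area jitter ×exp(N(0, 0.02²)) make replicate wells of one
lot resemble each other more than other lots, which is what drives the
replicate-clustering behaviour seen in PCA and UPGMA.

**Other descriptors.** The 15 non-area descriptors derive analytically
from area through a rough-ellipse model (aspect ratio 1 + lognormal,
Ramanujan perimeter × a roughness factor ≥ 1, convexity/extent/Feret
noise), with *class-independent* shape noise by default — so the class
signal lives in the distributional SD dynamics, not in mean shape. An
optional `shape_signal` switch adds a class-dependent elongation shift.

**CFSE.** Log10 fluorescence is the mixture
`(1−π) N(3.0, 0.15²) + π N(1.8, 0.25²)` with π the lot's true proliferated
fraction: Low-risk π ~ U(0.01, 0.05); High-risk "risky anomalies"
(positions 1–2 of the preset cycle, lots 8–9) U(0.15, 0.30); "clear
anomalies" (positions 3–4, lots 10–11) U(0.55, 0.80).

**Random streams.** Each lot, well and CFSE sample draws from a
`default_rng([master_seed, stream ids…])` substream, so enlarging a panel
never perturbs previously generated lots, and identical seeds reproduce
byte-identical output.

**What the generator does not model**, and what passing tests therefore do
not show about real data: confluence effects, migration, mitosis events,
debris, physical phase-contrast optics, per-cell tracking, donor
covariates beyond the class label, and any instrument noise structure.
The benchmark demonstrates that the *pipeline* recovers the signals it is
calibrated to contain; performance on real microscope data depends on
signals the generator only postulates.

## Rendering and segmentation

Rendered frames place each cell as a low-order-Fourier-perturbed ellipse
(boundary polygon renormalised to the prescribed area before
rasterisation), brighter rim inside the mask, darker interior, uniform
background with additive Gaussian noise. Placement is overlap-free by
rejection sampling; cells that cannot be placed are dropped, counted and
warned about — never silently.

Segmentation: Gaussian high-pass flattening (σ = 30 px), thresholding of
the absolute contrast at max(Otsu, 5 robust background SDs — the floor
prevents pure-noise fields from yielding regions), closing, hole filling,
minimum-area filter (default 200 μm²). Touching cells are split by a
watershed on the distance transform (markers: smoothed-distance maxima at
minimum separation √(min_area)/2), but only for connected components with
solidity < 0.88: convex single cells are kept whole, because the distance
ridge of an elongated convex cell is a plateau that a blanket watershed
would oversplit.

Descriptor conventions: 8-connected regions; perimeter is the
marching-squares contour length at the 0.5 level of the σ = 1 px smoothed
region — this sub-pixel convention keeps the circle identity
(shape factor 1.00 ± 0.03) and the square's π/4 within 2 %, where
integer boundary-step counting biases smooth boundaries by ~5 %.
Feret diameters come from convex-hull vertex pairs (max) and rotating-
caliper edge-normal widths (min) on the pixel-corner cloud. Single-pixel
regions use a fixed convention (perimeter 4·pixel_size, shape factor
clamped ≤ 1.2) and are flagged.

## Profiling

Frames aggregate to 16 means + 16 sample SDs (n−1 denominator; the choice
is a convention, exposed as `ddof`). Frames with fewer than `min_cells`
(default 200) are QC-flagged; flagged or absent time points are imputed by
linear interpolation in time (nearest value at the edges), standing in for
the manual removal of debris-contaminated frames in real studies; a sample
with >20 % of its schedule missing is rejected with an explicit report.
FOV pseudo-samples are fixed spatial quadrants of the well, consistent
across time; they are used only for classification — for growth-rate
regression the whole well is one sample, enforced by the benchmark
orchestration.

## Assays

The CFSE gate is placed automatically at the kernel-density minimum
between the two highest modes, falling back to the midpoint of a
2-component Gaussian mixture when the density is unimodal; a fixed gate
can be supplied. The score is N_below/N_above (∞-with-flag when nothing
lies above). The High-risk rule — replicate-mean proliferated fraction
> 5 % — is a reconstruction of a peak-pattern judgement, and the cutoff is
configurable. With the default mixture, the auto gate lands in the
inter-peak valley (≈2.5) and the score reproduces the odds π/(1−π) of the
generating fraction (e.g. π = 0.8 → 3.98 at n = 10⁶).

## Modeling

Estimators standardise features with train-fold statistics (zero-variance
features pass through centred). kNN uses Euclidean distance, k = 5,
distance ties broken by the smaller training-row index and vote ties by
the nearest neighbour's label. The "LASSO" classifier is L1-penalised
logistic regression (liblinear); the "LASSO" regressor is plain L1
linear regression; both select their penalty on a 13-point (classifier)
or 15-point (regressor) log grid by an inner lot-grouped 3-fold CV, with
ties resolved toward the stronger penalty. Random forests use 500 trees
with √p features per split and a fixed seed. These defaults are package
choices — the study pins none of them — and all are constructor
parameters.

Positive class for precision is Low-risk (label 1); specificity is the
High-risk recall; the confusion matrix is always emitted so the opposite
convention can be recomputed. Metrics are pooled over held-out
predictions rather than averaged per fold (switchable by consumers of the
per-fold predictions in `CVReport`).

The LASSO selection report counts, per feature, the folds with a nonzero
coefficient and the mean signed weight; the top-15 table sorts by count,
ties by |mean weight|.

## Exploration

PCA operates on the flattened per-sample profile (704 features for the
full window), centred and by default z-scored; component signs are fixed
by making each component's largest-magnitude loading positive.
Hierarchical clustering uses d = 1 − Pearson r over the same flattened
profiles with average (UPGMA) linkage; constant samples are rejected by
name. The SD group test is a pooled-variance two-sample Student's t on
per-well SD values at each requested time point, two-sided.

## Problem sizes and determinism

The shipped benchmark is the full study geometry (11 lots × 3 wells × 22
frames, 132 classification / 33 regression samples) with cell counts of
2000–18000 per well frame; headline metrics are averaged over 10 generator
seeds both in the test suite and in `scripts/acceptance.py`, whose every
random draw derives from `--seed`. Monte-Carlo checks of the area
calibration use 10⁶ draws; CFSE distribution checks use 10⁵–10⁶ events.

## Known limitations

* The true 16-descriptor set of the original instrument software is not
  public; the set here preserves its cardinality and size/shape/
  heterogeneity semantics, and column names are schema-level, so a user
  with the authoritative list can rebind them.
* The CFSE gate, the 5 % risk cutoff, the sample-SD denominator, the
  imputation rule and the pooled-metric convention are reconstructions of
  procedures the study does not specify numerically.
* Growth-rate predictability from only-SD features holds by construction
  of the heterogeneity–growth coupling; its strength on real lots is an
  empirical question the synthetic benchmark cannot answer.
* The renderer is a geometric stand-in for phase-contrast optics; trained
  models should not be expected to transfer to real images without
  re-profiling.
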