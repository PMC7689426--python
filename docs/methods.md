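# Methods

## Scope and data model

The package reimplements, as a tested pipeline, a radiomics prognosis
analysis of short-axis cardiac MR in takotsubo syndrome: per-subject
texture features from one T2-weighted and one LGE slice with a hand-drawn
left-ventricular polygon, reliability-based dimension reduction across
three ROI readings (reader 1 twice, two weeks apart, and reader 2 once),
and ten-fold cross-validated classification of a binary 5-year MACCE
label. Patient cohorts of this kind are not public, so no quantitative
clinical classifier table is a reproduction target here; the pipeline's
correctness is established by exhaustive oracles and by property-based
calibration on a synthetic cohort whose ground truth is known by
construction.

## Preprocessing

Images carry physical pixel spacing (DICOM `PixelSpacing`, or a JSON
sidecar for the 16-bit ASCII-PGM fixture format). All images are resampled
bilinearly to an isotropic 0.390625 mm grid — the native resolution of a
200 mm field of view on a 512 matrix — before any texture computation;
polygons are rescaled and re-rasterized on the target grid rather than
interpolating masks. Order of operations: resample raw intensities first,
then normalize within the resampled ROI, so the normalization window is
computed on the grid that is actually analyzed.

Grey-level normalization is the μ ± 3σ window over in-ROI pixels:
`level(v) = clamp(1 + floor((v − lo)/(hi − lo)·Ng), 1, Ng)` with
`lo = μ − 3σ`, `hi = μ + 3σ`; values at or outside the window clip to the
extreme levels. The exact windowing arithmetic is not standardized across
tools; this mapping is documented here and frozen by unit tests. A
zero-variance ROI maps to all-ones with a warning rather than erroring, so
degenerate fixtures flow through. Rasterization uses the pixel-center
rule on validated simple polygons (geometric containment, equivalent to
even-odd filling); masks below 16 pixels are rejected because
co-occurrence and run-length statistics are meaningless there.

## Texture panel

282 descriptors per ROI, registry-driven (a plain-text registry file can
redefine the panel; duplicate names are rejected at load):

* **Histogram (4)** — mean, variance, skewness, excess kurtosis of the
  windowed (clipped) in-ROI intensities. Variance-zero ROIs define
  skewness/kurtosis as 0.
* **GLCM (220)** — symmetric co-occurrence counts at distances 1–5 and
  offsets (0,a), (a,0), (a,a), (a,−a) (labelled 0°, 90°, 45°, 135°),
  jointly normalized; 11 Haralick statistics on the 6-bit image. Entropies
  use natural logs with 0·log 0 ≡ 0; the sum-variance moment is taken
  about the sum average; a single-level matrix defines correlation as 0.
  Features are kept per direction (not direction-averaged).
* **RLM (20)** — maximal equal-level runs along rows, columns, diagonals
  and anti-diagonals of the 6-bit image, truncated at mask boundaries;
  short/long-run emphasis, grey-level and run-length non-uniformity, and
  run percentage (runs per in-mask pixel).
* **Gradient (5)** — Euclidean magnitude of the central-difference
  gradient on the 4-bit image at pixels whose four axial neighbours are
  in-mask; moments plus the fraction of non-zero gradients.
* **Autoregressive (5)** — causal four-neighbour model (W, NW, N, NE) fit
  by mean-centered least squares over pixels with all four neighbours
  in-mask; σ is the residual standard deviation. Rank-deficient designs
  degenerate to zeros with a warning; fewer than 20 eligible pixels makes
  the family missing.
* **Wavelet (28)** — orthonormal Haar energies (mean squared coefficient)
  of the LL/LH/HL/HH sub-bands at scales 1–7, computed over the largest
  dyadic square inside the mask's bounding box (centred). The input is the
  ROI-standardized image, z = (v − μ)/σ clipped to ±3, so wavelet
  energies — like the quantized families — depend on the segmentation
  through the normalization window. Unrealizable scales are missing, and
  any feature missing for at least one subject is dropped before
  selection.

Missing values propagate explicitly and are never imputed.

## Feature selection

Reliability uses the two-way random-effects, absolute-agreement,
single-measure ICC(2,1) computed from the ANOVA mean squares; raters are
treated as random. Inter-reader ICC pairs reader 1/read 1 with reader 2;
intra-reader ICC pairs reader 1's two reads (two pairwise ICCs rather than
one three-way model). A feature is dropped when min(inter, intra) ≤ 0.6 —
requiring both agreements is the conservative reading of "poor intra- and
inter-reader agreement". Bands follow Landis–Koch (substantial
(0.6, 0.8], excellent (0.8, 1.0]).

Redundancy pruning is a deterministic greedy sweep over ICC survivors in
order of descending mean ICC (ties by registry order): keep a feature iff
its absolute Pearson correlation with every already-kept feature is ≤ 0.8.
|r| is used (a sign-flipped duplicate is equally redundant); the strict
">" comparison carries an 1e-12 epsilon so an exactly-0.8 correlation is
never tipped over by float round-off. Correlations are computed on reader
1/read 1 values. Zero-variance features are dropped with a warning. Age,
sex (0/1) and BMI enter selection like any feature.

## Classification and statistics

Stratified seeded ten-fold CV: with 6 events in 58 subjects, unstratified
folds regularly contain no event, making fold-wise metrics undefined, so
folds are stratified and held-out predictions are pooled across folds
before metrics are computed. Features are standardized per training fold.
Classifier mapping: MLP = one hidden layer of ⌊(p + c)/2⌋ units, SGD with
learning rate 0.3 and momentum 0.2; J48 = entropy-criterion decision tree
with cost-complexity pruning (α = 0.01); Gaussian naive Bayes (a
from-scratch reference implementation backs the posterior oracle test);
random forest = 100 bagged trees with √p feature subsampling; SMO =
linear-kernel SVC. All are seeded; every run is bit-reproducible given
(spec, seed, table).

Metrics: sensitivity, specificity, precision, recall, F-measure, midrank
ROC-AUC (identical to Mann–Whitney U/(n₁n₂), cross-checked in tests), and
average-precision PRC area. Both label orientations are always reported
because the positive class behind this kind of published table is often
ambiguous. Confidence intervals are normal-approximation intervals of the
mean over 10 independently seeded CV replicates — published bracketed
intervals of this kind rarely state their derivation, so the replication
scheme is documented as this package's own convention.

AUC comparisons use the Hanley–McNeil closed form
(Q₁ = A/(2−A), Q₂ = 2A²/(1+A)) with a caller-supplied correlation term;
a helper estimates it as the average of the within-positive and
within-negative Pearson correlations of the paired scores. Mann–Whitney U
uses midrank ties, exact enumeration of all C(n₁+n₂, n₁) assignments for
n₁+n₂ ≤ 12, and a tie- and continuity-corrected normal approximation
otherwise.

## Synthetic cohort

`SyntheticCohortSpec` defaults encode the study conditions: 58 subjects,
6 events (exact, not binomial, so the 10.3% rate holds per cohort), 56
women, age ~ N(68.4, 11.8²) clipped to [30, 95] years, BMI ~ N(24.4, 4.3²)
clipped to [14, 45] kg/m² (clipping logged), 256×256 images at
0.390625 mm.

The LV is a slightly elliptical disc (myocardial ring around a blood
pool) on a dark background. Ring geometry varies only slightly between
subjects (radii ≈ 40.5/62.2 px, ellipticity 0.985–1.0, centre jitter
±3 px): geometry is nearly standardized so that between-subject feature
variance reflects tissue texture, not ring size — otherwise mask-area
driven statistics (run-length non-uniformity) would be reproducibly
different between subjects and pass reliability filtering on geometry
alone, which is not the phenomenon being modelled.

**T2w-like sequence.** In-disc intensities are a Gaussian random field
(white noise filtered with an isotropic Gaussian kernel, standardized)
with per-subject correlation length ℓᵢ ~ N(3.0, 0.5²) px and amplitude
σᵢ ~ N(80, 15²), plus white noise (SD 20). These per-subject parameters
are the reproducible between-subject signal that gives T2w features their
high ICC. The outcome effect is injected here only: event subjects get
ℓ += 2.5 px and σ += 50. Effect sizes are free parameters of the design —
there is no published quantitative texture difference between outcome
groups to calibrate to; the defaults are chosen as a decisively strong
effect, and
`SyntheticCohortSpec.null()` switches it off for null calibration.

**LGE-like sequence.** A high-frequency field (ℓ = 0.8 px, amplitude 80)
with no subject-level parameters, on a bright disc (500 vs background
100), with the field amplitude ramping toward the LV boundary
(weight 0.3 → 1.0 with a cubic radial profile). Re-segmentation therefore
swaps extreme-valued pixels in and out of the ROI and shifts the ±3σ
window, while between-subject variance is only shared-field sampling
noise — so LGE feature ICCs concentrate well below 0.6 and the selection
step discards the sequence, the qualitative headline the generator is
designed to make testable.

**Readers.** Each of the three readings is an independent radial
perturbation of the 24-vertex boundary trace, vertex displacement
N(0, 1.5² px), with simplicity enforced (10 retries, then the unperturbed
polygon with a warning). At the default jitter the mask Dice against the
unperturbed ROI concentrates around 0.985.

Rendering is lazy: subjects carry deterministic per-subject child seeds
and render images on first access, so demographics-only sweeps (e.g. the
grand-mean-age acceptance quantity over 200 cohorts) cost milliseconds
per cohort while identical (spec, seed) still yields a bit-identical
cohort.

What the generator does **not** emulate: cardiac anatomy and ballooning
morphology, MR physics and k-space artefacts, scanner/site heterogeneity,
informative clinical covariates (age/sex/BMI carry no outcome signal by
construction), and any calibrated quantitative texture difference between
outcome groups. Passing calibration therefore shows the pipeline
faithfully recovers structure the generator encodes — not that the
original clinical effect sizes are reproduced.

## Problem sizes and numerical choices

Calibration properties use 20 seeded cohorts per condition (strong/null
effect) with the NaiveBayes classifier, 10 fold-seed replicates per run;
the effect-monotonicity check adds 10 runs at half effect. The ICC
recovery study uses 500 replicates at n = 58 per true value. The
brute-force texture oracle runs on 21 integer images up to 8×8 at all
distances and directions. One full default run (simulate → extract →
select → evaluate) takes well under a minute on one CPU.

Degenerate-input rules are uniform across the package: zero-variance
windows, single-level matrices, constant designs and all-tied tests warn
and return documented values (0, level 1, or p = 1) instead of raising,
while genuinely unusable inputs (missing spacing, self-intersecting
polygons, sub-16-pixel ROIs, empty masks) raise. Seeds derive from a
single master seed via SHA-256 stage hashes (below 2³¹), so stages are
individually replayable from the run manifest.
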