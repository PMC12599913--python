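# Methods

This note documents the models, conventions and numerical choices
behind punctakit, and what the synthetic benchmarks do and do not show
about real imaging data.

## Input model

The unit of analysis is a *crop*: a straightened strip image of a nerve
cord, 1–2 aligned fluorescence channels of identical shape. The first
array axis is the crop height (short axis), the second runs along the
cord; edge margins and per-100 µm normalizations follow this
convention. Intensities are processed as floats with no rescaling at
load; normalization is an explicit detection step. Crops live on disk
as grayscale TIFFs (one file per crop, multi-page = channels, page 1 =
channel 1) in per-genotype directories, read in lexicographic order so
dataset ordering is stable across runs. Pixel size is a per-dataset
scalar; the shipped example value 0.21 µm/px corresponds to a 63×
confocal dataset (3 px ≈ 0.63 µm).

## Detection

**Local-means threshold.** Pixel *p* is foreground iff
`I(p) > mu_w(p) * 2(1-s)`. Design choices:

* *Sensitivity mapping.* The `2(1-s)` factor satisfies the required
  contracts — `s` spans [0, 1], permissiveness is monotone in `s` on
  non-negative images, and `s = 0.5` reduces to a plain
  compare-to-local-mean. Other GUI tools expose a similar dial without
  publishing the mapping, so per-pixel mask equality with any specific
  third-party binary is not claimed.
* *Window.* `mu_w` is an edge-replicated `w × w` window mean
  (`scipy.ndimage.uniform_filter`, mode `nearest`); replication keeps
  the mean unbiased at crop borders, which matters because crops are
  thin. The filter's running-sum arithmetic can drift an exactly-zero
  background to ~−1e−17, which would flip the strict comparison, so on
  non-negative images the mean is clamped at 0 (the true mean of a
  non-negative window is non-negative).
* *Strict inequality*, so constant or zero regions yield no ROIs.
* Defaults: `s = 0.2`, `w = 15` — tuned once for the bright synthetic
  reporter (below) and matching the bright-reporter optimum of the
  robustness study; dim reporters want `s ≈ 0.35`.

**Otsu baseline.** A single global threshold maximizing between-class
variance on a 256-bin histogram of the min-max-normalized image,
foreground strictly above. A constant image has no separating
threshold and returns an empty mask.

**Watershed.** Elevation `E = -(D ⊙ normImg)` with `D` the Euclidean
distance to the nearest background pixel and `normImg` the per-crop
min-max normalization (per-dataset normalization was rejected: crops
differ in exposure context; a constant channel normalizes to zeros).
Conventions, none of which are forced by the formula itself:

* 8-connectivity for foreground components, regional minima and
  flooding;
* each connected regional-minimum *plateau* is one seed, preventing
  over-segmentation of flat-topped puncta;
* watershed ridge pixels are background in the output (so touching
  ROIs stay disjoint);
* output labels are relabeled to a contiguous 1..K in seed order,
  making label maps bit-reproducible;
* the watershed runs on every foreground component, not only large
  ones.

A 15 px window rejects the valley between two puncta 8 px apart
(both blobs inflate the local mean there); a window spanning the pair
(~25 px) merges them into one component, which the watershed then
splits — the regime the splitting benchmark exercises.

## ROI measurement and restriction

One record per label: area (px² and µm², µm² = px²·pixel_size²),
sum/mean/max intensity, centroid, bounding box, circularity,
length-to-width ratio, within-ROI intensity variance (population
variance), and edge-contact flags. Conventions:

* *Circularity* = 4πA/P² with the boundary-weighted perimeter from
  `skimage.measure.regionprops`, clamped to 1.0 because tiny digital
  regions nominally exceed it (a 2×2 square gives π); a single-pixel
  ROI is defined as circularity 1.
* *Length-to-width ratio* = major/minor axis of the
  second-central-moment ellipse; a zero minor axis (perfectly straight
  ROI) gets the documented sentinel ratio = area; single pixel → 1.
* *Variance filter* is double-bounded and disabled by default — the
  useful direction is dataset-dependent.

Restriction removes an ROI iff any of its pixels falls within
`x_edge_px` of the left/right or `y_edge_px` of the top/bottom border
(any-pixel rule, not centroid: edge artifacts such as gut granules
merely impinge on the crop), or any enabled feature bound is violated.
Decisions are evaluated independently per ROI, so filtering is
order-free and idempotent; survivors keep their pixel sets and are
relabeled contiguously in original order. Default restriction:
`y_edge_px = 3`, `min_area_px2 = 5` (0.22 µm² at 0.21 µm/px).

Crop summaries: ROI count, count per 100 µm
(`n / (length_px · pixel_size_um) · 100`), and SNR defined as the summed
intensity inside ROIs over the summed intensity outside (an empty mask
gives 0; an all-zero background leaves the ratio undefined and raises).

## Colocalization

* **PCC** is computed over *all* crop pixels, unmasked — the crop
  itself is the background-minimizing step. `pcc_normalized = (PCC+1)/2`
  is used only where PCC must share a [0, 1] axis with M1/R1 (the noise
  study).
* **Manders** is implemented on binary indicators (pixel counts of
  thresholded signal), deliberately *not* the classic
  intensity-weighted 1993 form. Empty masks leave the coefficient
  undefined and raise.
* **R1/R2**: ROI *a* of channel 1 is colocalized iff
  `overlap(a)/area(a) ≥ θ` *and* `overlap(a) > 0` — the extra clause
  means a zero-overlap ROI never counts, even at θ = 0. The overlap is
  taken against the other channel's post-restriction label support
  (both channels have passed identical pipelines); `roi_overlap_ratio`
  accepts any signal mask, so thresholded-only masks can be passed
  instead. R1(θ) is non-increasing, with R1(0) = "any overlap" and
  R1(1) = "fully covered".

## Validation

TPR = true ROI px / truth ROI px, TNR = true non-ROI px / truth non-ROI
px, BA = (TPR+TNR)/2, exact rational fractions. `column1d` mode first
collapses both masks column-wise (a column is positive if it holds at
least one ROI pixel), the only fair comparison for 1D baselines.
Ground truth with no positives (or no negatives) raises rather than
returning a silent 0/0.

The 1D peakfinder sums rows into a profile and keeps strict local
maxima by prominence, width at half prominence (≤ `max_width_cols`) and
a height floor of `noise_to_signal_ratio × median(profile)` — the
noise floor is a relative convention of this implementation, exposed as
a parameter. Each peak claims its half-prominence column interval;
how 1D peaks should be widened for pixel scoring has no canonical
answer, and this choice is the simplest one consistent with the width
filter.

The sensitivity sweep re-runs threshold → watershed → restrict → count
per grid point (optimum ± 0.15, step 0.01, clipped to [0, 1]) and
tests genotype separation with a Welch one-way ANOVA
(`pingouin.welch_anova`); unequal-variance pairwise comparisons are
available via Games–Howell. Degenerate inputs: groups recovered with
zero count variance make Welch's statistic undefined, so all-constant
groups short-circuit (p = 1 if all means equal, p → 0 otherwise) and
mixed constant/varying groups fall back to the classic one-way ANOVA.
Genotypes with fewer than two crops are excluded from the test with a
warning.

## Synthetic scenes and noise models

`generate_scene` emulates a straightened crop: flat background offset
(default 10), `n_puncta` isotropic Gaussian puncta with amplitude
~U(80, 120) and σ ~U(1.5, 2.5) px, centers rejection-sampled with a
12 px minimum separation and a margin keeping footprints clear of the
borders, optional bright blobs centered within 3 px of a y-edge (gut
granule mimics, present in the image but never in the truth), and
additive Gaussian read noise (SD 2), clipped at zero. Ground truth for
punctum *k* is its half-maximum contour in the noiseless image, ties to
the strongest contributor — real annotation has no such convention;
half-maximum is the standard spot-extent definition. Everything is
driven by one integer seed and is bit-reproducible.

Two named conditions: `overexpressed_like` (the defaults; peak ≈ 50×
read noise) and `endogenous_like` (amplitude 15–25, read noise 3;
peak ≈ 5–8× read noise), standing in for bright transgene arrays and
dim endogenous tags respectively. The robustness benchmark uses the
bright condition for control (12 puncta) vs severe (3 puncta) genotypes
and the dim condition for the mild phenotype (9 puncta at 0.7×
amplitude), because threshold-setting fragility is a low-SNR
phenomenon: at the permissive end of the sensitivity grid, noise blobs
pass the filters in dim crops, inflating counts with enough variance to
blur a 3-count genotype gap.

Noise is applied on a min-max [0, 1] rescaled copy, clipped back to
[0, 1] and mapped to the original range (the common imaging-toolbox
convention): Gaussian additive N(mean, var); speckle multiplicative
`x(1+U)` with zero-mean uniform U of the given variance; salt & pepper
replaces a `density` fraction with the extremes (half 0, half 1),
touching only the hit pixels; Poisson draws with mean `x·c` on a counts
scale `c` (default 1000 — Poisson on [0, 1] intensities is ill-posed,
and the counts scale sets the effective shot-noise strength, so it is a
documented parameter, not physics). Parameter grids are validated
against the study ranges (gaussian mean/variance ≤ 0.2, speckle
variance ≤ 0.2, density ≤ 0.05). Zero-parameter Gaussian/speckle/
salt-and-pepper are exact identities.

The noise study pairs each scene with its noisy copy as channel 2, runs
both through fixed detection/restriction, and reports mean ± SD of
normalized PCC, M1 and R1 across scenes; per-image metric failures
(e.g. an empty mask at extreme noise) become missing values with a
warning.

## Problem sizes and determinism

The shipped benchmarks use 20×500 px scenes; oracle checks use 200
random 20×60 strips; watershed splitting 50 seeded two-punctum scenes;
recovery 100 crops; the noise study 50 scenes per condition; the
robustness sweep 15 crops per genotype, evaluated at the grid's
endpoints and optimum (0.05/0.20/0.35), with 20 replicate datasets for
the mild-phenotype question. These sizes give stable statistics at
desk scale. Every stage is deterministic given the configuration and
seeds; replaying a saved session yields bit-identical CSVs and label
maps.

## What passing synthetic benchmarks does not show

The generator omits optical blur (no PSF model — puncta are drawn as
Gaussians, which flatters the half-maximum truth convention),
structured background (real crops have sloping, textured backgrounds
from out-of-focus tissue), anisotropic or overlapping puncta, and
camera gain/offset beyond the four noise models. Perfect recovery on
bright scenes therefore bounds optimistic performance; the dim
condition and the noise study probe robustness but cannot substitute
for validation against hand-annotated real data. Reported accuracy
bars from real worm datasets are not reproducible here because those
images are not shipped.
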