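# punctakit

Detection, restriction and colocalization analysis of discrete
fluorescent puncta in straightened nerve-cord *crops* — the thin strip
images (typically 20 px tall, a few hundred px long) that *C. elegans*
synapse imaging pipelines extract around an axon or nerve cord.
Synaptic reporters in these crops form a beads-on-a-string pattern of
spots; punctakit turns each crop into labeled regions of interest
(ROIs), per-ROI feature tables, crop-level summaries and, for
two-channel crops, three families of colocalization metrics, with a
validation framework and a synthetic scene generator so the whole stack
is testable without any imaging data.

## Method

**Thresholding.** The primary detector is an adaptive local-means
(Bradley) threshold: pixel *p* is signal iff

    I(p) > mu_w(p) * 2 * (1 - s)

where `mu_w(p)` is the mean over an odd `w x w` neighborhood centered
at *p* (edge-replicated at crop borders) and `s` in [0, 1] is the
sensitivity — higher values are more permissive, and masks are nested
in `s`. Adaptive thresholds tolerate the sloping backgrounds, edge
artifacts and low signal-to-noise typical of endogenously tagged
reporters. A global Otsu threshold and a 1D sum-projection peakfinder
are included as comparison baselines.

**Segmentation.** Touching puncta that threshold into one connected
component are split by a marker-free watershed on the elevation

    E = -(bwdist(~mask) . normImg)

the negative pixelwise product of the Euclidean distance to background
and the min-max-normalized intensity, flooded from the regional minima
of E inside the mask; watershed ridges stay background.

**Restriction.** ROIs are dropped if any pixel lies within a
configurable x/y edge band (guarding against autofluorescent gut
granules that impinge on crop borders) or if area, circularity
(4&pi;A/P&sup2;), length-to-width ratio, or within-ROI intensity
variance leave their bounds — removing the few-bright-pixel specks that
noise pushes over an adaptive threshold.

**Colocalization.** For two-channel crops: Pearson correlation (PCC)
over all pixel intensities; binary Manders coefficients
M1 = |S1 &cap; S2| / |S1| (and symmetrically M2) on the thresholded
signal masks; and ROI Overlap Ratios R1/R2 — the fraction of a
channel's ROIs whose pixel overlap with the other channel's signal
reaches an Overlap Threshold &theta;, a per-punctum binary measure that
ignores incidental boundary overlap.

**Validation.** Predicted masks are scored against ground-truth masks
by TPR (sensitivity), TNR (specificity) and Balanced Accuracy
(TPR + TNR)/2, pixelwise or collapsed column-wise for 1D baselines. A
robustness sweep re-runs the pipeline over a sensitivity grid
(optimum &plusmn; 0.15 in 0.01 steps by default) and reports a Welch
one-way ANOVA p-value per grid point, asking whether genotype
separation depends on the exact setting. A noise study measures how
normalized PCC, M1 and R1 degrade under Poisson, Gaussian, speckle and
salt-and-pepper noise.

## Worked example

```python
import punctakit as pk

# a synthetic straightened crop: 12 bright puncta on a noisy background
crop, truth = pk.generate_scene(pk.SceneSpec(n_puncta=12, seed=1))

det = pk.DetectionParams(sensitivity=0.2, neighborhood_size=15)
restr = pk.RestrictionParams(y_edge_px=3, min_area_px2=5.0)
result = pk.analyze_channel(crop.channels[0], det, restr, pixel_size_um=0.21)

print(f"detected ROIs: {len(result.table)} (seeded puncta: {truth.max()})")
print(f"count per 100 um: {pk.count_per_100um(len(result.table), crop.length_px, 0.21):.2f}")
rates = pk.confusion_rates(result.labels > 0, truth > 0)
print(f"TPR={rates.tpr:.3f}  TNR={rates.tnr:.3f}  BA={rates.balanced_accuracy:.3f}")
```

prints

```
detected ROIs: 12 (seeded puncta: 12)
count per 100 um: 11.43
TPR=1.000  TNR=0.977  BA=0.989
```

All 12 seeded puncta come back as exactly one ROI each; every
ground-truth signal pixel is recovered (TPR 1.0) and the detected
footprints extend only slightly past the half-maximum truth contours
(TNR 0.977). The normalized count says the 500 px crop (105 µm at
0.21 µm/px) carries ~11.4 puncta per 100 µm.

The same stages are scriptable from the shell:

```sh
punctakit simulate --out data --n-crops 10 --seed 1
punctakit run --in data/crops --out results
punctakit validate --pred results_mask.tif --truth truth_mask.tif
punctakit sweep --config config.json --in data/crops --out sweep.csv
punctakit noise-study --out noise
```

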