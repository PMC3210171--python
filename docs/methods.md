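# Methods notes

## The enumeration model

A patient sample is a stack of four-channel tiles recorded from an
EpCAM-enrichment cartridge. The method treats enumeration as four
deterministic stages — imaging-area detection, histogram-threshold
segmentation, four-feature measurement, threshold-box classification — so
that a fixed classifier always produces the same count for the same images
(the variability of the count is exactly zero, unlike human review).

**Imaging area.** The cartridge edge appears in the FITC (debris/control)
channel as a band of depressed intensity along tile edges. For each tile and
each edge, the 1-D mean-intensity profile is walked inward while it stays
below `(1 - contrast)` times the tile-interior median (`contrast` = 0.25 by
default); the walked band is excluded. This profile search was chosen over
2-D contour fitting because the border is axis-aligned in cartridge
coordinates; a tile with no sufficient transition (including an all-zero
FITC channel) keeps its full area and a warning is logged rather than
raising, since an absent border must not abort a sample.

**Segmentation.** One histogram per sample, pooled over all tiles, one bin
per integer intensity level. The triangle (Zack) threshold takes the bin at
maximal perpendicular distance from the chord joining the histogram peak to
the last nonzero bin on the long-tail side; ties break toward the lowest
intensity so that more candidates survive to classification, which filters
later anyway. Per-tile thresholding is available as a switch
(`segment_objects` accepts any threshold) but pooling is the default: CTC
are rare, so many tiles contain no object and a per-tile histogram can
degenerate to pure background. Components use 8-connectivity, the standard
for fluorescence blobs. No minimum-size filter is applied at this stage;
size selection belongs to the classifier.

**Features.** `ck_std` is the population (divide-by-N) standard deviation
of CK-PE over the object mask — fixed to the population convention for
reproducibility. DAPI and CD45 peaks are maxima over the object mask dilated
by 2 px (configurable; 0 gives the strict-mask reading): nuclei and CD45
staining can extend past the cytokeratin boundary. Sizes derive from the
pixel area 0.448 µm²/px, back-computed from the printed size-bound pair
(500 px = 224 µm²), the only geometric anchor available; the equivalent
circle diameter is `2·sqrt(area/π)`.

**Classification.** Printed `>`/`<` bounds are strict, the size range is
inclusive, so ties at a bound resolve deterministically. The micro-particle
(TMP) definition reads "CK standard value" as the same `ck_std` feature (no
second CK statistic exists) and implements "< 4 µm in diameter" as the
equivalent-circle diameter; DAPI positivity is not imposed on TMPs. Note the
optimal box and the TMP box are disjoint by construction: 75 px is already
33.6 µm², i.e. a diameter above 4 µm.

## Survival statistics

Groups are compared by a Cox proportional-hazards model with a single
binary covariate (high vs low count), Efron correction for tied event times
(Breslow available via `ties="breslow"`), Wald 95% CI from the observed
information. The public `cox_hr` route goes through lifelines; a compact
in-module Newton solver for the single-binary-covariate case (Efron and
Breslow variants) backs the grid search, where thousands of fits are needed
— a test pins the two routes to each other at 1e-6. All events in one group
make the partial likelihood monotone; this is returned as a flagged
non-convergence, never as a silent estimate. HR is reported as
(count ≥ cutoff) vs (count < cutoff), matching the convention that the
high-count group has shorter survival. Median OS is undefined (NaN,
"not reached") when the Kaplan–Meier curve never reaches 0.5.

During training, patients are dichotomized at the cohort **median** count —
it balances group sizes, minimizes HR error, and makes HRs comparable
across candidate classifiers; fixed cut-offs 1–10 are used for reporting
(`cutoff_table`, with degenerate dichotomies flagged, not dropped). The
clinical cut-off conversion `derive_cutoff` evaluates the automated-vs-
manual regression line at the routine manual cut-off of 5 and rounds to the
nearest positive integer; with slope 1.33 both the with-intercept (−3.03)
and slope-only readings land at 4 after rounding against reference 5 and
6.65→7 respectively — the with-intercept form is the default because the
fitted line, not the slope alone, is the calibration between the two
counting scales.

## The training objective

The published desiderata — high baseline and follow-up HR, follow-up HR
above baseline HR, low absolute and relative control counts — name no
formula, so the search implements them as hard feasibility constraints plus
a weighted score:

- feasible iff `hr_followup > hr_baseline · (1 + margin)` (margin 0 by
  default), total control count ≤ `max_control_total` (default 1, mirroring
  a background of one object across an entire healthy-control set), and
  mean control count / mean baseline patient count ≤ `max_control_relative`
  (default 0.02);
- among feasible candidates, maximize `w_b·hr_baseline + w_f·hr_followup`
  (defaults 1, 1); ties break toward the stricter classifier (smaller
  accepted feature volume over the observed feature ranges), then earlier
  grid order.

The search is exhaustive over the grid product. Grids default to 8–12
values per bound spanning the observed feature range when built by hand;
the tests use 4-point grids around the planted bounds. Bootstrap
aggregation resamples **patients** (not objects), because the objective is
patient-level survival; replicates with zero events or no feasible
candidate are skipped and counted. Feature screening (`rank_features`)
scores each feature by the HR of median-split object counts and greedily
drops features correlated above 0.8 (object-level Pearson) with an
already-selected one.

## What the simulator emulates — and what it does not

`synthetic.simulate_cartridge` renders disks with a Gaussian radial profile
`I(d) = peak·exp(−d²/2σ²)` truncated at the disk radius, on a truncated-
Gaussian background (clipped at ±3.5 sd, so background has bounded support
and cannot leak above a threshold at its ceiling), with Poisson photon
noise on object signal and a half-intensity FITC border band (20 px
default). Four regimes straddle the classifier bounds: CTC-like objects
(radius 6–8.5 px, CK peak 225–255 with steep falloff σ = 0.4r — the steep
profile is what gives them `ck_std` ≈ 58–65, emulating textured cytokeratin),
leukocytes (flat CK 70–110, CD45 140–220), micro particles (radius
1.6–2.4 px, hence < 4 µm), and FITC-bright debris (flat CK, dim DAPI).
Intensity distributions for real objects are not published; these regimes
are chosen to straddle the printed thresholds, not to match any archive.
Bit depth defaults to 8 — the printed threshold constants (50, 60, 170
counts) are consistent with 8-bit imagery.

The exact-count closure that the tests assert (planted = segmented =
classified) holds under the simulator's stated conditions — ≥5:1
peak-to-background contrast, ≥2 px spacing, bounded background — and says
nothing about overlapping cells, saturated high-density samples (the known
failure mode of the real algorithm), illumination gradients, focus drift or
optical PSF effects, none of which are modelled. Tile counts default to 144
(a full cartridge scan is 144–180 tiles); tests and examples use 4–10 tiles
of 128×128 px to keep runtimes in seconds, which leaves the per-tile logic
identical and only shrinks the sampled area.

Survival cohorts (`simulate_cohort`) draw counts from a negative binomial
(mean 8, dispersion 0.6 — heavy-tailed like CTC counts), exponential
event times with hazard multiplied by `true_hr` when count ≥ `cutoff_link`,
and independent exponential censoring. `simulate_feature_cohort` generates
the training study: only objects inside a planted feature box
(`ck_std` ∈ (50, 85), `cd45_peak` ∈ (0, 60)) carry prognostic signal; two
risk-independent nuisance populations (sub-box CK "debris", above-box CD45
"leukocytes") punish loosening either bound, and the narrow signal band
makes over-tightening costly too, so the planted box is the population
optimum of the objective. Follow-up samples separate risk groups more
sharply than baseline (Poisson means 0.5/7 vs 1.5/9), reflecting that
post-treatment counts discriminate outcome better.

## Numerical choices and degenerate inputs

- Triangle threshold: peak and distance ties both resolve to the lowest
  intensity; a single nonzero bin returns itself; an empty histogram raises.
- Newton solvers clip steps to |Δβ| ≤ 2 and stop at |Δβ| < 1e-12; lifelines
  fits use `precision=1e-11` so both routes agree with a brute-force grid
  maximization of the written-out partial likelihood to 1e-6 on the HR.
- Degenerate dichotomies and monotone likelihoods are flagged
  (`degenerate`/`converged=False`), never dropped or silently reported; CI
  bounds may be infinite on tiny cohorts.
- `derive_cutoff` results below 1 clamp to 1 with a warning.
- Manifest validation rejects overlapping disks (rim separation below
  `min_separation_px`), out-of-range intensities (naming the object) and
  objects that do not fit their tile.

## Known limitations

- Objects spanning tile boundaries are treated as distinct per tile; no
  stitching, matching the per-tile archive format.
- No illumination flat-fielding or thumbnail-gallery rendering.
- The grid search cost is the grid product times two Cox fits; it is meant
  for the handful of features the screening step retains, not for
  high-dimensional spaces.
- The published classifier constants (50 / 75–500 / 170 / 60) derive from a
  specific instrument, objective and stain set; the search machinery, not
  those constants, is what transfers to other imaging conditions.
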