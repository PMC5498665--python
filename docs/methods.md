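# Methods

`neuroquant` quantifies neuronal differentiation readouts of cultured cells
(the SH-SY5Y neuroblastoma model and similar systems) from three kinds of
raster data — phase-contrast micrographs, digitized Western-blot films, and
two-channel immunofluorescence pairs — and pools the measurements through
the nested experimental design in which such data are collected. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

## Neurite enhancement

Phase-contrast images are enhanced by a fixed chain: Gaussian smoothing
(`gaussian_sigma_px`, default 1.0) to suppress sensor noise, a Laplacian
high-pass (4-connected by default; 8-connected optional) to respond to thin
processes, a median filter (3×3 default, odd sizes only) to despeckle, and
binarization of the absolute response. The default cut is Otsu's
between-class-variance criterion on the absolute response; a fixed value
may be supplied instead. A constant image yields an all-false map by
definition (no gradients). The kernel sizes are the smallest standard
choices that perform both the "remove noise" and "detect and enhance"
roles; enhanced maps are rendered as blue overlays on the grayscale
original for visual review.

## Neurite length

A neurite's length is the chained Euclidean distance along its trace from
the cell body to the tip, in pixels, converted to micrometres by the
scale-bar calibration (`um_per_px`). For branched neurites the reported
length is always the **longest root-to-tip path**; when two paths tie,
either may be taken (only the length is an output). Two measurement modes:

* **Annotation mode** (reference): operator-supplied polylines are measured
  exactly — vertex-wise segment sums, no raster involvement. Measuring the
  synthetic generator's own truth polylines reproduces the stored truth to
  machine precision; this is the mode equivalent to operator-guided
  measurement on enhanced images.
* **Automated mode** (convenience): the edge map is closed with a 2-px disk
  (the |Laplacian| of a ridge marks its centre and both flanks; closing
  makes the band solid so its skeleton is the centreline), somata are
  masked out with a 5-px guard ring (their own edge response would fuse
  distinct neurites), the remainder is skeletonized, and each skeleton
  component whose enclosing band touches a soma becomes a tree rooted at
  the nearest soma pixel. Within a component, a shortest-path tree is grown
  from the attachment pixel over the 8-connected pixel graph (step weights
  1/√2); unary pixel runs are Douglas-Peucker-simplified (tolerance 2 px)
  back to polylines so lengths are chained Euclidean distances rather than
  chain-code step counts. Three corrections address systematic thinning
  artefacts: leaf runs are walked back while they overhang the image's
  foreground (Otsu cut on the intensity raster), tips are then pushed out
  along their final heading while the image stays foreground and retracted
  by the stroke's local half-width (thinning retracts from blunt band
  ends), and skeleton pixels hugging the soma cut are dropped in favour of
  a straight bridge from the soma boundary. Trees shorter than
  `min_length_px` (default 10 px, excluding skeleton stubs) are discarded
  with a log line. On synthetic scenes these corrections bring per-neurite
  errors to ≈1% on average; occasional neurites can still err by ~5%,
  dominated by junction displacement on branched trees.

Coordinates are (row, col), 0-based, pixel centres at integer coordinates,
stated once here and used everywhere.

## Blot densitometry

The integrated density value of a band is

    IDV = Σ(pixels in band ROI) − mean(pixels in background ROI) × area(band ROI)

with the background taken from a caller-placed, same-size, disjoint region
near the band (the default helper puts it one ROI-height above the band).
Interpreting "average background subtracted" as per-pixel mean × area keeps
the expression dimensionally consistent; it also makes the IDV exactly
invariant to adding a constant to every pixel. All band ROIs in an analysis
must share identical dimensions (`enforce_uniform_roi`), which is what
makes IDVs comparable across bands and experiments. Films carry dark
signal on light background, so pixels are inverted (bit-depth maximum
minus value) before summation by default; the flag exists for
signal-positive images. Negative IDVs (noise below background) are
reported as-is; normalization requires a positive loading-control IDV and
propagates a negative target as a negative ratio with a warning.
Normalization is two-stage: each target band by its lane's loading control
(e.g. β-actin), then every lane ratio by a reference condition so the
reference reads exactly 1.

When quantifying Gaussian-like bands with a tight ROI (±2.5σ), the partial
coverage factor is identical for target and loading bands of equal width
and cancels exactly in the ratio, while the smaller box keeps the ROI's
noise contribution low — the reason the synthetic benchmark recovers
planted fold changes within 2% at band noise of 2% of amplitude.

## Relative fluorescence intensity

The RFI of a marker in a picture is the cumulative sum of the values of
all pixels **strictly above** a pre-determined threshold (literal reading:
the raw values of qualifying pixels are summed, not their excess over the
threshold). The marker sum is divided by the nucleus-channel sum computed
the same way, normalizing for cell abundance. Thresholds default to fixed
per-channel values supplied in configuration; Otsu is the fallback when no
value is given. Comparability across conditions presumes identical
exposure, gain and illumination per channel — the tool can only record and
warn about this assumption, not verify it. A nucleus channel with zero
suprathreshold signal has no normalizer and is excluded (with a logged
reason) rather than silently skipped.

## Hierarchical aggregation

Measurements arrive as experiment → replicate → picture → values. The
pooled estimate composes, in fixed order:

1. per-picture sample mean and unbiased variance;
2. within a replicate, picture means pooled **weighted by measurement
   count**: mean Σnᵢmᵢ/Σnᵢ, carrying upward the frequency-weighted sample
   variance of the member means, Σnᵢ(mᵢ−m̄)²/(Σnᵢ−1);
3. within an experiment, replicate summaries pooled **by inverse
   variance**: wᵢ ∝ 1/vᵢ, variance of the mean 1/Σ(1/vᵢ);
4. across experiments, the same inverse-variance pool.

Inverse-variance weighting minimizes pooled variance for independent
unbiased inputs. Degenerate members (variance 0 from a single picture or
identical values) take the smallest positive member variance; if no member
has positive variance the level falls back to count weighting. The final
standard error reported is sqrt(variance_of_mean) of the last pool,
labelled as such.

**Known limitation.** The weights at the experiment level derive from
within-experiment (replicate) spread, which cannot estimate the
between-experiment variance component; when that component dominates, the
reported SEM understates true sampling error and the grand-mean recovery
z-score can exceed 3 on individual simulations even though the estimator
itself is unbiased. A random-effects adjustment would fix this but is a
different estimator from the one this package implements.

## Group statistics

One-way ANOVA uses the classical between/within decomposition with the
upper F tail at the 95% confidence level (α = 0.05 throughout,
configurable). The post-hoc test is Tukey's: q = |mᵢ−mⱼ| /
sqrt(MSW/2·(1/nᵢ+1/nⱼ)) — the Tukey–Kramer form, exact for the balanced
duplicate design and conservative otherwise — against the studentized-range
critical value at (k, df_within). The family is controlled per response
variable; no cross-variable correction is applied. Agreement between
paired assays (e.g. indirect cell counts vs a metabolic assay) is the
determination coefficient R² = 1 − SS_res/SS_tot of the least-squares line,
undefined for constant inputs. Assay readings are normalized to protein
content and then to their condition's control.

## Synthetic data

Each generator is a pure function of (spec, seed) — one seeded PCG64
instance per call, no global state, default seed 0 — and stores ground
truth computed on the noise-free scene:

* **Neuron scenes**: bright soma disks plus anti-aliased polyline neurites
  (width 3 px default) on a dark background; truth is the vertex geometry,
  not the raster. Cells are placed with disjoint territories (soma +
  maximal reach), so neurites of different cells never touch; same-cell
  neurites occupy distinct angular sectors. A branch replaces the distal
  part with two arms; truth records all root-to-tip paths and the longest
  length. Per-picture neurite lengths are uniform over the spec range (the
  source protocol does not state a distribution). Unplaceable geometry
  fails with the spec field to shrink. Defaults (1024², 5 cells, 2
  neurites of 60–110 px at 0.5 µm/px, noise SD 300 on a 2000/40000
  background) emulate a 20× field with high-contrast enhanced processes.
* **Blot films**: per lane a target and a loading band, isotropic Gaussian
  bumps of amplitude A and width σ subtracted from a light background with
  a linear row ramp; truth is each bump's discrete sum over the raster and
  the per-lane target/loading ratio. Bands may not overlap (pitch > 4σ)
  nor exceed the background level (clipping would corrupt the truth).
* **Fluorescence pairs**: nucleus disks plus slightly larger marker disks
  over the positive fraction of objects; truth is each noise-free
  channel's suprathreshold sum at the spec threshold and their ratio.
* **Hierarchies**: values = grand mean + experiment offset + picture
  offset + within-picture noise, all normal; replicates share their
  experiment's offset (repeated handling of one preparation). Defaults
  mirror the design of the neurite-length protocol: 3 experiments in
  duplicate, 5 pictures per replicate, 15–30 measurements per picture.
* **Assay tables**: raw = base × fold × protein × (1 + cv·z) with protein
  content varying 5% around its mean, so protein-then-control
  normalization recovers the planted folds exactly at cv = 0.

Noise is additive Gaussian clipped to the 16-bit range. The generators do
not simulate optics (PSF), uneven illumination, film saturation, cell
texture, touching cells, or neurite crossings; passing the recovery
benchmarks therefore demonstrates correctness of the measurement chain on
clean, well-separated geometry, not robustness to the pathologies of real
micrographs — on real data the annotation mode with operator judgement
remains the reference path.

## Problem sizes in the benchmarks

The acceptance computations use 12 annotation scenes (512²), 20 traced
scenes (1024², ten neurites each), one 6-lane blot, one 384² fluorescence
pair, 1000 null ANOVA replicates, and one 200-experiment hierarchy — sizes
at which every recovery quantity is stable yet the whole script completes
in well under a minute.
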