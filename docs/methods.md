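# Methods

## The detection model

`pidspot` counts sub-resolution fluorescent nanoparticles ("phosphor-
integrated dots", PIDs) in single-channel 12-bit micrographs. The method
rests on two physical facts: a PID spot is far brighter than tissue
autofluorescence, and it is spatially much sharper — autofluorescence is a
low-spatial-frequency field, while a ~150 nm particle imaged at 0.16 µm
pixels is an approximately PSF-shaped impulse. The pipeline therefore:

1. **High-pass filters** the image as `I − G_σ * I` (subtraction of a
   Gaussian blur, default σ = 2 px ≈ the spot radius at 40× / 0.16 µm
   pixels). Negative values are clamped to 0 before any thresholding so
   that the fixed ADU thresholds below keep their meaning on the 12-bit
   scale. The filter family is a package choice; any filter that removes
   the smooth background while passing PSF-scale structure would serve.
2. **Scans for strict 3×3 extrema.** A pixel is a local maximum iff
   strictly greater than all 8 neighbours (minimum: strictly smaller).
   Strictness means plateaus and gradual gradients yield no extrema, and no
   two maxima can be 8-adjacent. Border pixels are never extrema.
3. **Applies the noise tolerance.** Each maximum is paired with the nearest
   minimum within `min_search_radius` (default 10 px; ties broken by lower
   value, then smaller y, then smaller x, for determinism). The maximum is
   accepted iff `v_max − v_min ≥ noise_tolerance` (default 32 ADU). The
   boundary is inclusive: the published rule states that differences *less
   than* 32 are rejected, so exactly 32 passes. A maximum with no minimum
   within the radius is compared against an implicit background of 0 ADU —
   in a clamped high-pass image, a minimum-free neighbourhood means the
   surroundings sit on the zero floor, so the maximum's own height is its
   prominence.
4. **Binarizes at 16 ADU (inclusive ≥)** and labels connected components
   (default 8-connectivity; compact blobs should not split across diagonal
   necks). A component containing ≥ 1 accepted maximum becomes one spot; a
   component with several maxima is still *one* spot (the standard curve
   converts bright/large regions into multi-particle counts, so splitting
   is unnecessary). Components without an accepted maximum are discarded;
   accepted maxima outside every component are dropped. Regions touching
   the border are kept by default (`drop_border_regions` to change).

Each spot reports an intensity-weighted centroid, pixel area, **integrated
signal** (sum of clamped high-pass ADU over the region — the default
quantity fed to the standard curve, since step 4 exists precisely to define
the integration area) and the **peak value**, retained so that peak-based
calibration (`signal_kind="peak"`) remains available.

Key parameters (ADU = analog-to-digital unit on the 0–4095 scale):

| parameter | default | meaning |
|---|---|---|
| `noise_tolerance` | 32 ADU | minimum maximum-to-minimum prominence |
| `binarize_threshold` | 16 ADU | spot-area threshold on the high-pass image |
| `highpass_sigma` | 2.0 px | blur subtracted by the high-pass filter |
| `min_search_radius` | 10 px | nearest-minimum search cap |
| `connectivity` | 8 | component connectivity for spot areas |

## Calibration and quantification

The standard curve `count = slope·signal + intercept` is fitted by ordinary
least squares (optionally through the origin); the quality metric is the
Pearson correlation of the raw pairs. A line is the minimal model consistent
with fluorescence intensity being proportional to the number of emitters in
a spot. Per-spot counts are kept continuous — reported quantities are means
(per 0.01 mm² field, or per cell), where fractional values such as 0.09
particles per cell are meaningful; rounding is deferred to reporting. A
fitted slope ≤ 0 triggers a warning and the curve refuses to convert.

Particle density is reported per 0.01 mm² (the 100 µm × 100 µm field).
Per-cell values use the 100 µm² square-cell convention (100 cells per
field) unless explicit cell ROIs or a cell count are supplied; automatic
cell segmentation is out of scope, so ROIs are caller-provided and
overlapping ROIs are rejected as ambiguous. Spots outside all ROIs are
reported separately, never silently dropped.

Group comparison: a two-sided F-test of the sample-variance ratio (larger
variance in the numerator, one-tailed probability doubled — the common
convention; sidedness is otherwise unspecified in the source procedure)
gates at p ≥ 0.05 between Student's pooled t-test and Welch's t-test with
Satterthwaite degrees of freedom, both two-sided. The statistics are
computed from first principles against the F and t distributions;
`scipy.stats.ttest_ind` is used only as an independent oracle in the tests.

## The synthetic scene generator

`pidspot.synthetic` emulates what the detector must cope with in tissue:

* **Autofluorescence** — a Gaussian random field (white noise blurred at
  correlation length 25 px, amplitude 80 ADU about a 400 ADU mean). It is
  low-frequency by construction, mirroring why a high-pass filter works on
  real tissue.
* **Spots** — `n_spots` (default 40 per 400×300 field) centers placed with
  ≥ 6 px separation; each spot holds 1–12 particles (uniform by default,
  matching the calibration-table convention). A particle adds a Gaussian
  kernel of sd 1.3 px (the PSF at 40×/0.95 NA and 0.16 µm pixels),
  jittered within a 2 px box — a ~150 nm particle is sub-resolution, so a
  k-particle spot is pointlike but ~k× brighter. Per-particle amplitude is
  lognormal (mean 250 ADU, log-sd 0.2).
* **Camera** — Poisson shot noise applied at the photoelectron level with
  `photons_per_adu = 50`, plus Gaussian read noise (sd 8 ADU), rounding,
  and clipping to [0, 4095].

The shot-noise conversion deserves a note. A fixed 32 ADU prominence
threshold is only a meaningful noise test in a photon-rich regime: at
50 photoelectrons/ADU the shot-noise contribution at the default
background is √(400/50) ≈ 2.8 ADU, subordinate to the 8 ADU read noise,
making the tolerance a ~3.5–4 σ test. Applying Poisson statistics directly
on the ADU scale would instead imply 20 ADU of shot noise at a 400 ADU
background — a regime in which *any* fixed 32 ADU threshold admits
thousands of false maxima per field and the method as published could not
function. The default camera model is therefore the one the published
parameters presuppose.

What the generator does **not** model: vectorial/defocused PSFs, spectral
bleed-through, hematoxylin counterstain, spatially varying illumination,
spot clustering along membranes, and fixed-pattern camera noise. Passing
tests on synthetic fields demonstrate algorithmic correctness and
noise-regime behaviour, not performance on any particular real tissue
preparation.

## Evaluation conventions

Detections are matched to ground truth greedily in increasing-distance
order, one-to-one, within a 3 px radius (about one PSF diameter); distance
ties resolve by index so the matching is deterministic. Greedy matching can
in principle fall one pair short of the maximum-cardinality matching in
contrived geometries; the tests compare it against an exact matching oracle
and bound the discrepancy. Precision, recall and F (harmonic mean) are
pooled over images; the matching criterion behind published F-measures of
this kind is rarely stated, so the 3 px greedy rule is documented here as
this package's convention.

## Problem sizes and numerical choices

The shipped test and acceptance workloads use 400×300 px fields with 40
spots (20 fields for detection scoring, 5 + 10 for the end-to-end recovery
check) and 443-pair calibration tables — sizes at which every check runs in
seconds while keeping ≥ 800 ground-truth spots in the pooled F-measure.
Degenerate inputs are rejected rather than guessed at: images smaller than
3×3, calibration sets with < 3 pairs or zero signal variance, groups with
< 2 observations, zero-variance correlation inputs. Centroids fall back to
the unweighted mean in the (threshold-impossible) case of an all-zero
region. 12-bit normalization at load time is by container convention
(8-bit ×16; 16-bit pass-through when max ≤ 4095, else right-shift 4) with
an explicit `bit_depth_hint` override, and the chosen mapping is logged.

## Known limitations

* Spot "brightness" for calibration is integrated signal by default; peak
  value is recorded but the two are not automatically cross-validated.
* No sub-pixel localization, PSF fitting, deconvolution or watershed
  splitting — overlapping spots closer than the minimum separation merge.
* The standard curve is linear with no saturation term; at very high
  particle numbers per spot (clipping at 4095 ADU) counts will be
  underestimated.
* Per-cell quantification requires user-supplied cell ROIs or counts.
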