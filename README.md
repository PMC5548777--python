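# pidspot

Quantitative immunohistochemistry by counting fluorescent nanoparticles.

Phosphor-integrated dots (PIDs) are ~150 nm nanoparticles packing on the
order of 10^5 organic fluorophores — roughly 100× brighter than a quantum
dot, and bright enough to stand out above tissue autofluorescence. When a
target protein is immunostained with PIDs, its expression level can be
measured as a *particle count* rather than a staining intensity, which makes
the readout linear over a wide dynamic range. `pidspot` implements the image
analysis that turns a single-channel fluorescence micrograph into such
counts, for microscopists and digital-pathology developers who have
PID-stained (or similar nanoparticle-labelled) tissue images:

1. **Spot identification.** The 12-bit image is high-pass filtered
   (subtraction of a Gaussian blur, σ = 2 px) to remove the smooth
   autofluorescence background. The filtered image is scanned with a 3×3
   window: a pixel strictly greater than its 8 neighbours is a local
   maximum, strictly smaller a local minimum. Each maximum is paired with
   its nearest minimum; only maxima with prominence

   `v_max − v_min ≥ NT`,  noise tolerance NT = 32 ADU,

   are kept as *positive bright spots* — a real spot must rise well above
   the local noise floor.
2. **Spot area definition.** The filtered image is binarized at a fixed
   threshold (16 ADU) and 8-connected components are extracted. Components
   containing at least one positive point become spots; the rest are
   discarded.
3. **Particle-number estimation.** A standard curve `count = a·signal + b`,
   fitted by ordinary least squares to spots whose particle numbers are
   known independently (electron-microscopy counting in the reference
   workflow), converts each spot's integrated fluorescence signal into a
   particle count. Counts are then reduced to particles per 0.01 mm²
   (100 µm × 100 µm field) or per cell (10 µm-square cell convention:
   100 cells per field), and groups are compared with an F-test-gated
   Student/Welch t-test.

Because real PID micrographs are not distributable, the package ships a
synthetic scene generator (`pidspot.synthetic`) producing tissue-like
images — smooth autofluorescence, PSF-blurred multi-particle spots, shot
and read noise, 12-bit clipping — with exact ground truth, so the entire
pipeline is testable end to end. See `docs/methods.md` for the model and
all parameter choices.

## Worked example

```python
import pidspot as ps

# calibration fields: detections paired with known particle counts
pairs = []
for seed in range(100, 105):
    img, truth = ps.generate_image(ps.SceneParams(seed=seed))
    spots = ps.detect(img)
    m = ps.match_detections(spots, list(zip(truth.xs, truth.ys)), radius_px=3.0)
    pairs += [ps.CalibrationPair(spots[d].integrated_signal, float(truth.particles[t]))
              for d, t in m.pairs]
curve = ps.fit_standard_curve(pairs)
print(f"standard curve: n={curve.n}, slope {curve.slope:.6f} particles/ADU, "
      f"intercept {curve.intercept:.3f}, r = {curve.r:.3f}")

# a fresh test field
img, truth = ps.generate_image(ps.SceneParams(seed=42))
spots = ps.detect(img)
m = ps.match_detections(spots, list(zip(truth.xs, truth.ys)), radius_px=3.0)
precision, recall, f = ps.f_measure(m)
print(f"planted spots: {truth.n_spots}, detected: {len(spots)}, "
      f"precision {precision:.3f}, recall {recall:.3f}, F {f:.3f}")

cal = ps.calibrate_spots(spots, curve)
density = ps.particle_density(cal, img.area_mm2)
print(f"estimated particles: {sum(s.particle_count for s in cal):.1f} "
      f"(planted {truth.total_particles})")
print(f"density: {density:.1f} particles per 0.01 mm^2; "
      f"per 10-um-square cell: {ps.particles_per_cell_from_density(density):.2f}")
```

Output:

```
standard curve: n=200, slope 0.000946 particles/ADU, intercept 0.052, r = 0.985
planted spots: 40, detected: 49, precision 0.816, recall 1.000, F 0.899
estimated particles: 264.8 (planted 262)
density: 861.9 particles per 0.01 mm^2; per 10-um-square cell: 8.62
```

The curve maps integrated spot signal (ADU) to particles; on the unseen
test field the pipeline finds every planted spot (recall 1.0, with a
handful of noise-induced false positives) and recovers the planted total of
262 particles to about 1%. The density line shows the standard per-area and
per-cell reductions used for reporting.

The same workflow is available from the shell:

```sh
pidspot simulate --n-images 1 --seed 1 --out sim/
pidspot detect --input sim/img_000.tif --noise-tolerance 32 --binarize-threshold 16 --out spots.csv
pidspot eval --detected spots.csv --truth sim/truth_000.csv --out eval.json
pidspot geometry --area 70650 --ligands 2460   # streptavidin density, nm^2/molecule
```

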