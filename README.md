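# band4 — quantifying the RPE / Bruch's membrane complex in visible-light OCT

Visible-light OCT resolves the outermost hyperreflective band of the retina
("band 4") into sub-bands: the retinal pigment epithelium (RPE) cell body, a
hyporeflective zone beneath it, and the thin Bruch's membrane (BM). Measuring
BM is hard for a physical reason: melanosomes in the RPE multiply scatter
light, and the late-arriving photons are mapped to depths *beyond* their
origin, laying a decaying tail across BM that skews and broadens its
intensity peak. `band4` implements the measurement chain that corrects for
this, for researchers building or validating outer-retinal quantification
pipelines:

* **Axial PSF arithmetic** — resolution from the source spectrum
  (δz = 0.44 λ₀²/Δλ), field→intensity FWHM (÷√2), and quadrature
  deconvolution `w_true = sqrt(w_meas² − w_psf²)` for Gaussian profiles.
* **Monte Carlo photon transport** through an RPE slab over a specular BM
  (Henyey–Greenstein scattering, absorbing-BM mode to isolate the
  multiple-scattering tail, local-estimator scoring).
* **Tail-corrected BM thickness**: align A-scans on the BM peak, average and
  normalize, fit the tail inner to BM with a 4-parameter model (cubic or
  biexponential), extrapolate across BM, subtract, and fit a Gaussian:
  FWHM = 2√(2 ln 2)·σ, with R² reported.
* **Morphometry**: three fovea-centration strategies, area-weighted
  9-sector macular maps (0.75 / 2.25 / 4.5 mm circles), through-origin
  proportional fits with 95% CIs, and a centration-free thickness-vs-proxy
  histogram.
* **Depth-resolved RPE reflectivity** by eccentricity, in percentage and
  absolute depth, with log-decay rates.
* **A seeded synthetic-retina generator** (radial scan sets with exact
  ground truth, speckle, per-eye cohort variability) that closes the loop:
  every stage is tested against what the generator put in.

## Worked example

Validate the tail correction in silico (a reflective-BM and an absorbing-BM
simulation, quantified four ways):

```python
from band4 import RunConfig, run_validation_study

cfg = RunConfig(mode="simulate_validation", n_photons=200_000, seed=0)
print(run_validation_study(cfg).round(4).to_string(index=False))
```

```
method  fwhm_um  r_squared  rms_vs_oracle  n_photons      seed
  none   0.7321     0.9995         0.0402     200000 205180295
 cubic   0.7297     1.0000         0.0078     200000 205180295
 biexp   0.7250     0.9999         0.0108     200000 205180295
oracle   0.7281     0.9998         0.0000     200000 205180295
```

The BM reflector in the simulation is a delta function, so a perfect
measurement returns the intensity-PSF width (0.707 µm). Without correction
the scattering tail inflates the width; subtracting the extrapolated cubic
tail recovers it, and agrees with the in-silico oracle (subtracting the
absorbing-BM run directly) to better than 1% RMS of the peak.

Run the full pipeline on a small synthetic cohort:

```python
from band4 import RunConfig, run_cohort_study

report = run_cohort_study(RunConfig(n_eyes=3, seed=1))
print(report.bm_summary.round(4).to_string(index=False))
```

```
method  mean_fwhm_um  sd_um    cov  mean_r2  n
  none        2.9247 0.6932 0.2370   0.9448  3
 cubic        2.5351 0.0641 0.0253   0.9846  3
 biexp        2.4433 0.2081 0.0852   0.9942  3
```

The generator renders each eye with a true BM FWHM of 2.40 µm, which a
0.707 µm PSF broadens to √(2.40² + 0.707²) = 2.50 µm. Without tail
correction the measured width is overestimated (2.92 µm) with high
across-eye variability; the corrections recover the convolved truth.
`report.sector_stats` carries the area-weighted RPE thickness per macular
region (the same run printed a central-disc mean of 11.08 µm against a
calibrated truth of 11.13 µm), `report.proportional_fits` the
through-origin slopes between sectors, and `report.rpe_profile` the
depth-resolved interior reflectivity per eccentricity bin.

The same chains are scriptable from a shell:

```
band4 simulate --seed 0 --n-photons 200000
band4 cohort --seed 1 --n-eyes 3 --out runs/demo
band4 quantify-bm scans/eye.tiff --method cubic
```

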