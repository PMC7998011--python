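# Methods

This note documents the models, algorithms, default parameters and known
limitations of the `band4` package: what each stage assumes, which knobs
matter, and what the synthetic-data experiments can and cannot show about
real visible-light OCT data.

## The measurement problem

Visible-light OCT resolves the outer retinal band 4 into sub-bands: the
hyperreflective RPE cell body (4C), a hyporeflective zone (4D) and the thin
Bruch's membrane band (4E). Two quantities are fragile:

* **BM thickness.** Operationally the FWHM of the BM intensity peak.
  Multiply scattered light from the melanosome-laden RPE arrives late and is
  mapped to depths *beyond* its origin, laying a decaying "tail" across BM
  that skews and broadens the peak. The package implements the correction:
  estimate the tail on a window inner to BM with a 4-parameter model (cubic
  polynomial or biexponential), extrapolate it across the BM zone, subtract,
  then fit a Gaussian (optionally with a constant baseline) and report
  FWHM = 2√(2 ln 2)·σ and R².
* **The PSF contribution.** A measured Gaussian band is the convolution of
  the true profile with the axial intensity PSF; widths add in quadrature.
  The intensity PSF FWHM is the field (coherence-envelope) FWHM divided by
  √2; the true width is recovered by quadrature subtraction
  (`deconvolve_fwhm`). If the true profile is better modeled as rectangular,
  no correction applies and a mode flag returns the input unchanged.

## Monte Carlo model (`montecarlo`)

Geometry: a 1-D pencil beam enters a homogeneous scattering slab (the RPE)
resting on a planar specular reflector (BM). Free paths are exponential with
rate `mu_s`; deflections follow Henyey–Greenstein with anisotropy `g`;
absorption `mu_a` attenuates packet weight; the BM either mirror-reflects
with relative weight `bm_reflectance` or, in the absorbing mode used to
isolate the tail, terminates the packet. Detected light is scored at the
apparent depth (total optical path)/2 − slab thickness, so the ballistic BM
echo lands at z = 0, and the histogram is convolved with the Gaussian
intensity PSF.

Defaults (configuration-exposed; chosen as order-of-magnitude RPE optics at
visible wavelengths): slab thickness 10 µm, `mu_s` = 0.3 µm⁻¹,
`g` = 0.94, `mu_a` = 0.05 µm⁻¹, acceptance half-angle 5°,
`bm_reflectance` = 0.003. The reflectance acts purely as a relative weight
(profiles are normalized downstream); 0.003 places the ballistic echo
clearly above the multiple-scattering tail, matching the qualitative
appearance of the validation experiment the simulation reproduces.

Numerics. Naive exit-cone tallying at a 5° aperture leaves the tail far too
noisy for stable extrapolation fits at 10⁶ packets, so the simulator scores
with a **local (next-event) estimator**: at every scattering vertex it adds
the expected contribution of (a) scattering directly into the acceptance
cone and escaping, and (b) scattering vertically down, bouncing off BM and
escaping; the unscattered echo is added in closed form. Packets turning
upward for the first time — rare events that feed the tail — are split 8-way
at 1/8 weight. Both techniques preserve the expectation of the physical
tally. Low-weight packets are terminated by Russian roulette at weight
10⁻⁴ (survival 0.1). Detected contributions are classified ballistic
(no scattering), quasi-ballistic (accumulated deflection < 10°, a
diagnostic threshold only) or multiple.

Verification: across 12 seeds at 10⁶ packets, the cubic-corrected BM FWHM
lies within ±5% of the 0.707 µm intensity PSF, the uncorrected FWHM is
strictly larger, and the cubic-corrected profile agrees with the
absorbing-BM oracle within 5% RMS of the normalized peak.

## Synthetic retina (`phantom`)

The phantom is a radially symmetric parametric macula with eight boundaries
(ILM, ELM, inner EZ, inner photoreceptor OST, apical RPE, inner BM, BM peak,
outer BM).

**Calibration.** The true RPE thickness profile is a plateau of 11.13 µm
inside r ≤ 0.375 mm followed by a smooth cosine ramp
t(r) = floor + (11.13 − floor)·(1 + cos(π·u^p))/2, u = (r−0.375)/(3−0.375),
with floor = 9.0765 µm and p = 0.5722 solved so that the area-weighted means
over the standard 0.75 / 2.25 / 4.5 mm circles are exactly
11.13 / 10.55 / 9.56 µm. The true BM band is a Gaussian of FWHM 2.40 µm,
i.e. 2.502 µm once convolved with the 0.707 µm PSF. Between-eye variability
uses multiplicative factors (clipped Gaussians renormalized to unit cohort
mean, so cohort-level truth equals the calibrated values): thickness scale
SD 7.9% (reproducing a 0.88 µm central-disc SD) and BM width SD 6.9%
(reproducing a 0.16 µm SD of the measured width). Tail amplitude and
choriocapillaris brightness vary 30% per eye; scan-center decentration is
drawn at 0.03 mm SD per axis (the acquisition centers on the foveola with an
alignment cross, so residual errors are small); each eye carries a random
retinal tilt plane (3 µm/mm SD per axis).

**Rendering.** Bands with resolvable substructure (ILM, ELM, EZ, OST, the
RPE interior) are drawn as anti-aliased top-hat or windowed profiles, so
after convolution with the symmetric PSF their operational boundaries — the
maximal-gradient loci — coincide with the anatomical edges. BM, which the
system barely resolves, is drawn as a Gaussian; its inner/outer boundaries
are *defined* as the inflection points of the PSF-convolved band
(peak ∓ one convolved sigma), the positions a gradient segmentation finds.
The RPE interior decays as exp(−2µd) with a single volumetric attenuation
µ = 0.15 µm⁻¹ shared across eccentricities (an optional second, deeper
organelle band is available but off by default); the multiple-scattering
tail is exponential from the apical RPE outward (amplitude 1.5 relative
units, decay 0.08 µm⁻¹ — strong enough that the uncorrected BM width is
overestimated by ~25%, as in vivo); a dim choriocapillaris plateau (0.12)
starts 1.5 µm below the outer BM. Fully developed speckle is multiplicative
unit-mean exponential intensity noise, independent across the 30 averaged
frames; the frame average is drawn directly from the equivalent
Gamma(30, I/30) distribution. Each B-scan receives a random sub-pixel axial
offset: a real scanner never aligns its pixel grid to the anatomy, and a
fixed phase would lock pixel-grid localization errors coherently across
columns and eyes.

Scan geometry follows the radial protocol: six lines every 30°, 840 A-scans
over 15°, 0.3 mm/degree, axial pixel 0.35 µm (the reconstructed pitch is a
free choice; the PSF is oversampled). Ground truth (subpixel contours,
per-column thickness, fovea position) is stored with every render.

What the phantom does **not** model: vascular shadows, choroidal texture,
pathology, motion artifacts, inter-frame speckle correlation, and
wavelength-dependent scattering. Passing tests therefore demonstrate
pipeline correctness under controlled conditions, not robustness to every
property of in vivo scans.

## Segmentation (`segmentation`)

A dynamic-programming search per boundary maximizes summed directional
gradient (dark→bright for band tops, bright→dark for bottoms) with a
±3 px/column jump limit, inside per-column windows anchored on previously
found boundaries. The ellipsoid zone is found first as the *upper* of the
two strongest non-overlapping dark→bright paths (the apical RPE step can
out-gradient the EZ when the scattering tail is strong, and the EZ is always
the shallower of the two). Integer paths are refined to subpixel positions
by a parabolic fit of the gradient peak, computed on a more laterally
smoothed gradient (σ = 8 columns; the steep foveal ILM is exempt) because
peak-location bias under speckle scales with local noise variance while
contours vary slowly across columns. The BM peak is the intensity maximum
between the BM contours. Column failures are masked, never interpolated
silently; there is no interactive correction.

Alignment (`align_to_bm_peak`) finds each column's BM peak, smooths the peak
positions laterally over 15 columns (aligning on raw speckle maxima
artificially sharpens the averaged peak — an order-statistics bias worth
≈ −0.4 µm of fitted FWHM), and resamples columns so all peaks share the
median row.

Recovery on the default phantom: noise-free RMSE ≤ 0.25 px for every
boundary; with 30-frame speckle, ≤ 0.7 px for the inner BM and ≤ 0.25 px for
the apical RPE.

## BM quantification (`bmquant`)

`quantify_bm` composes transverse averaging and peak normalization, tail
fitting, extrapolated subtraction (negative values clipped at zero, clipped
fraction reported) and the Gaussian fit. The Gaussian includes a constant
baseline by default (it absorbs residual signal from beneath BM);
a no-baseline mode is available. The biexponential uses 8 deterministic
multi-starts on a log-spaced rate grid with linearly solved amplitudes,
bounded rates ≥ 0 and a capped refinement budget; ties break by residual
then by the lower rate.

Window placement is relative to the segmented contours and differs by
geometry, mirroring how the validation and in-vivo analyses show different
fit ranges:

* **Validation (BM band ≈ PSF):** tail fit from apical RPE + 2 µm to inner
  BM − 1.5 PSF FWHM; subtraction/fit region to outer BM + 1.5 PSF FWHM.
* **Cohort pipeline (BM band ≈ 3.5× PSF):** tail fit from apical RPE + 1 µm
  to inner BM − 2.0 PSF FWHM, and the extrapolated tail is clamped to be
  non-negative and non-increasing with depth (a scattering tail decays; the
  clamp stops polynomial swings beyond the fit window). These defaults were
  set by nulling the window-placement bias on noise-free phantoms, where the
  short validation guard would leave ~13% of the BM Gaussian flank inside
  the tail window and bias the corrected width low.

On the default cohort the three methods behave as the physics predicts:
no correction overestimates the BM FWHM by ~25% with a poor Gaussian fit and
a large across-eye CoV; both tail corrections recover the true convolved
width. A known property of the synthetic world: because the generator's
tail is exactly exponential, the biexponential is the *true* tail model and
extrapolates essentially perfectly, so its across-eye CoV can match or beat
the cubic's — on real profiles, whose tails are not clean exponentials and
which carry elevated signal outer to BM, the cubic's local-smoother
stability is the reason it is preferred.

## Morphometry (`morphometry`)

Sector statistics use the 0.75 / 2.25 / 4.5 mm circles with
nasal/temporal/superior/inferior quadrants split at the ±45° diagonals
(9 regions). Each radial sample carries the annular-area weight
|r dr| = |p·d̂|·Δs of the segment it represents (the exact Jacobian for a
line that misses the center), normalized within each region.

Centration: method 1 recenters each B-scan at its own smoothed
(0.25 mm window) minimal ILM-to-band-1 thickness; method 2 fits a smoothed
thin-plate-spline surface to that thickness over all six lines and minimizes
it on a 0.01 mm grid with a 5× sub-grid refinement (recovery ≤ 0.02 mm on
the default cohort); method 3 avoids eccentricity entirely by pairing
thickness with the inner-band-2→outer-band-4 thickness proxy. Sector
statistics are computed from the measured samples at their recentered
positions; reinterpolating onto new spokes is available for map rendering
but not used for statistics, since linear interpolation across lines biases
the concave foveal plateau low.

The through-origin proportional fit uses slope = Σxy/Σx² with a
normal-approximation 95% CI from the residual variance under the
through-origin model.

## RPE interior profiles (`rpe_profile`)

Per column the intensity is resampled on a 0–100% depth grid (2% step)
between the apical RPE (0%) and inner BM (100%), averaged within
|eccentricity| bins ({0–0.5, 0.5–1, 1–1.5, 1.5–2.25, 2.25–3, 3–4.5} mm,
minimum 50 columns per bin), normalized to 1 at 0%, and averaged
(unweighted) across scans and subjects. Conversion to absolute depth uses
each bin's mean thickness. On the default phantom the total drop is larger
centrally (thicker RPE) while absolute-depth log-decay rates over 2–3 µm
agree across bins within 15% — the constant-volumetric-density picture.
With the scattering tail disabled, the measured rate recovers twice the
generator's one-way attenuation coefficient (round-trip path) within 15%;
with the default tail present, the apparent rate is lower because the
slowly decaying tail adds to the interior signal.

## Study sizes and seeds

The cohort study analyzes 19 eyes (six 840-column B-scans each) in about
two minutes on one CPU; the Monte Carlo validation uses 10⁶ packets per run
(reflective + absorbing, ≈1–2 minutes). Every stochastic stage draws a
deterministic sub-seed from the run seed (CRC-based stage hashing), so
identical configurations reproduce byte-identical outputs.

## Known limitations

* The Monte Carlo optical coefficients are order-of-magnitude stand-ins;
  absolute tail magnitudes should not be interpreted quantitatively.
* The generator's exponential tail makes the biexponential fit artificially
  exact (see above); method-comparison CoV orderings between the two
  *corrections* are therefore near ties in silico, unlike in vivo.
* Boundary localization retains a sub-0.1 px pixel-phase systematic under
  speckle; with phase randomization it averages below 0.1% of thickness at
  the cohort level.
* The 15° field exactly spans the 4.5 mm grid, so decentration truncates
  outer-ring coverage asymmetrically; with 0.03 mm decentration SD the
  induced sector bias is ≤ 0.1%.
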