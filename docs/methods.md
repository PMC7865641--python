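# Methods

This note documents the models, numerical choices and known limitations of
`irisqc`. It is the reference for *why* the package computes what it
computes; the README covers *what* it does.

## Optical model

The chip is modeled as a four-layer stack at normal incidence:
ambient medium (air for dry scans, water for in-flow acquisitions),
an effective biolayer of thickness `d_bio` and index 1.45, thermally grown
SiO₂ of thickness `d_ox` (nominally 110 nm for imaging chips, 100 nm for
fluorescence chips), and a crystalline-silicon substrate with a complex
index. Reflectance is computed with the characteristic-matrix
(transfer-matrix) method; an independently coded recursive-Airy summation
(`optics.airy_reflectance`) implements the same physics through a different
formula and is used only as a cross-check — the two agree to < 1e-10 over
the full parameter range, and tests enforce this.

Refractive indices ship as a built-in table (`constants.py`): Si from
Aspnes & Studna (1983), SiO₂ from the Malitson Sellmeier dispersion, water
from standard visible-range tabulations, biolayer n = 1.45 (the usual
effective index for dense DNA/protein films). All are overridable per
wavelength through `OpticsConfig`. Assumptions: normal incidence (the
imaging objective has low NA), non-dispersive biolayer, absorption only in
the substrate.

### Mass conversion

Two conventions are available, selected by `OpticsConfig.mass_convention`:

- `film_density` (default): Γ = c·d_bio with c = 1.2 ng/mm² per nm, the
  effective-film-density convention common in reflectometric biosensing.
- `de_feijter`: Γ = d_bio·(n_bio − n_medium)/(dn/dc), dn/dc default
  0.17 mL/g.

The conversion is linear and invertible; which convention a given published
pg/mm² number used is generally not stated, so both are first-class.

### Look-up table and inversion

`build_lut` precomputes R on a dense (d_ox, d_bio) grid, default step
0.1 nm, oxide window nominal ± 20 nm, biolayer window 0–30 nm; bilinear
interpolation between nodes is the defined evaluation semantics
(interpolation error < 1e-4 reflectance units, far below the noise floor).
Reflectance is periodic in optical thickness; the restricted oxide window
makes the inversion single-valued because chips are manufactured near
nominal.

`fit_thickness` minimizes Σ_λ (I_λ − g_λ·R(d_ox, d_bio, λ))² by exhaustive
scan over the LUT nodes inside the search window, parabolic sub-node
refinement, and finally a bounded local least-squares polish against the
exact forward model. The polish matters: the biolayer index (1.45) nearly
matches the oxide (1.46), so the (d_ox, d_bio) cost surface has a long
shallow valley and the discrete argmin can sit over a nanometre along it;
the continuous polish lands on the true minimum. The procedure is
deterministic — no random starts; ties break toward the smallest d_bio.
Degrees of freedom are checked up front: a free common gain requires ≥ 3
wavelengths, known gains ≥ 2. Minimizers on the window boundary are flagged
(`window_edge`); all-zero observations raise a degenerate-input error.

### Gain calibration and local referencing

Per-channel illumination intensities are unknown. Calibration is two-step:
(1) fit the chip-level d_ox from the spectral shape of the spot-free
background across all wavelengths with one free common gain, d_ox
restricted to nominal ± 10 nm (manufacturing tolerance); (2) freeze
per-channel gains as background intensity / model reflectance. The scheme
presumes channel balance known to roughly a percent (a monitored LED
source); residual imbalance trades against d_ox at about 0.5 nm per percent
and rescales the d_bio sensitivity by ~1.4 %/nm — one reason quantification
is differential (below).

Each spot is then quantified against its *local* background annulus: the
annulus (assumed probe-free) pins a local oxide thickness with d_bio = 0 and
d_ox free within ± 5 nm of the chip calibration, and the spot fits d_bio at
that local oxide. This cancels smooth oxide-thickness variation across the
chip (the generator plants ± 0.5 nm of it) and any residual calibration
offset. If the spot fits *below* its background, the signed differential is
recovered through the spot's oxide-equivalent thickness and reported as a
negative raw mass (clipped to 0 in the headline value, with a warning).

### Single-wavelength kinetic readout

Around an operating point (d_ox, d_bio) fitted from a four-color pre-scan,
ΔΓ = c·(I/I₀ − 1)·R/(∂R/∂d_bio), with the slope from a central finite
difference (h = 0.01 nm). Operating points at an interference extremum
(|∂R/∂d| / R below 1e-3 per nm) raise an error — the readout has no
sensitivity there. Implied |Δd_bio| > 5 nm triggers a linearization
warning. At 110 nm oxide in water at 452 nm the relative slope is
~0.45 %/nm, which sets the conversion noise floor.

## Chip QC

Grid registration: difference-of-Gaussians band-pass tuned to the spot
radius (rectified, since spots can be brighter or darker than background
depending on where the biolayer moves the interference curve); local maxima
above 6 propagated-noise sigmas, border excluded; rotation from
nearest-neighbor displacement angles folded mod 90°, then refined by
Procrustes; lattice anchor chosen per axis to maximize detections inside
the layout, ties resolved toward the grid most centered in the image.
Fewer detections than 25 % of the expected spots raise `GridNotFoundError`.

Per-spot measurement: the mask starts as the disk of expected diameter
(default 150 µm — droplets from an 80 µm piezo nozzle spread on the polymer
coating) and is refined by half-contrast thresholding when the spot stands
≥ 3 noise sigmas out of its local background; geometry (centroid,
equivalent diameter, circularity 4πA/P²) comes from the refined mask, while
intensity medians use the mask eroded by 2 px, because the printed rim is a
soft ramp that otherwise dilutes the median by ~20 %. The background is the
1.2–1.8 spot-radius annulus clipped to the grid cell. Medians are used
throughout (robust to comets and debris). Saturation is counted against the
declared bit depth over the full mask.

Classification precedence: missing (< 0.2 ng/mm² absolute) > saturated
(> 1 % full-scale pixels) > irregular (circularity < 0.7 or diameter off by
> 35 %) > low-density (< 50 % of the replicate-group median) > ok. The
defaults separate a ~0.4 ng/mm² failed immobilization from a ~2 ng/mm²
healthy group with a wide margin; all thresholds live in `QCThresholds`.
Replicate CV uses the sample (n−1) standard deviation. The chip fails if
any probe's replicate group is entirely missing or more than 25 % of spots
are non-ok; partially flagged groups downgrade to pass-with-warnings by
default.

## Binding kinetics

Curves: per frame, spot and annulus medians (masks frozen from the
registered pre-scan) are converted to ΔΓ around their own operating points.
Source-power drift is removed first by dividing every trace by the median
normalized background trace — an exact common-mode rejection, whereas
subtracting after conversion cancels drift only to first order in the
operating-point difference. The local background is then subtracted and
replicate spots averaged (mean ± SD). Frame-to-frame rigid drift is checked
against frame 0 via median displacement of matched blob detections (robust
to the intensity changes that binding itself causes — phase correlation is
not, and also aliases by whole pitches on a periodic array); recoverable
drift is compensated by integer shifts, unrecoverable drift (> 0.25 pitch)
raises `DriftError`.

Specificity: one column per injection; the entry is the median of the last
30 s of the following wash minus the median of the 30 s before injection,
and is called specific when it exceeds 5 baseline sigmas. The baseline
sigma combines the detrended pre-injection scatter with the replicate SD
pooled over the movie (the short baseline alone is an unstable estimator).
Windows shrink with a warning for injections shorter than 30 s. Note one
physical subtlety the synthetic experiments exposed: a probe already
saturated by its own earlier cognate injection shows almost no net change
for a later cross-reactive analyte — cross-reactivity is only detectable on
probes whose surface is still free.

Langmuir fitting: piecewise closed-form 1:1 model under the schedule,
weighted least squares in log-parameter space, deterministic multi-start
over a fixed grid (k_on ∈ {1e4, 1e5, 1e6} /M/s, k_off ∈ {1e-5…1e-2} /s).
Standard errors propagate from the Jacobian. When the total wash decay
k_off·t_wash < 0.02 (or the log-k_off standard error exceeds 1), k_off is
reported as the resolution-limited upper bound 0.02/t_wash. Flat curves
(span below 5 noise sigmas) raise `NoBindingSignalError`. Mass-transport
depletion is ignored in the fitted model: a recirculated millilitre at
50 nM holds ~µg of analyte against sub-ng bound, so depletion is
negligible; experiments are at room temperature and temperature effects are
out of model.

## Concentration optimization

The saturation index S = (Γ_high − Γ_mid)/(Γ_mid − Γ_low) is scale-free;
its linear expectation for the 10/25/50 µM design is L = 25/15 ≈ 1.67.
Verdicts: *linear* when |S − L| ≤ 0.25·L; *saturating* when S < 0.5·L and
the Langmuir-isotherm residual does not exceed the proportional fit's;
otherwise *ambiguous*. The index and thresholds are this package's
formalization of a judgement usually made by eye; they are configurable.
With three design points the Langmuir isotherm is exactly identified, so
its residual is only a cross-check and the verdict leans on S. A
non-monotone low end leaves S undefined (ambiguous, with warning). Under
5 % per-replicate noise in quadruplicate the mean masses carry 2.5 % noise,
and a truly saturating isotherm (K·c_high ≈ 6) is classified *saturating*
about 93–95 % of the time — the misses fall in the deliberate ambiguous
band, which is the price of a three-point design; more replicates or
concentrations would close it.

The optimum is the argmax of binding signal, ties (within 2σ of the max)
breaking toward the lowest concentration; crowding is flagged when any
higher concentration binds less than the optimum by more than 2 combined
replicate sigmas. Fluorescence is ingested as arbitrary-unit tables and
never converted to mass; cross-modality agreement is summarized by Pearson
and Spearman correlations per chemistry and pooled, undefined below three
matched points.

## Synthetic data generator

The generator is the package's instrument stand-in; every analysis module
is validated against its planted ground truth.

- **Chip images**: per-pixel reflectance through the same forward model the
  inversion uses (but with independently planted thicknesses), spots as
  soft-edged disks (3 px rim), smooth ± 0.5 nm oxide-thickness variation,
  per-channel gains = one auto-exposure scale × 1 % channel deviations
  (see calibration above; fully independent per-channel auto-exposure would
  flatten the background spectrum and make any background-based oxide
  calibration information-free), 0.5 % multiplicative detector noise,
  16-bit quantization after noise. Saturation scenarios raise the gain so
  spots clip at full scale. Healthy probes immobilize at ~2 ng/mm²
  (lognormal across probes, 15 % spread); planted failures retain
  0.02 ng/mm² residual.
- **Binding movies**: per-spot Γ(t) from the closed-form 1:1 model under
  the injection schedule (cognate-only unless a cross-reactivity matrix is
  planted), rendered through the forward model at 452 nm in water. The
  default experiment mirrors the documented protocol: five probes in
  duplicate, sequential 50 nM injections, 20 min association, 10 min wash,
  2 min baseline, 10 s sampling. Traces mode emits region-median
  intensities with noise scaled by 1.2533/√n_pixels (the median of n noisy
  pixels), so it is statistically interchangeable with rendering frames and
  extracting medians; frames mode renders actual movies.
- **Concentration series**: NHS-ester immobilization follows a Langmuir
  isotherm in spotting concentration (capacity 2.4 ng/mm², K = 0.12/µM —
  strong saturation, K·c_high ≈ 6); azide-DBCO click immobilization is
  linear (0.06 ng/mm²/µM) up to a 5 ng/mm² cap, so the click surface
  allocates more probe at 50 µM. Probes differ by deterministic density
  factors (0.8–1.4), reflecting sequence-dependent spotting yield. Binding
  signal = η(Γ)·Γ·occupancy(C, K_d, t), with the crowding model
  η(Γ) = η₀/(1 + (Γ/Γ*)^h), defaults η₀ = 1, Γ* = 2.5 ng/mm², h = 2. The
  dedicated crowding scenario uses Γ* = 1.8, h = 4 over the linear
  chemistry, which puts the 50 µM density well past the efficiency
  collapse and the optimum at 25 µM. Fluorescence = gain × binding signal
  × 10 % lognormal readout noise. Replicates are quadruplicate with 5 %
  multiplicative noise. The crowding and chemistry models are simulation
  devices that emulate observed behavior, not fitted mechanistic models.

Determinism: a seed is mandatory; identical scenario + seed reproduce
bit-identical outputs. Changing only the seed redraws noise and instrument
nuisances (grid jitter, gains, oxide field) but leaves the planted
scientific truth (masses, defects, kinetics) unchanged.

### What the generator does not emulate

No optical point-spread function, vignetting, or stage drift beyond rigid
translation; no spot morphology pathologies other than planted ellipticity;
no bulk refractive-index jumps at injection boundaries; no probe-sequence
effects beyond scalar density/kinetic parameters; no surface regeneration
or two-state binding. Passing tests therefore demonstrate correctness of
the analysis chain under the stated physics and noise models, not
robustness to every artifact a real instrument can produce.

## Problem sizes in the tests and acceptance script

Oracle agreement is checked on a 121 × 31 grid × 4 wavelengths; inversion
round trips on 1000 random stacks; panel QC on 20 seeded chips (33 probes,
duplicate); specificity on 20 seeded five-probe runs (trace mode; the frame
mode is exercised on shorter movies); kinetic recovery on 100 seeded curves
at SNR 20 sampled at 2 s; verdict rates on 200 seeded replicates per
scenario. These sizes give stable rates while keeping a full run in about a
minute.
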