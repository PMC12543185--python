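# Methods

This note documents the models, numerical choices, and known limitations of
`lamsal`. Notation: θ is the orientation contrast of the foreground bars
(90°, 15°, 0°), depths are deep (D), middle (M), superficial (S), and all
response amplitudes are in percent signal change (psc) unless stated.

## Synthetic study conditions

The generators default to the study conditions the pipeline is designed
for: 30-s stimulus blocks interleaved with 15-s fixation, six blocks per
run (two per θ, balanced order), 60 texture events per block (200 ms
stimulus, ISI drawn from {200, 300, 400} ms), a paired repetition time of
5.02 s, and five partial-volume compartments (WM, three equi-volume
cortical layers, CSF).

**Event packing.** Sixty events with a mean slot of 500 ms exactly fill a
30-s block in expectation, but a random ISI draw can overflow it. The
schedule draws all ISIs, then sets the final ISI so the last event slot
ends exactly at the block boundary; if the drawn ISIs already overflow, all
ISIs are shrunk proportionally instead. Every block therefore contains
exactly 60 events, confined to the block.

**Laminar phantoms.** Each voxel is assigned a home compartment; its volume
fractions are a Dirichlet draw concentrated there, with neighbouring
compartments sharing mass (concentration parameter `pv_concentration`,
default 50 — rows are ~60–90% pure, mimicking 0.8-mm voxels straddling
layer boundaries). Ground truth gives every cortical layer a common base
response (1 psc) for all θ plus a 90°-specific increment of `effect_size`
weighted by the profile: `v1_like` (0.3, 0.5, 1.0) over (D, M, S) — an
intracortical, superficial-peaked effect; `ips_like` (0.4, 1.0, 0.4) —
feedforward, middle-peaked; `v2_like` (0.3, 1.0, 0.9); `flat` uniform.
WM and CSF are silent. Defaults `effect_size = 1.0` psc and
`noise_sd = 0.5` psc per timepoint give single-run laminar contrasts of
realistic (2–4 σ) detectability.

**Paired VASO runs.** The neural regressor per θ is the block boxcar
convolved with a unit-peak double-gamma HRF (peak 6 s, undershoot 16 s,
ratio 1/6) — a documented, swappable stand-in for the unstated canonical
block response; at the level of block-design fits the choice of impulse
shape is inconsequential. Voxel CBV amplitude is `weights @ b_true`. The
nulled series *dips* with CBV (VASO convention), the BOLD-like component
(same laminar amplitudes, scaled by `bold_gain`, default 2) multiplies both
series so that division removes it, and each series carries Gaussian noise
and a per-voxel linear drift (`drift_amplitude` % per run, random sign).
Nulled volumes are sampled at kTR, not-nulled at kTR + TR/2 (alternating
acquisition). The residual BOLD contamination of nulled volumes is not
separately parameterized; `bold_gain` controls the shared multiplicative
BOLD factor, and the simulator makes no claim about incomplete nulling.

**Gaze.** 1-kHz positions follow an AR(1) process (lag-1 coefficient 0.95)
whose stationary covariance matches the requested (σx, σy, ρ), so BCEA
estimators face realistic autocorrelation rather than white noise. Blinks
are a Poisson process (default 0.2 Hz) with exponential durations (mean
100 ms).

What the generators do **not** emulate: MR physics (k-space, T1 recovery),
motion, distortion, spatially structured (vascular or thermal-coil) noise,
drowsiness/attention drift, or saccadic main-sequence dynamics. Passing
recovery tests therefore demonstrates the correctness and calibration of
the analysis chain under its own assumptions, not robustness to every
artifact of real scans.

## BOLD correction and GLM

`boco_correct` linearly interpolates both series onto the TR/2 grid
anchored at the nulled sampling times (this realizes the TR/2
co-registration shift of the not-nulled series), divides nulled by
not-nulled, centres the ratio on its per-voxel median, inverts the sign so
CBV increases are positive, and by default rescales to percent signal
change about the median ratio. The psc scaling (rather than raw ratio
units) makes downstream GLM betas directly interpretable as psc and is
what the end-to-end recovery tests validate; `scale="ratio"` returns the
raw centred ratio.

The block GLM uses the same unit-peak convolved boxcars as the simulator,
plus Legendre polynomials to order 2 per run and optional user nuisance
columns (e.g. head motion). With `resample_tr` set to the acquisition TR,
condition regressors are sampled at that TR and linearly interpolated to
the analysis grid — the same temporal resampling the data underwent.
Without this, the interpolation mismatch attenuates betas by ~3–5%
(measured noiselessly); the pipeline enables it. A single HRF serves both
CBV and BOLD contrasts; no onset shift is applied for VASO's slower
hemodynamics, since block-design fits are insensitive to it.

Rank deficiency raises an error naming the collinear columns (QR
diagnostic). tSNR is mean/SD of the raw series; CNR is the
stimulus-minus-fixation mean difference over the residual SD after
removing the two state means; constant voxels are flagged, not silently
dropped.

## Layer unmixing and normalization

Unmixing solves all five compartments jointly by OLS (`Y = X·B + U`) and
reports standard errors from the residual variance; WM/CSF estimates are
retained for QC while the statistics use the three cortical layers.
Ordinary (not weighted) least squares matches the plain GLM formulation.
The RMS normalizer is computed over exactly the 9 cortical layer ×
condition cells (WM/CSF excluded; the normalization domain is fixed here
because the alternative — including WM/CSF cells — is not well defined for
3-layer inputs). The normalization leaves a per-subject RMS equal to the
group mean normalizer r̄, so group units remain psc; it is invariant to
per-subject rescaling and equivariant to global rescaling.

## gPPI

"Dot product" of the shifted boxcar and the seed is implemented as the
elementwise product forming a regressor (a scalar product would not yield
a timeseries). The boxcar shift is one sample of the analyzed series
(TR/2 = 2.51 s after BOLD correction) by default and configurable
(`shift_trs`), since a one-paired-TR shift is equally defensible. Seeds
are z-scored per run; PPI betas are therefore in units of the z-scored
seed — recovery tests rescale by the seed SD when comparing against
generating couplings. BOLD series are the default input for connectivity
(higher SNR); a flag runs the same analysis on CBV. The estimator equals
the generating coupling difference up to HRF-induced attenuation of the
block-boundary samples; the recovery test measures this (≲5% at the
default design) rather than assuming it away. Across subjects, pathway
deltas are compared by paired t, with Holm correction across the two
pathways' one-sample tests.

## Retinotopy

Polar angle is measured within each hemisphere from the upper vertical
meridian (0°) to the lower vertical meridian (180°); left-hemisphere nodes
project to the right visual hemifield and vice versa, so the corrected
anchor (127.88°, 4.28°) lands in the lower contralateral quadrant, at the
foreground's location. The default grid spans x ∈ [−8°, 8°],
y ∈ [−8°, 0°] at 0.1° — covering the 12.5° × 6.5° lower-field stimulus.
pRFs are isotropic unit-volume Gaussians (no compressive summation); a
center falling off-grid triggers a warning reporting the truncated mass.
Within each subject all depths share one normalization (the across-depth
maximum), so relative laminar amplitude is preserved; group maps average
the normalized subject maps.

## Statistics

rm-ANOVA (pingouin) reports GG-corrected p and ε per effect; Mauchly's
test accompanies one-way designs. When an effect's sum of squares is
exactly zero the F ratio is reported as 0 with p = 1 (the 0/0 limit of a
null effect). The permutation FWE test uses the signed maximum correlation
across ROIs (one-sided in r, matching "the largest r"), the add-one p
estimator (p ≥ 1/(n_perm+1); default n_perm = 10,000), and the 95th
percentile of the null maxima as the significance threshold; an exhaustive
mode enumerates all n! permutations for n ≤ 8 and returns exact p values.
BCEA uses the χ²₂ quantile (5.9915 at 95% coverage) by default;
`chi2_quantile` accommodates k-factor parameterizations in the
fixation-stability literature. Gaze preprocessing pads each blink by
200 ms on both sides, interpolates linearly, detrends linearly, and
subtracts per-block means; BCEA moments use only originally valid samples.
Two-sided tests throughout.

## Pipeline and problem sizes

The demonstration pipeline simulates a per-subject saliency trait
(N(1, 0.25), truncated at 0.4) that jointly scales the laminar effect, the
behavioral 90° sensitivity, and the feedforward coupling — producing the
coupled behavior–fMRI–connectivity structure the group statistics are
designed to detect. Defaults: 20 subjects, 3 runs per subject per region,
300 voxels per region, 150 pRF nodes per hemisphere, 30-s gaze traces per
condition for 12 eye-tracked subjects. Three runs (rather than a full
nine-run session) and 300 voxels already give near-ceiling laminar-ordering
recovery, so they are the default problem size; all sizes are
configuration fields. Recovery-suite sizes (100-replicate ordering, 500 ×
1000 permutation calibration, 200-replicate threshold recovery) are chosen
so each suite establishes its property with comfortable statistical margin.

## Known limitations

- Layer weights are inputs: no surface reconstruction, equi-volume depth
  computation, or ROI definition from real anatomy.
- Deconvolution-based PPI and dynamic causal modelling are out of scope, as
  are Bayes factors; inference is frequentist.
- The deposited-workbook reader maps sheets/columns by an explicit schema;
  workbooks with other internal layouts need a YAML schema override.
- The ratio nonlinearity of BOLD correction leaves O((ΔS/S)²) residuals
  (~1% of response amplitude at default gains); they are measured by the
  tests, not corrected.
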