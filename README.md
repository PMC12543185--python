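# lamsal

Laminar VASO-fMRI analysis of visual saliency, as a tested, reusable Python
pipeline.

Cortical-depth-resolved fMRI can distinguish where a neural signal is
*generated* from where it is merely *received*: feedforward input terminates
in the middle cortical layers, intracortical (horizontal) computation lives
in the superficial layers, and feedback targets deep/superficial layers.
`lamsal` implements the full analysis chain used to ask where the visual
saliency map originates — from adaptive-staircase psychophysics and paired
blood-nulled/not-nulled (VASO) acquisitions through BOLD correction,
partial-volume layer unmixing, normalized laminar saliency statistics,
layer-dependent gPPI effective connectivity, pRF-based visual-field
back-projection, and permutation-corrected group inference. A first-class
synthetic-data module generates every input with known ground truth, so each
stage is validated by parameter recovery.

It is intended for laminar-fMRI methodologists and vision scientists who
want the statistical machinery of a depth-resolved saliency study without
the scanner: to validate analysis choices on phantoms, to power or stress
new designs, or to re-run the group statistics on deposited per-participant
tables.

## The model in brief

**Behavior.** A 2AFC foreground-localization task at bar Michelson contrast
`C = (L_bar − L0)/(L_bar + L0)`, driven by a 3-down-1-up staircase
(geometric 15% steps, start 0.2863). A Weibull psychometric function

```
p(C) = γ + (1 − γ − λ)(1 − exp(−(C/α)^β)),    γ = 0.5, λ = 0.01
```

is fitted by maximum likelihood; the threshold `C_th` is the contrast at 80%
accuracy, sensitivity `S = 1/C_th`, and the behavioral saliency score is
`SS_behavior = (S(90°) − S(15°)) / mean(S)` for orientation contrasts θ of
the foreground against the background texture.

**Laminar CBV responses.** Paired nulled/not-nulled series are upsampled ×2,
co-registered by a TR/2 shift, and divided (BOLD correction); the
sign-inverted ratio in percent signal change enters a block GLM with a
canonical double-gamma HRF. Voxel betas `Y` are unmixed into five
compartments (WM, deep, middle, superficial, CSF) by the spatial regression
`Y = X·B + U`, where `X` holds each voxel's volume fractions. Responses are
normalized per subject s by the RMS over the 9 layer × condition cells,

```
S_fMRI(s,l,θ) = r(s,l,θ) / r_norm(s) · r̄ ,   r_norm(s) = RMS_{l,θ} r(s,l,θ),
```

and the saliency-sensitive response is `SS_fMRI = S_fMRI(90°) − S_fMRI(15°)`
per depth.

**Connectivity.** Deconvolution-free gPPI: the PPI regressor is the
elementwise product of the condition boxcar (shifted one TR) and the
z-scored seed timecourse; `Δβ = β_PPI(90°) − β_PPI(15°)` contrasts
saliency-dependent coupling for the feedforward (V1 superficial → IPS
middle) and feedback (IPS deep → V1 deep) pathways.

**Retinotopy.** Atlas pRF coordinates are rescaled so the localizer peak
(Am, Em) maps to the foreground's screen location (127.88°, 4.28°); depth
responses are back-projected as response-weighted unit-volume Gaussians and
jointly normalized by the across-depth maximum.

**Inference.** Repeated-measures ANOVA with Greenhouse–Geisser correction,
paired t tests, Pearson correlations with max-statistic permutation FWE
across ROIs, Holm correction, and fixation stability via the 95% bivariate
contour ellipse area `BCEA = π · χ²₂(0.95) · σx σy √(1−ρ²)`.

## Worked example

```python
from lamsal.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1), out_dir="out")
summary = result["bundle"]
print(summary["layer_ss_means"]["V1"])
print(summary["behavior"]["t"], summary["behavior"]["p"])
print(summary["connectivity"]["feedforward_delta_mean"],
      summary["connectivity"]["feedback_delta_mean"])
```

With the default configuration (20 synthetic subjects, 3 runs each, 300
voxels per region) this prints

```
{'deep': 0.3038919150843674, 'middle': 0.4998739605715641, 'superficial': 1.0234022868747048}
11.610555299025753 4.5138964340956877e-10
0.4649134685004954 -0.05847321279152262
```

i.e. the group-mean saliency-sensitive CBV response `SS_fMRI` in V1 peaks in
the superficial depth (1.02 vs 0.30/0.50 percent signal change — the
generating laminar profile), the 90° foreground is detected at reliably
higher contrast sensitivity than the 15° foreground (paired t₁₉ = 11.6),
and only the feedforward V1→IPS pathway carries a positive
saliency-dependent coupling difference (0.46 vs −0.06). `out/summary.json`
holds the full bundle, stamped with the config hash and seed; re-running the
same config reproduces the outputs byte for byte.

A thin CLI mirrors the library: `lamsal simulate`, `lamsal behavior
simulate|fit`, `lamsal run`, and `lamsal reproduce <workbook.xlsx>
<analysis>` to recompute group statistics from deposited per-participant
tables.

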