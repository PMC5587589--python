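# ctfr — statistical iterative CT reconstruction with feature refinement

`ctfr` reconstructs fan-beam CT images from **sparse-view** and
**limited-angle** projection data, the two standard ways of cutting
patient dose by acquiring fewer projections. With so little data,
filtered back-projection (FBP) produces severe streak artifacts, and
plain total-variation (TV) regularization removes the streaks but also
flattens small, low-contrast anatomy into patches. This package
implements the PWLS-TV-FR approach: a penalized weighted least-squares
data term with TV regularization, followed after **every** iteration by
a feature-refinement (FR) step that finds the structure lost to the TV
prior in the residual between successive iterates and blends it back.

It is aimed at researchers in CT reconstruction and preclinical
(micro-CT) imaging who want a compact, fully tested 2-D fan-beam
implementation with a matched projector pair, a built-in simulator and
an FBP baseline.

## The method

Given log-transformed line integrals `y` with per-ray variances
`Σ = diag(σ²ᵢ)` and the fan-beam system matrix `G` (Siddon
intersection-length ray tracing; the back projector is its exact
transpose), each iteration performs

1. **PWLS-TV update** (steepest descent with exact line search):

       μ^{n+1} = μ^n − τⁿ H − β_tv ∇TV(μ^n),
       H  = Gᵀ Σ⁻¹ (G μ^n − y),
       τⁿ = HᵀH / (GH)ᵀ Σ⁻¹ (GH),
       TV(μ) = Σ_{s,t} √((μ_{s,t}−μ_{s−1,t})² + (μ_{s,t}−μ_{s,t−1})² + α).

   By default the TV move is scaled relative to the data move,
   `β_tv = β · ‖τⁿH‖ / ‖∇TV‖` with `β = e⁻²`, so that `β` is the
   dimensionless fraction of the data step spent on smoothing
   (`tv_step_mode="absolute"` gives the unscaled `β·∇TV` form).

2. **Feature refinement**: from the fresh iterate `μ^{n+1}` and its
   Gaussian-degraded copy `μ_d`, patch statistics (3×3, unbiased) give
   the structure descriptor

       f_t = 1 − |(2σ_qp + C) / (σ_p² + σ_q² + C)| ∈ [0, 1],

   which is large where smoothing changes the neighbourhood, i.e. at
   structure. The new image is the clamped blend
   `μ_new = P[μ^{n+1} + f_t ⊗ (μ^n − μ^{n+1})]`, with `P` the
   non-negativity operator.

The first iterate is the FBP image. Accuracy is reported as RMSE and
PSNR (the PSNR uses a `Q−1` denominator; `--psnr-convention standard`
switches to the conventional `Q`).

## Worked example

Simulate a low-dose sparse-view scan of the built-in head phantom
(40 of the protocol's 120 views, 10⁶ incident photons per ray), then
reconstruct and evaluate it:

```
$ ctfr simulate --preset xcat_sparse --views 40 --grid-size 64 \
      --i0 1e6 --seed 1 --out scan.h5 --phantom-out truth.tif
wrote scan.h5 (40 views x 672 bins)

$ ctfr reconstruct scan.h5 --method pwls-tv-fr --iterations 10 --out recon.tif
pwls-tv-fr: RMSE=0.00149649 mm^-1  PSNR=22.07 dB  (10 iterations)

$ ctfr evaluate recon.tif truth.tif
{
  "rmse": 0.0014964930088039628,
  "psnr": 22.072517475470946,
  "psnr_convention": "unbiased"
}
```

The RMSE is the root-mean-square deviation from the ground-truth
attenuation map in mm⁻¹ — about 7% of the phantom's 0.019 mm⁻¹ peak for
this deliberately crude 40-view scan — and the PSNR is the matching
peak signal-to-noise ratio in dB. `recon.history.csv` holds the
per-iteration step size, cost terms and metrics; `recon.config.yaml`
the fully resolved run configuration. The same objects are available as
library calls (`ctfr.make_geometry`, `ctfr.make_head_phantom`,
`ctfr.analytic_sinogram`, `ctfr.add_transmission_noise`,
`ctfr.reconstruct`).

Geometry presets: `xcat_sparse` (120 views/360°, 672 bins, 1040 mm
source–detector), `xcat_dense` (1160-view reference orbit),
`micro_sparse` / `micro_dense` (225/450 views, 4000 bins over a
50.12 mm arc) and `micro_limited` (291 views over 197.88°).

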