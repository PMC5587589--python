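# Methods

This note records the model, the numerical choices and the reasoning
behind the places where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Imaging model and geometry

The object is a 2-D map of linear attenuation coefficients μ (mm⁻¹) on
a square pixel grid centred on the rotation axis. A point X-ray source
and a detector rotate around it; the detector is curved-equiangular by
default (bins equally spaced in fan angle on an arc centred at the
source), with a flat equispaced option. Measurements are
log-transformed line integrals, so the forward model is linear,
`y = Gμ`, with `G` built by Siddon-style ray tracing: each matrix entry
is the exact intersection length (mm) of one ray with one pixel, one
ray per detector bin. The back projector scatters with the identical
weights, making the pair an exact matrix transpose. This matters twice:
the exact line-search step `τⁿ` is only optimal if the `Gᵀ` used in the
gradient really is the transpose of the `G` used in the cost, and the
adjoint identity `⟨Gx, y⟩ = ⟨x, Gᵀy⟩` becomes a machine-precision test
(≤ 1e-10 relative, verified on full-orbit and 197.88° geometries)
rather than a loose consistency check.

Conventions (the scan protocols do not fix them, so they are declared
here): 0-based indices with pixel (0,0) top-left; view angle 0 puts the
source on +x; angles increase counter-clockwise; view angles are
`k·range/n_views` so a full orbit never repeats its first view; the
default grid inscribes the fan's field of view (256² for the head
protocols, 512² for micro-CT, where the bin count identifies the
protocol family).

Preset geometries carry the protocol numbers exactly: 120 (sparse) or
1160 (dense reference) views over 360° with 672 bins, 1040 mm
source–detector and 570 mm centre–detector for the head protocol;
225/450 views over 360° or 291 views over 197.88° with 4000 bins on a
50.12 mm arc, 121 mm object–source and 165 mm object–detector for the
micro-CT protocols. The head protocol leaves the detector extent open;
it is chosen so the fan inscribes a 500 mm field of view, a standard
body FOV for a 672-bin scanner, and recorded in the preset.

## Filtered back-projection

Standard direct fan-beam inversion for the curved detector: pre-weight
by `D·cos γ`, convolve each view with the band-limited ramp including
the `(γ/sin γ)²` equiangular modification, back-project with `1/L²`
distance weighting and the angular increment as quadrature weight. The
flat-detector variant rescales to a virtual detector through the
rotation axis. A Hamming-windowed ramp at full cutoff is the default
(the protocols name no filter; the window suppresses the noise
amplification of the pure ramp), with plain ram-lak selectable for
oracle work. Limited-angle data are reconstructed with the same formula
over the available range, deliberately without Parker weighting or
missing-wedge compensation: FBP here is the intentionally naive
baseline whose degradation the iterative method is measured against.

## PWLS-TV update

The data term is `½(Gμ−y)ᵀΣ⁻¹(Gμ−y)` with `Σ` the diagonal of per-ray
variances; its gradient is `H = GᵀΣ⁻¹(Gμⁿ−y)` and the exact step along
`−H` is `τⁿ = HᵀH/(GH)ᵀΣ⁻¹(GH)`. A vanishing gradient or a denominator
below 1e-30 flags convergence and terminates cleanly. The update
descends: `μⁿ⁺¹ = μⁿ − τⁿH − β_tv ∇TV(μⁿ)`. (The update is written
here in its self-consistent descent orientation; with the residual
`y − Gμⁿ` the same expression would ascend the quadratic.)

The smoothed TV sums `√(Δv² + Δh² + α)` over all pixels whose upper
and left neighbours exist (α = 1e-8 keeps it differentiable; a Neumann
boundary variant that zero-pads the missing differences is selectable).
Its gradient is the exact analytic derivative — each pixel appears in
up to three root terms — validated against central finite differences.

**TV step scaling.** The open design question was how β = e⁻² couples
to the TV gradient. `∇TV` entries are dimensionless ratios of order 1
at edges, while attenuation images live at ~0.02 mm⁻¹, so the literal
move `β·∇TV` (available as `tv_step_mode="absolute"`) is an order of
magnitude larger than the entire image: measured on the noise-free
120-view phantom it drives PWLS-TV to an RMSE ~80× *worse* than FBP,
i.e. the literal coupling cannot produce the behaviour the method is
defined by. The default therefore follows the established
steepest-descent-TV practice (the ASD-POCS family) of scaling the TV
direction relative to the data step,
`β_tv = β·‖τⁿH‖/‖∇TV‖`, which makes β the dimensionless fraction of
the data move spent on smoothing — e⁻² ≈ 13.5% — and is invariant to
the image's physical scale and to rescaling Σ. With this coupling the
expected ordering (PWLS-TV better than FBP, PWLS-TV-FR better still)
holds in every tested scenario. No non-negativity clamp is applied in
this update; clamping belongs to the FR step.

Stopping: fixed iteration budget (default 100) or relative image
change below 1e-6, whichever first.

## Feature refinement

After each PWLS-TV update, the fresh iterate `μⁿ⁺¹` is degraded by a
normalized Gaussian kernel (3×3, σ = 1 px by default — the same scale
as the statistics patch; both configurable) and per-pixel patch
statistics of the pair are collected over 3×3 neighbourhoods with
symmetric padding: means with 1/N, standard deviations σ_p, σ_q and
covariance σ_qp with the unbiased 1/(N−1) form. The descriptor
`f_t = 1 − |(2σ_qp + C)/(σ_p² + σ_q² + C)|` is provably in [0, 1] by
Cauchy–Schwarz and the AM–GM inequality; the implementation clips the
covariance to the Cauchy–Schwarz bound to absorb floating-point
cancellation, which also makes the bound exact in the presence of
rounding. C = 1.25e-5 sits at the scale of squared attenuation
contrasts (~0.005² = 2.5e-5), so it stabilises truly flat regions
without masking real structure. The same constant appears in numerator
and denominator exactly as the descriptor is defined; no SSIM-style
split into separate constants is attempted. `f_t` is zero for constant
images and under identity degradation, and concentrates at edges —
both are tested properties.

The refinement blends the previous iterate back where structure was
detected, `μ_new = P[μⁿ⁺¹ + f_t⊗(μⁿ − μⁿ⁺¹)]`, and the non-negativity
operator P zeroes negative pixels. The blend is computed in a form
exact at the endpoints f_t = 0 and 1 and at zero residual. The
descriptor is always computed from the freshly updated iterate; the
blend source is the previous one.

## Simulator

Phantoms are additive ellipse compositions — an outer high-attenuation
shell (0.019 mm⁻¹, bone-like), brain-like interior (~0.0105 mm⁻¹),
ventricles and several small low-contrast insets, eight ellipses in the
default head, values spanning [0, 0.019] mm⁻¹. A mirror-asymmetric
variant exists because a symmetric object would understate
limited-angle anisotropy. Ellipses give closed-form fan-beam line
integrals (quadratic ray–ellipse intersection), so the simulator is
simultaneously the noise-free ground truth and an independent oracle
for the discrete projector (they agree to ~0.5% relative RMS at 256²;
the residual is pure discretization). Rasterization anti-aliases with
4×4 sub-pixel sampling and is bit-deterministic.

Noise follows the Poisson transmission model: counts
`N ~ Poisson(I₀·e^{−y})` floored at one electronic count, noisy
integral `ln(I₀/N)`, and the delta-method variance `e^{y}/I₀`
(evaluated at the measured y, floored at 1e-12) as the Σ diagonal — the
nonlinear mean–variance relationship of low-dose sinogram data in its
simplest testable form. An identity-Σ mode covers the unweighted case.
Randomness comes from a counter-based Philox generator under a single
integer seed.

What the simulator does **not** emulate: scatter, beam hardening,
detector blur and crosstalk, electronic read noise beyond the count
floor, and real anatomy. Passing tests therefore demonstrate the
correctness and relative behaviour of the algorithms under the stated
statistical model, not clinical image quality.

## Problem sizes and defaults

| Parameter | Default | Notes |
|---|---|---|
| α (TV smoothing) | 1e-8 | differentiability constant |
| β (TV weight) | e⁻² ≈ 0.1353 | fraction of data step (relative mode) |
| patch side | 3 | N = 9; balance of detection vs. cost |
| C (descriptor) | 1.25e-5 | matches squared-contrast scale |
| Gaussian kernel | 3×3, σ = 1 px | degradation for the descriptor |
| FBP filter | Hamming, cutoff 1.0 | ram-lak selectable |
| iterations | 100 (CLI), 50 (studies) | fixed budget |
| grids | 256² head / 512² micro presets | studies use 128² |

The ordering studies (tests and `scripts/acceptance.py`) run at 128²
with 50 iterations — small enough to re-run routinely on one CPU,
large enough that FBP streaks, TV patchiness and FR recovery are all
clearly expressed. The projector-consistency check runs at the full
256²/672-bin protocol resolution.

## Known limitations

- 2-D fan-beam only; no cone-beam, helical or 3-D geometries.
- One ray per bin (no detector footprint model); supersampling exists
  for oracles, not reconstruction.
- The exact line search optimizes the data term only; the TV move can
  transiently increase the total objective, which is inherent to the
  two-step scheme rather than a convergence-proof descent method.
- PSNR keeps the (Q−1) denominator of its defining formula by default,
  which differs from the common convention by ~10·log₁₀(Q/(Q−1)) dB
  (negligible at realistic Q but visible on tiny test images); the
  standard convention is a flag away.
- The noise model is per-ray independent Poisson; correlated detector
  effects and the full nonlinear mean–variance calibration of real
  scanners are out of scope.
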