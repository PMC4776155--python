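# Methods

This note records the models implemented by micskit, the parameter choices
that matter, the numerical decisions, and what the synthetic validation does
and does not establish.

## Coordinates and acquisition model

Frames are `(time, row, col)` with 0-based indices, origin top-left. The
raster fast axis is x (columns): pixel (row, col) of frame f is acquired at
`t = f·frame_interval + row·τ_l + col·τ_p`, with τ_p the pixel dwell time and
τ_l the line period. A column shift ξ therefore probes delays of order τ_p·ξ
and a row shift ψ delays of order τ_l·ψ. Metadata (pixel size δr, τ_p, τ_l,
frame interval, beam waist ω₀, axial waist ω_z) is supplied as a YAML/JSON
sidecar; proprietary microscope headers are out of scope.

Two standard geometries are built in:

* fast scan (RICS): 128×128 px, 80 nm/px, τ_p = 6.3 µs, τ_l = 1.2×128·τ_p
  (20% flyback allowance), continuous frames;
* strip scan (mICS): 256×32 px, 100 nm/px, τ_p = 1.27 µs, 49.6 ms/frame,
  1000 frames.

ω₀ and ω_z are instrument calibration constants, not fit parameters; the
defaults are 0.25 µm and 3ω₀. γ is fixed at 0.3536 (3D Gaussian volume).

## Preprocessing

**Bleaching correction** rescales each frame so both the spatial mean and
variance stay at their initial values:
`I′ = I/√(f(t)/f(0)) + f(0)(1 − √(f(t)/f(0)))`, with f(t) the frame mean.
The 1/√ factor restores shot-noise-limited variance; the additive term
restores the mean exactly. The correction is exact for the mean (tested to
1e-6 relative on analytically bleached stacks) and holds the variance of a
30%-bleached Poisson stack flat within 10%.

**Immobile-fraction removal** (mICS): subtract the per-pixel time average.
Only moving or exchanging emitters survive into the correlation.

**Temporal high-pass** (RICS): subtract a centered per-pixel moving average.
An even requested span is widened to the next odd span (10 → 11 frames) so
the average is exactly centered — a centered average cancels a linear ramp at
interior frames, which an off-center even window does not. At stack edges the
window shrinks symmetrically. The global mean is added back before
correlation so the intensity normalization is defined.

## RICS

Each frame's intensity-normalized spatial autocorrelation
`G(ξ,ψ) = ⟨I(x,y)I(x+ξ,y+ψ)⟩/⟨I⟩² − 1` is computed with zero padding
(non-periodic) and per-shift pair-count normalization — at 128 px frames,
circular FFT wrap would bias the tails materially. FFT and direct summation
agree to 1e-10 (tested). Surfaces are averaged over frames and fitted with
the raster diffusion model (README) on |ξ| ≤ 16, |ψ| ≤ 8 with the (0,0)
point excluded (shot-noise spike). Multi-start initialization
D₀ ∈ {0.1, 1, 10, 100} µm²/s guards against local minima; N₀ = γ/G(1,0);
b₀ = min(surface); ties go to smaller D. Standard errors come from the
Jacobian covariance at the optimum.

**High-pass transfer.** Subtracting a moving average is a linear temporal
filter. When frames remain correlated across the averaging span — which is
exactly the slow-D regime (at D = 1 µm²/s and 124 ms frames, the
between-frame displacement is ~6 px, well inside the fit range) — the filter
removes a wide, lag-mixed component from the measured correlation; fitting
the plain model then biases D low by up to ~85% at D = 1 µm²/s. `fit_rics`
therefore fits the model *through* the filter: the filter kernel's
autocorrelation weights, applied to the model evaluated at delays
τ + k·frame_interval. With this transfer the D ∈ {1, 3, 10, 30} µm²/s sweep
recovers medians within 25% and strictly monotone (tested, 10 seeds each).
Residual bias (−8…−19%) comes mostly from per-line trajectory sampling in
the simulator (below) and the truncated fit range.

## mICS

The lag correlation of a window is
`C(ξ,ψ;Δt) = ⟨δI(x,y,t) δI(x+ξ,y+ψ,t+Δt)⟩ / (⟨I⟩_t ⟨I⟩_{t+Δt})`,
averaged over all T−Δt ordered frame pairs and all in-bounds pixel pairs
(non-periodic, pair-count normalized; the normalization uses the *raw*
window mean intensities). Per-frame FFTs are computed once and reused across
lags. The surface is cropped to |ξ|, |ψ| ≤ 8 for 32 px windows (≈ 8× more
data points than parameters).

**Mixture fit.** Stage 1 fits the isotropic model (a₁, σ_iso, ε), seeded
from the second moments of the positive part of the surface. Stage 2 fits
the full model, seeded at the isotropic optimum plus a principal-axis
decomposition of the residual, which also guarantees SSE_full ≤ SSE_iso up
to optimizer failure (treated as retaining the isotropic model). Widths are
constrained to [0.5 px, 2×max_shift] (isotropic) and [0.5 px, max_shift]
(anisotropic axes): sub-pixel correlation structure cannot exist in
pixel-sampled data and only threads individual noise points, and a component
much wider than the fitted crop is indistinguishable from the uniform ε.
θ is reported modulo π. Standard errors come from the inverse Hessian of the
SSE at the selected optimum (H ≈ 2JᵀJ); a singular Hessian yields NaN errors
with the fit still returned.

**Model selection.** The one-sided likelihood-ratio statistic for Gaussian
residuals is Λ = n·ln(SSE_iso/SSE_full), compared against an upper χ² tail;
the anisotropic term is kept when p < 0.05. The naive df would be 6 (a₂,
µ_ξ, µ_ψ, σ_major, σ_minor, θ), but under the null a₂ = 0 the orientation,
center and widths are unidentified, which inflates the null distribution
(the classic boundary problem for mixture components). Monte Carlo
calibration on isotropic surfaces with iid noise puts the empirical null at
χ²(9); with df = 9 the test has its nominal 5% size (df = 6 would give
~18%). The package default is therefore df = 9; `select_model` takes df as
an argument. If the fitted extra component comes out centered (|µ| ≤ 0.5 px)
and circular (axis ratio < 1.2) it duplicates the isotropic component's
symmetry and carries no anisotropy evidence — occasionally the optimizer
swaps the two components' roles this way — so the isotropic model is
retained in that case.

**Classification** applies, in order: the R² gate (R² ≤ 0.1 of the selected
model ⇒ noise — such surfaces have no spatial structure), the LRT, and the
amplitude gate (a component is reported only if its amplitude exceeds 10⁻⁴).
R² is computed on the selected model.

**Derived quantities.** FWHM = 2√(2 ln 2)·σ converted to µm for display
(circle for the isotropic term, cross along θ, θ+π/2 for the anisotropic
term, line weight ∝ relative amplitude). Under free diffusion the isotropic
variance follows σ²(τ) = σ₀² + 2Dτ; `diffusion_from_lag_series` fits this
line over lags with an isotropic component (≥ 5 required) and returns
D = slope/2 with its standard error.

## Colocalization and kymographs

Shifted Pearson r is computed over the overlapping pixels only — zero
padding would bias r toward 0 — for all shifts in a (2s+1)² grid (default
s = 4), with axis profiles exposed separately. Identical overlap data
returns exactly 1. Zero-variance overlaps are reported as missing. Kymograph
extraction samples each frame by bilinear interpolation at equally spaced
arc-length positions along a polyline; at integer pixel centers the
interpolation is exact.

## Synthetic scenes

Emitters live in a 2D plane (single-plane acquisition; ω_z enters only the
RICS model) on a field extending 6ω₀ beyond each frame edge, with periodic
re-entry, so the density in view is stationary. Pixel values are
`Σ_p brightness·exp(−2d²/ω₀²)` plus Poisson counting noise and optional
Gaussian read noise; `brightness` is the expected peak count per emitter per
dwell, default 25 (single-emitter peak SNR ≈ 5). Default densities: 60
emitters on the fast-scan field (sparse, strong fluctuations), 900 on the
strip field (≈ 5 /µm²).

Motion modes: free diffusion (Gaussian steps, per-axis variance 2DΔt);
bound (static, or exponential residence with relocation — see below);
diffusion in a reflecting box whose +x wall oscillates as x₀ + A·sin(2πt/P);
a rigid filament of emitters translated sinusoidally perpendicular to its
axis; directed drift v·Δt plus optional diffusion.

`render_raster` samples trajectories per scan line: all pixels of a line see
the line-start positions. Within-line displacement at D ≤ 30 µm²/s over
µs dwells is far below the pixel size, so this is adequate for RICS — at
D = 30 it contributes a small down-bias (≈ −14%, within the validated 25%
band). `render_frames` samples whole frames at their start time, valid when
motion per frame ≪ PSF (the mICS regime); for static scenes the two
renderers agree exactly (tested).

**Binding phenotype.** A fully static emitter is removed *exactly* by
time-average subtraction and contributes nothing to any lag correlation — a
binding plateau cannot arise from permanently immobile emitters. Binding
scenes therefore use a finite residence time (default 20 s: long against the
1 s maximum lag, short against the 49.6 s acquisition), after which an
emitter rebinds at a new uniform site. This yields the lag-stable amplitude
plateau (ratio ≈ 0.9 over τ = 1…20) that distinguishes binding from
diffusion (ratio ≈ 0.2).

## Translocation Monte Carlo

500 particles start uniform on [0, 50] µm and step every 1 s for 1800 s.
Each step independently draws one of three modes — diffusion (Normal(0,
√(2DΔt)); written with the √Δt factor so the simulator is dimensionally
correct for any Δt), standing still, or dynein transport toward the nucleus
(magnitude Normal(vΔt, vΔt/2) truncated at 0 to enforce unidirectionality).
The membrane (x = 50) reflects; at the envelope (x ≤ 0) the particle is
absorbed with probability p(t) — constant p₀ or the linear schedule
min(1, p₀ + k·t) — and otherwise reflected. Mode probabilities default to
(0.5, 0.4, 0.1); these are placeholders, not measured values. Reflection (as
opposed to waiting at the envelope) and per-step independent mode redraws
are the simplest consistent readings of the model; both are config-visible
behaviours.

Validated properties: sealed envelope ⇒ zero uptake; pure drift v from a
uniform start with p₀ = 1 ⇒ mean first-passage time L/2v = 25 s (±10%);
diffusion-only translocation keeps the surviving cytoplasmic distribution
near-uniform (KS < 0.15 while > 30% remains) whereas transport-only piles
particles into the envelope-adjacent bin; constant permeability gives
early-rapid depletion (early/late slope ratio > 1) while a linearly
increasing permeability delays it (ratio < 1). The depletion-scale
permeabilities used in validation (p₀ = 0.01–0.02, or slope 1.1e-5 /s with
p₀ = 0) are chosen so that roughly half the population translocates within
20–30 minutes, the physiological timescale for ligand-induced nuclear entry.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
RICS recovery uses 100-frame 128×128 stacks (10 and 5 seeds per D
respectively); mICS phenotypes use 1000-frame 256×32 stacks (2–5 seeds per
phenotype, 6–10 filament replicates, one to three 32-px windows); the LRT
calibration uses 200 generated surfaces; the Monte Carlo runs use the full
500×1800 configuration. These sizes give stable medians while keeping a full
run to a few minutes.

## Known limitations

* **The LRT is anti-conservative on real correlation surfaces.** The χ²(9)
  calibration holds for iid surface noise. Estimated lag surfaces violate
  that: all shifts share the same underlying speckle data, so surface noise
  is spatially correlated over many pixels, and with 1000-frame stacks the
  test then detects seed-specific lumps as "significant" anisotropy on truly
  isotropic scenes — typically a broad component with a₂ ≈ 2–30% of a₁,
  while the isotropic parameters (σ², amplitude, recovered D) remain
  accurate. Interpret weak accepted anisotropic components cautiously;
  the amplitude and R² gates do not screen them out.
* Per-line trajectory sampling slightly biases fast-D RICS (above).
* The simulator has no axial dimension, no blinking/triplet photophysics and
  no bleaching (bleach correction is validated on analytically bleached
  stacks instead); real cytoplasm adds heterogeneity none of the synthetic
  scenes emulate. Passing tests establish correctness of the estimators on
  their own model classes, not performance on arbitrary cellular data.
* The translocation model is 1D with a single absorbing species; geometry,
  ligand binding kinetics and nuclear export are out of scope.
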