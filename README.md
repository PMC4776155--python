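# micskit

Image correlation spectroscopy for live-cell fluorescence fluctuation data:
**mICS** (multimodal ICS) lag analysis, **RICS** diffusion fitting,
pixel-shift Pearson colocalization, kymograph extraction, a raster-scanned
confocal simulator with ground-truth motion, and a 1D Monte Carlo model of
nucleocytoplasmic translocation.

## The problem

A fluorescent protein in a cell rarely moves in just one way. A transcription
factor such as the androgen receptor diffuses freely, binds transiently to
structures, and may ride motor proteins along the cytoskeleton — all at once,
in different subpopulations. Single-particle tracking fails at cellular
expression levels, and classical FCS reports only fast diffusion at a point.
Correlation analysis of fluctuation *images* covers the gap:

* **RICS** exploits the raster scanner's timing — pixels along the fast axis
  are microseconds apart, lines milliseconds apart — so the shape of the
  within-frame spatial autocorrelation encodes diffusion at µm²/s rates.
  The correlation is fitted with
  `G_RICS(ξ, ψ) = S(ξ, ψ) · G(ξ, ψ) + b`, where
  `G(ξ,ψ) = (γ/N) (1 + 4D(τ_p|ξ| + τ_l|ψ|)/ω₀²)⁻¹ (1 + 4D(τ_p|ξ| + τ_l|ψ|)/ω_z²)^(−1/2)`
  carries the molecular dynamics and
  `S(ξ,ψ) = exp(−δr²(ξ² + ψ²)/ω₀² / (1 + 4D(τ_p|ξ| + τ_l|ψ|)/ω₀²))`
  the scanning optics. Free parameters: diffusion coefficient `D`, mean
  occupancy `N`, offset `b`.

* **mICS** targets the slow end (binding, confinement, transport ≲ 1 µm²/s).
  After photobleaching correction and removal of the time-averaged image,
  the spatiotemporal correlation `C(ξ, ψ; Δt)` is computed in sliding 32×32
  pixel windows for frame lags τ = 1…20 and each lag surface is fitted with
  a two-component Gaussian mixture

  `C(ξ,ψ) = a₁ exp(−(ξ²+ψ²)/2σ_iso²) + a₂ exp(−½ (r−µ)ᵀ Σ⁻¹ (r−µ)) + ε`

  — a centered isotropic term (diffusion or binding) plus an offset, rotated
  anisotropic term (confined or directed motion along a structure). The
  anisotropic term is kept only when a one-sided likelihood-ratio test
  rejects the isotropic model (p < 0.05); fits with R² ≤ 0.1 are noise, and
  components are reported only above an amplitude of 10⁻⁴. The lag behaviour
  separates phenotypes: binding gives a lag-stable `a₁`, diffusion a decaying
  `a₁` with `σ²(τ) = σ₀² + 2Dτ` (iMSD), and transport a lag-shifting center µ.

The package also ships the synthetic ground truth needed to validate all of
this (point emitters with Gaussian PSF, Poisson noise, and diffusing / bound /
confined-oscillating / filament / directed motion, rendered with or without
raster timing), plus the translocation Monte Carlo: 500 particles on a 50 µm
cytoplasm choosing diffusion / stalling / dynein transport each second, with
a nuclear envelope acting as a one-way sink of given permeability.

## Worked example

```python
from micskit import (MotionModel, standard_rics_scene, standard_mics_scene,
                     bleach_correct, remove_time_average, fit_mixture, Window)
from micskit.rics import rics_preprocess, rics_average, fit_rics
from micskit.mics import stics_correlate_multi, diffusion_from_lag_series
from micskit.synth_imaging import mics_acquisition

# RICS: simulate a D = 10 um^2/s scene at 128x128 px / 80 nm / 6.3 us dwell
stack = standard_rics_scene(MotionModel(mode="diffusion", D=10.0), seed=1)
fit = fit_rics(rics_average(rics_preprocess(stack)))
print(f"RICS: D = {fit.D:.2f} +/- {fit.stderr['D']:.2f} um^2/s")

# mICS: slow diffusion at the 256x32 px / 49.6 ms strip geometry
stack = standard_mics_scene(MotionModel(mode="diffusion", D=0.1), seed=1)
fluct = remove_time_average(bleach_correct(stack))
maps = stics_correlate_multi(fluct, Window((0, 112), 32), range(1, 21), max_shift=8)
fits = [fit_mixture(m) for m in maps]
D, se = diffusion_from_lag_series(fits, mics_acquisition())
print(f"iMSD slope -> D = {D:.3f} +/- {se:.3f} um^2/s")
```

prints

```
RICS: D = 9.17 +/- 0.07 um^2/s
iMSD slope -> D = 0.100 +/- 0.002 um^2/s
```

i.e. the fast-scan analysis recovers the 10 µm²/s ground truth from the
raster timing, and the lag analysis recovers the 100-fold slower motion from
the growth of the correlation width with lag (the isotropic amplitude decays
from 0.71 at lag 1 to 0.13 at lag 20 — the diffusive phenotype; a binding
scene keeps it flat).

A command-line interface wraps the same operations:

```sh
micskit simulate stack --config scene.yaml --out stack.tif
micskit rics  --stack stack.tif --meta stack.tif.meta.yaml --out fit.csv
micskit mics  --stack stack.tif --meta stack.tif.meta.yaml --out map.csv --overlay map.png
micskit coloc --red r.tif --green g.tif --meta meta.yaml --out rp.csv
micskit kymo  --stack stack.tif --meta meta.yaml --path path.csv --out kymo.csv
micskit simulate translocation --config mc.yaml --out series.csv
```

Every command writes a JSON manifest (inputs, parameters, seed) next to its
output, so results are reproducible from the manifest alone.

## Layout

| module | contents |
| --- | --- |
| `micskit.stack_io` | TIFF stacks, acquisition metadata, analysis windows |
| `micskit.preprocess` | bleaching correction, time-average / moving-average removal |
| `micskit.rics` | frame autocorrelation, raster diffusion model, D fitting |
| `micskit.mics` | lag correlation, Gaussian-mixture fits, model selection, kinetic maps |
| `micskit.coloc_kymo` | pixel-shift Pearson colocalization, kymographs |
| `micskit.synth_imaging` | motion models, PSF rendering, standard scene geometries |
| `micskit.translocation_mc` | 1D nuclear-translocation Monte Carlo |
| `micskit.cli` | `micskit` command-line interface |

See `docs/methods.md` for the models, parameter choices, numerical details
and known limitations.
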