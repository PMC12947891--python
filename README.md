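# tfpop — nucleus-wide transcription-factor population analysis

`tfpop` quantifies the coexisting populations of a nuclear transcription
factor — freely diffusing molecules, DNA-bound molecules, and slowly moving
clusters — from live confocal imaging, and maps how those populations
depend on the total nuclear concentration.  It was built around the
morphogen Dorsal (Dl) in the *Drosophila* blastoderm embryo, where the
total nuclear concentration varies naturally across nuclear cycles 10–14
and along the dorsoventral (DV) axis, but every component is generic.

The package combines three measurement modalities with a synthetic-data
layer that generates each modality's inputs with known ground truth:

* **RICS** (raster image correlation spectroscopy).  The spatial
  autocorrelation of a raster-scanned image encodes diffusion through the
  known pixel dwell time τ_p and line time τ_ℓ.  For one Brownian species
  observed through a 3D Gaussian PSF (lateral radius w0, axial radius wz):

      G(ξ, ψ) = A · (1 + 4Dτ/w0²)⁻¹ (1 + 4Dτ/wz²)^(−1/2)
                  · exp(−(ξ² + ψ²)Δr² / (w0² + 4Dτ)),     τ = τ_p ξ + τ_ℓ ψ

  with Δr the pixel size and A = γ/(V_psf·c̄), V_psf = π^{3/2} w0² wz,
  γ = 2^(−3/2); A yields the absolute concentration.  Mixtures enter as
  fraction-weighted sums of this kernel: the two-component model fits the
  slowly moving fraction φ, the three-component model (D = 0, 0.1,
  3 µm²/s) the mobile-cluster fraction φ₁.  Comparing fits at two scan
  line times (5 ms vs 17 ms) discriminates model order.
* **ccRICS**: cross-correlating the factor's channel with a histone-marker
  channel isolates the DNA-correlated (bound) fraction through the
  amplitude ratio of the cross- to red-autocorrelation.
* **SPT step-size distributions**: displacement magnitudes of tracked
  puncta follow a Rayleigh mixture,
  P(r) = Σ f_i · r/(2(D_iΔt+σ²)) · exp(−r²/(4(D_iΔt+σ²))), with
  localization variance σ²; an absorbing-slab survival factor Z_corr(Δt)
  corrects for the preferential defocalization of the faster population.
* **LLPS threshold model**: above a saturation concentration C₀ the free
  pool stays pinned at C₀ and additional material grows the condensed
  pools linearly in (c_total − C₀); fitting the x-intercept of slow pool
  vs total concentration estimates C₀ (~30 nM for Dl).

## A worked example

`examples/01_rics_concentration.py` simulates a 12-frame, 256×256
raster acquisition of a nucleus holding 30 nM free (3 µm²/s) plus 90 nM
immobile protein over a 100 ± 10 AU amplifier offset, then runs the full
chain:

```
amplifier offset: 101.0 +- 10.6 AU (detector zero-current level, removed before correlation)
ACF amplitude A = 0.0196  (fitted w0 = 0.281 um)
total nuclear concentration = 115.1 nM (generator truth 119.4 nM)
slowly moving fraction phi = 0.84 (truth 0.75)
-> free pool 18 nM, slow pool 97 nM
```

The fitted amplitude converts to 115 nM against a 119 nM ground truth;
the slowly moving fraction from a single 12-frame field carries the
speckle noise of the static bound pattern (averaging repositioned fields
tightens it — see `docs/methods.md`).  The other examples cover
line-time model discrimination (`02`), defocalization-corrected step-size
mixtures (`03`), the two-color bound fraction (`04`), and the DV threshold
map (`05`); each prints the recovered values next to the generator truth.

A thin CLI mirrors the library for shell use:

```bash
rics simulate --n-pixels 256 --n-frames 12 --out sim_out
rics fit --stack sim_out/stack.tif --model 2c --out results.csv
rics ssd --traj tracks.csv --dt 0.09 --k 2 --correct --out fit.json
rics dosemap --records records.csv --mode dv --out fits.json
```

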