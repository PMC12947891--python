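# Methods

This note records the models implemented in `tfpop`, the conventions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the package's known limitations.

## Correlation model and units

Lengths are µm, times s, diffusivities µm²/s, concentrations nM
(1 nM = 0.6022 molecules/µm³).  The PSF is a 3D Gaussian with 1/e²
radii (w0, wz); defaults w0 = 0.25 µm, wz = 3·w0 = 0.75 µm.  wz is not
measurable from a 2D scan, so it is a required configuration entry
whenever absolute concentrations are wanted.

The raster ACF kernel (module docstring of `tfpop.rics`) is evaluated at
nonnegative effective lags; data ACFs are folded onto the positive
quadrant by averaging the four sign combinations before fitting.  The
fast-axis shift grid extends to ±64 pixels and the slow axis to ±32 lines
by default — beyond the PSF support for the 31.95 nm default pixel but
wide enough to resolve the slow-axis broadening of a 0.1 µm²/s species at
a 17 ms line time.

**Amplitude calibration.**  The concentration conversion uses
A = γ/(V_psf·c̄) with V_psf = π^{3/2} w0² wz and illumination factor
γ = 2^(−3/2) by default (configurable).  For a strictly ideal 3D-Gaussian
detection profile the amplitude would instead be 1/(V_psf·c̄): the γ
factor expresses that a real instrument's effective observation volume is
larger than the nominal V_psf.  The raster simulator therefore renders
its axial detection profile with radius wz/γ, emulating an instrument for
which the γ-calibrated relation holds exactly while leaving the lateral
correlation shape — and hence the fitted w0 — untouched.  Setting γ = 1
in both places recovers the ideal-Gaussian instrument.

## Data ACF estimation

Per frame, the masked estimator computes
G(ξ,ψ) = ⟨δI·δI_shifted⟩/⟨I⟩² with an FFT over the mean-subtracted,
mask-zeroed frame, normalized by the mask's own autocorrelation (the
count of valid pixel pairs per shift); shifts whose overlap falls below
25% of the mask size are dropped as NaN.  Frames are averaged uniformly
within groups (default 12, the acquisition block length).  By
construction the masked ACF of a rectangular sub-mask equals the ACF of
the cropped sub-image to machine precision, which the tests assert.

The zero-lag point carries the uncorrelated shot- and read-noise variance
and is excluded from every fit.  The background nuisance parameter B is
bounded to |B| < 10⁻³ in all fits; a fit pinned at that bound is flagged.
Masks smaller than a few thousand pixels additionally bias the ACF by
−ΣG/N_pixels (mean-estimation bias), which B can no longer absorb — the
default minimum mask size of 1000 pixels is a floor, not a comfort zone.

Fits are bounded trust-region least squares (`scipy.optimize.least_squares`,
tolerances 10⁻¹⁵, Jacobian scaling) from a single heuristic start
(A from the interpolated zero-shift value, fractions from the interval
midpoint); the models have one or two free parameters and no observed
multimodality.  w0 may vary ±20% around its configured value in the
fast-axis fit.  Fractions landing at a bound are flagged as boundary
solutions.

## Background subtraction and segmentation

The amplifier offset is estimated from the lowest-intensity mode of the
first frame's histogram (smoothed, peak-found, Gaussian-fit over ±3
half-widths) and subtracted globally; this requires some out-of-nucleus
pixels in the field.  Degenerate histograms (constant or unimodal-bright
frames) raise a flagged error.  Tissue autofluorescence measured in a
label-free control enters as the multiplicative concentration factor
(I − I₀)²/I².  Nuclear segmentation of the histone channel is a simple
per-frame pipeline (Gaussian smooth, Otsu threshold, opening, hole fill,
small-object removal) — adequate for bright nuclei on dark cytoplasm, not
a general segmenter.

## Line-time model discrimination

The replicated-ACF study evaluates the analytic two-/three-component
models, multiplies every baseline parameter independently by (1 + 0.1u)
with u uniform on [−1, 1] per replicate (a bounded jitter; the
distribution is a package choice), and adds Gaussian noise with SD equal
to 2% of that replicate's amplitude (read as 2% *of the amplitude*, the
alternative being 2% of each value).  Twenty replicates per line-time
case are fit with one free fraction each, and case-1/case-2 fitted
fractions are compared by a two-sample t-test at α = 0.05.  A matched
model/system pair gives indistinguishable fractions; a mismatched pair
differs because a 0.1 µm²/s population partially decorrelates over a
17 ms line but barely over a 5 ms line.  The slow-axis diagnostic
compares the slow-axis cut against the PSF Gaussian in the tail region
(PSF below 10% of the amplitude) and declares an excess when two
consecutive shifts exceed three noise SDs — on the mean of 20 replicate
ACFs this flags cluster-containing systems at both line times and stays
quiet for free-plus-immobile systems.

## Cross-correlation

The CCF uses the same masked estimator with the green×red numerator and
is fit by a zero-diffusion displaced Gaussian over the full signed-shift
surface (displacements break quadrant symmetry); the averaged widths are
quadratic means of the two channels' PSF radii.  The axial displacement
is unobservable in a 2D scan; its amplitude factor (≈1.02 for the
modeled instrument) is ignored by default with a toggle.  The correlated
fraction is (ŵ0²ŵz)/(w0r²wzr)·Acc/Ared, clipped to [0, 1] with a warning.
Correlated concentration is the correlated fraction times the *total*
concentration (the alternative — times the immobile concentration — is a
documented toggle); the uncorrelated pool is the slow pool minus the
correlated pool, clipped at zero with a warning when noise inverts them.

## Step-size distributions

Steps are consecutive-frame Euclidean displacements; frame gaps yield no
step; trajectories shorter than three steps are discarded.  The mixture
density uses scales s_i² = 2(D_iΔt + σ²), so an immobile particle's mean
squared step is 4σ²; the default localization variance σ² = 4.5×10⁻⁴ µm²
comes from immobilized-bead calibration, and `calibrate_localization`
fits the SNR dependence σ²(SNR) = a/SNR + b/SNR² by nonnegative least
squares.

Fitting is maximum likelihood via EM on squared steps (exponential
M-steps, floor s² ≥ 2σ² enforcing D ≥ 0), initialized from data quantiles
and from the (k−1)-component solution padded with a weak broad component —
the latter guarantees the fitted likelihood is non-decreasing in k.  An
extra component is retained only when it improves the log-likelihood by
at least the BIC penalty for its two parameters (2·ln n); otherwise the
simpler solution is reported with the surplus component at exactly zero
weight.  Without this rule, pure MLE on over-specified mixtures sometimes
splits one true component along a likelihood ridge (observed improvements
2ΔLL ≲ 10, versus ~10²–10³ for genuinely separated components), which
would misreport the model-order comparison.  Raw MLE is available with
`parsimony=False`.  Components are reported in descending diffusivity;
near-coincident scales (within 1%) are merged and flagged.

**Defocalization.**  Z_corr(Δt) is the survival probability of 1D
Brownian motion in an absorbing slab of thickness Δz over one frame
interval, averaged over a uniform start: the image-method series is
truncated at term magnitude 10⁻⁹ (cap 200 terms) and integrated by
Simpson's rule on 257 points.  It agrees with an independent
eigenfunction expansion to 10⁻⁶ and with brute-force Monte-Carlo walkers
to within their statistical error.  The slab thickness is the optical
detection range (default 0.7 µm, treating the printed "~0.7 nm" for a
63×/1.4 NA objective as a unit typo) widened by the empirical term
0.21·√(D_free·1 s); exponent and coefficient are configurable since the
printed relation is dimensionally ambiguous — the square-root reading
matches the cited correction's form.  The corrected two-component model
is fit as a plain mixture followed by the exact reweighting
F_free = w_free/(w_free + Z_corr(1 − w_free)) at the fitted fast
diffusivity; because that map is a bijection at fixed Z_corr, this *is*
the MLE of the corrected model.  The correction is intended for the short
(90 ms) frame interval; at 500 ms only slow populations remain visible
and the uncorrected fit applies.

MSD diagnostics report the time-and-ensemble average per lag, the
log-log slope over the first five lags, and the sign of the MSD/Δt slope
— slope < 1 with a negative MSD/Δt trend indicates confined subdiffusion.

## Threshold model and dose/response maps

`llps_allocate` pins the free pool at the dispersed-phase saturation C₀
(default 30 nM) and splits the excess between the two condensed pools by
a constant ratio (default 1/3 to the DNA-correlated pool, matching the
steady-state proportions of the modeled system: free 30, correlated 30,
uncorrelated 60 of 120 nM total).  Mass is conserved exactly; the output
is continuous and piecewise linear with its only kink at C₀.  The
dense-phase concentrations set phase volumes but cancel from the
measured, nucleus-averaged pools, so they are carried only as model
metadata.

Equilibrium filtering removes nuclear cycle 10 entirely and the first
2/3/4/5 time points of cycles 11–14.  DV binning uses half-open,
lower-inclusive bins of width 0.05 from the ventral midline (DV = 0) and
drops bins with fewer than two embryos; per-bin means and SEMs are taken
over embryo means.  Dose/response fits are a fourth-order Hill function
y = ymax·x⁴/(K⁴ + x⁴) (order fixed; K flagged when it falls outside the
sampled x-range) and ordinary least squares with the threshold as
−intercept/slope and a first-order-propagated standard error (covariance
term neglected).  The DV gradient fit averages intensities per embryo
over a −26 to −20 min pre-gastrulation window, averages across embryos,
and fits a ventrally centered Gaussian with baseline; collapsed or
unbounded widths and negligible amplitudes are flagged.

## Synthetic generators: what they emulate

All generators are seeded `numpy.random.Generator` consumers: identical
seeds give bit-identical outputs.

**Raster simulator.**  Brownian particles in a 3D box spanning the field
laterally (periodic, or confined to a reflecting nuclear disk) and ±3
axial detection radii vertically (reflecting).  Positions advance once
per scan line: at 3 µm²/s and a 0.53 ms line-scan the within-line rms
displacement (≤0.06 µm) is negligible against w0, which is why per-pixel
propagation is not performed.  Pixel values are Poisson photon counts
from the summed PSF weights (contributions truncated at 3·w0 laterally
and 2 axial radii — below 10⁻³ of peak), scaled by a detector gain
(default 2 AU/photon) and added to Gaussian amplifier offset
(default 100 ± 10 AU); defaults give in-nucleus SNR near 10:1 over the
offset SD, matching the modeled acquisitions.  Particle numbers are
Poisson draws at the nominal concentration and the realized values are
reported as ground truth.  Not emulated: photobleaching (the measurement
protocol repositions the field instead), detector afterpulsing or
reconstruction artifacts of array detectors, within-line motion, and 3D
image output.  A recovery test passing here therefore validates the
estimator chain, not robustness to those instrument effects.

**Trajectory simulator.**  Per-particle component assignment by weight,
3D Brownian motion, recorded lateral positions perturbed by per-axis
localization noise of variance σ².  Axial escape is continuous-time
absorption at ±Δz/2, realized with 16 substeps per frame plus a
Brownian-bridge crossing test per substep, so the first-lag survival
matches the Z_corr series within Monte-Carlo error.  Because survivors
concentrate mid-slab, steps later in a trajectory escape less than the
uniform-start model assumes — physically real, but not what the
single-interval correction describes.  The i.i.d. defocalized step
sampler (`sample_steps_defocalized`) draws one uniform-start interval per
step, thinning each component by its own survival probability: it is the
exact generative counterpart of the corrected mixture model and is the
ground-truth source for correction-recovery tests.

**DV profile generator.**  Total concentration follows a ventrally
centered Gaussian (default peak 120 nM, width 0.32 DV units — chosen so
the lateral field at DV ≈ 0.45 holds a bit under 50 nM, a ~2.5-fold
ventral-to-lateral drop); pools allocated by the threshold model; each
measured pool receives independent multiplicative lognormal noise
(default CV 0.05) and the total is recomputed as the pool sum so mass
stays conserved record by record.

## Problem sizes and replication

Concentration-recovery runs use 256×256-pixel, 12-frame fields in a
3.5 µm nuclear disk.  A DNA-bound (immobile) pattern never refreshes
within one field, leaving ~300 independent speckle cells per field and a
~7% standard deviation on a single-field amplitude; recovery measurements
therefore average four independently seeded fields (the repositioning
protocol), giving a ~3% standard error.  The analysis mask erodes the
nuclear disk by 2·w0 so pixels whose PSF neighborhood is truncated by the
confinement boundary stay out of the estimator.  Step-size recoveries use
2×10⁴–10⁵ steps; Monte-Carlo oracles for the survival factor use
10⁵–1.5×10⁶ walkers with 256 substeps and bridge crossing tests.

## Known limitations

* Molecular brightness is assumed equal across species: clusters are
  brighter than monomers, which inflates their fluctuation contribution;
  no stoichiometry correction is applied, so absolute concentrations of
  cluster-rich samples are lower bounds in the same sense as the modeled
  analysis.
* The two-channel simulator co-positions bound molecules with the marker
  exactly; chromatin-density structure, chromatic aberration beyond a
  lateral offset, and spectral bleed-through are not modeled.
* The Hill machinery is descriptive — no goodness-of-fit criterion is
  enforced, mirroring its illustrative role.
* `segment_nuclei` is a heuristic; demanding microscopy should substitute
  a dedicated segmenter and pass the mask in.
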