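"""Diffusivities and fractions from particle-tracking step sizes.

Samples single-frame displacements from the two-population mixture seen at
a 90 ms frame interval — mobile clusters (0.1 um^2/s, 34%) and DNA-bound
particles (0.01 um^2/s, 66%) — including the preferential axial escape of
the faster population from the detection slab, then fits the
defocalization-corrected two-component Rayleigh mixture by maximum
likelihood.
"""

from tfpop import fit_ssd
from tfpop.spt import effective_axial_range
from tfpop.synthetic import mixture_90ms, sample_steps_defocalized

dz = effective_axial_range(detection_range=0.7, d_free=0.1)
print(f"effective absorbing-slab thickness: {dz:.3f} um")

mixture = mixture_90ms(axial_range=dz)
steps = sample_steps_defocalized(mixture, 50_000, seed=2)

fit = fit_ssd(steps, k=2, sigma2=4.5e-4, correction=True, dz=dz)
print(f"Zcorr (survival of the faster population per frame) = {fit.zcorr:.3f}")
for d, w, w_obs in zip(fit.diffusivities, fit.weights, fit.observed_weights):
    print(f"D = {d:.3f} um^2/s: observed weight {100 * w_obs:.1f}% "
          f"-> corrected fraction {100 * w:.1f}%")
print("truth: 0.100 um^2/s at 34% and 0.010 um^2/s at 66% — the raw step"
      " weights under-count the mobile clusters because they defocalize;"
      " the correction restores the true fractions.")

# model-order check: a third component finds no support in two-population data
fit3 = fit_ssd(steps, k=3, sigma2=4.5e-4)
print(f"three-component refit: smallest weight = "
      f"{100 * fit3.weights.min():.2f}% (surplus component rejected)")
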