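# shgquant

Quantitative characterization of fibrillar collagen in tissue by
second-harmonic-generation (SHG) microscopy. The package models and analyzes
the depth-resolved SHG response of scattering tissue sections to separate
*creation attributes* of the signal — the initial forward-emitted fraction
F_SHG and the relative conversion efficiency (∝ χ⁽²⁾) — from propagation
effects governed by the bulk optical parameters (μs, μa, g, n). The
motivating application is the comparison of normal versus malignant ovarian
stroma, where collagen remodeling changes both the creation attributes and
the bulk optics, but the machinery applies to any collagenous tissue imaged
with calibrated forward/backward SHG detectors.

It is written for microscopists and tissue-optics researchers who have
paired forward/backward detector z-stacks (or depth profiles extracted from
them), polarization-analyzed image pairs, and measured bulk optical
parameters, and who want the structural quantities those data encode.

## The model

The measured forward/backward intensity ratio F/B at focal depth z is a
convolution of the initial emission split F_SHG/B_SHG = F_SHG/(1 − F_SHG)
set by fibril packing, and subsequent photon migration through the slab with
scattering coefficient μs, anisotropy g (Henyey–Greenstein phase function)
and absorption μa at the SHG wavelength. The simulator is a multilayer-style
Monte Carlo: excitation reaches the focus ballistically through the NA cone
(transmission T(z), averaged over the cone), SHG creation scales as
η_rel·T(z)², and 50,000 emitted photons per depth are walked with
exponential steps, albedo weight deposition, Henyey–Greenstein deflection
and Russian roulette. F_SHG is recovered from a measured F/B profile by grid
search (0.50–1.00, step 0.01) minimizing the summed squared residuals
against simulations; η_rel the same way from the normalized forward
attenuation. Polarization anisotropy is
β = (I∥ − I⊥)/(I∥ + 2 I⊥) ∈ [−0.5, 1], computed on ROI intensity sums.
Group comparisons are two-sided pooled t-tests, from raw values or from
(mean, SD, n) summaries.

## Worked example

Simulate the depth-resolved F/B for both tissue classes at the measured
bulk optics and creation attributes, then refit the directionality:

```
$ python analysis/02_simulate_depth_response.py
Simulated F/B versus depth (seed 0):
tissue    cancer  normal
depth_um
0.0         1.61    4.81
10.0        1.78    5.24
20.0        1.98    6.19
...
80.0        3.84   12.73

$ python analysis/03_fit_directionality.py
normal: true %forward = 93, fit = 93 +/- 1, chi2 = 0.047 (crit 15.5 at alpha=0.05, not rejected)
cancer: true %forward = 77, fit = 77 +/- 1, chi2 = 0.012 (crit 15.5 at alpha=0.05, not rejected)
```

F/B rises with depth for both tissues (less room for multiple scattering
ahead of the focus) and the normal-stroma curve lies above the malignant one
at every depth: normal tissue scatters less at the SHG wavelength
(μs = 172 vs 267 cm⁻¹) *and* emits more forward initially (93% vs 77%).
The grid-search fit recovers both programmed forward fractions exactly, and
the chi-squared statistic shows the best-fit simulation is indistinguishable
from the data at the 0.05 level.

The numbered scripts under `analysis/` walk the full study: `01` bulk-optics
statistics and spectral slopes, `02` simulations, `03` directionality fits,
`04` conversion-efficiency fits, `05` image-stack and polarization
quantification, `06` the end-to-end cohort comparison (writes
`results/full_run/`). All computation lives in `src/shgquant/`; scripts are
thin drivers.

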