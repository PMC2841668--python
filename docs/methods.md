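# Methods

## Physical model

Second-harmonic generation (SHG) in fibrillar collagen is coherent: two
excitation photons (890 nm here) convert to one photon at half the
wavelength, and the emission has a well-defined initial direction split —
a fraction F_SHG leaves the focal volume forward (+z), 1 − F_SHG backward —
set by the sub-resolution fibril diameter, packing density and regularity.
What the microscope measures at each focal depth, the forward/backward
intensity ratio F/B, convolves that creation attribute with photon
migration through the turbid section. The package's simulator separates the
two:

1. **Excitation delivery (primary filter).** The focused beam reaches depth
   z ballistically; scattered excitation light is assumed not to contribute
   to SHG because conversion requires the coherent focused field.
   Transmission is the solid-angle-weighted average of
   exp(−μt·z/cosθ) over the aperture cone θ ∈ [0, asin(NA/n)], with
   μt = μs + μa at the excitation wavelength, evaluated by 64-node
   Gauss–Legendre quadrature (error far below the 1e-4 checked in tests).
   Uniform solid-angle weighting of the cone is a modeling choice; the
   pencil-beam limit reduces to Beer–Lambert.
2. **Creation.** The emitted weight at depth z is η_rel·T(z)² — quadratic
   because two excitation photons are consumed per SHG photon. η_rel is a
   relative conversion efficiency (∝ χ⁽²⁾-derived intensity), defined
   against a reference tissue with η_rel = 1.
3. **Propagation (secondary filter).** Photons launch at the focus into a
   forward or backward cone (uniform in solid angle within the NA cone;
   Bernoulli split with probability F_SHG) and follow the standard
   multilayer Monte Carlo walk at the emission-wavelength optics: step
   s = −ln ξ/μt, weight × μs/μt per interaction, Henyey–Greenstein
   deflection with anisotropy g, Russian roulette below weight 1e-4 with
   survival probability 0.1. Boundaries are index-matched (no Fresnel
   reflection), the slab laterally infinite, and all weight crossing a face
   is tallied regardless of exit angle — the experimental F/B calibration
   integrates whole fields, so no acceptance-angle filter is applied by
   default.

Absorption is included even though it is 25–50× weaker than scattering in
the tissues of interest; it costs nothing and makes the analytic
Beer–Lambert oracle exact. Polarization is not tracked during propagation,
and no coherent field model is attempted: the creation attributes are
phenomenological scalars.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| n_photons per depth | 50,000 | — | study condition; F/B standard error ≈ 2% at the deepest point |
| depth grid | 0–80, step 10 | μm | matches the 10 μm interval of the depth-wise tests in 100 μm sections |
| NA / n | 0.8 / 1.33 | — | 40× water-immersion objective; tissue index not separately measured, water-matched |
| roulette threshold / survival | 1e-4 / 0.1 | — | standard multilayer-MC defaults |
| F_SHG grid | 0.50–1.00 step 0.01 | — | the physically meaningful sweep; grid, not gradient, because MC noise at 50k photons defeats gradient methods |
| η_rel grid | 0.5–6.0 step 0.1 | — | brackets plausible brightness ratios |
| slab thickness | 100 | μm | section thickness used for 3D imaging |

Bulk optical parameters for the two tissue classes ship as a read-only CSV
fixture (per tissue and wavelength: μs, μa, g with SDs, the printed μs′
summaries, n). μs′ is recomputed as μs(1−g) wherever a derived value is
needed; the printed μs′ column is treated as independent fixture data (it
is a per-specimen average and differs slightly from μs(1−g) of the group
means).

## Fitting

The forward fraction is fit by simulating F/B at the measured depths for
each grid value and minimizing R²(f) = Σ_z (sim_z − meas_z)², ties broken
toward the lower fraction, on the linear F/B scale. Two variance-reduction
choices matter:

* **Common random numbers.** One seed drives the whole grid, so the
  residual curve is smooth and its argmin sharp.
* **Lobe decomposition.** Propagation does not depend on the emission
  split, so the forward- and backward-launched lobes are simulated once per
  depth and every grid value's response is the exact mixture
  (f·T_ff + (1−f)·T_bf)/(f·T_fb + (1−f)·T_bb) of the lobe tallies. This is
  equivalent to simulating each grid point with shared draws and makes the
  fit cost independent of grid size.

The reported uncertainty is the half-width of the grid interval where
R² ≤ min R² + 1 SE(R²), floored at one grid step. SE(R²) is propagated by
the delta method from per-depth batch variances (10 photon batches). A
residual curve whose spread is below numerical noise is declared
unidentifiable rather than returning an arbitrary argmin.

The relative efficiency is fit the same way from the forward-attenuation
curve, with one caveat the design makes explicit: a constant multiplier
cancels exactly under per-curve self-normalization, so attenuation curves
for this fit live on a *reference scale* — every candidate curve
η·T(z)²·f_trans(z) is divided by the maximum of the η = 1 reference curve,
and the measured input must be expressed on the same scale (this is the
convention under which a 3.9× brightness ratio between tissues is defined,
measured independently on thin sections where scattering is negligible).
`self_normalize=True` reproduces the strictly self-normalized convention
and is correctly reported unidentifiable.

Goodness of fit between a best-fit simulation and data uses Pearson's
Σ(meas−sim)²/sim with dof = n_depths − 1 against the χ² critical value at
α = 0.05.

## Image quantification

F/B per optical section is the summed forward-frame intensity over the
summed backward-frame intensity (detectors assumed cross-calibrated; a
config multiplier exists); its error is the standard error of frame-wise
ratios. Sections with zero backward integral are flagged undefined, never
dropped. Attenuation is the per-section mean integrated intensity
self-normalized to the maximum section. β uses ROI intensity sums, not
per-pixel averages — robust to dark pixels — with the (I∥ − I⊥)/(I∥ + 2 I⊥)
form whose range is exactly [−0.5, 1] (1 fully ordered, 0 random, −0.5 all
perpendicular); the simple (P−Q)/(P+Q) contrast is available behind a flag.
Whole-field integration with no background subtraction is the default.

## Synthetic data

The generators emulate the study's measurement conditions with known
ground truth: two tissue classes at the fixture optics (normal n = 5,
malignant n = 3 subjects), F_SHG = 0.93/0.77, β = 0.76/0.88, η_rel = 1/3.9.
Per-subject F/B profiles are simulator output plus multiplicative Gaussian
noise with σ = 5% of the local value — a subject-variability magnitude
chosen as realistic for integrated whole-field ratios from homogeneous
tissue, set once. Detector stacks carry Poisson pixel counts (the detectors
are photon counters) over an oriented-filament texture that is purely
cosmetic: only integrated sums carry signal. Polarization pairs satisfy the
β definition exactly in their pre-noise sums.

What the synthetic data do **not** emulate: real collagen morphology
(cross-hatched vs helical fiber patterns), lateral heterogeneity within a
field, depth-dependent aberrations, detector offsets, or fixation effects.
Passing round trips therefore demonstrate that the estimators invert the
package's own forward models at realistic noise levels — not that the
models capture every property of biopsy data.

## Numerical choices and degenerate inputs

* Weight conservation (forward + backward + absorbed = launched) holds to
  well under 0.5%; roulette-lost weight is left untallied (unbiased,
  bounded by the 1e-4 threshold).
* μt = 0 media are propagated ballistically in closed form; μs = 0 with
  μa > 0 reproduces Beer–Lambert exactly in expectation.
* F/B at a depth with zero backward weight is NaN + undefined flag.
* Zero-variance t-test comparisons report p = 1 (equal means) or p = 0
  (unequal) with a degeneracy path rather than NaN.
* All simulation entry points take one seed and use a single generator per
  call; identical seeds give bit-identical outputs.

## Problem sizes

Tests and the acceptance script run the study conditions directly: 50,000
photons per depth, 9 depths, 10 independent seeds per tissue for the
recovery study (the full 10-seed, two-tissue recovery completes in ~15 s on
one CPU thanks to the lobe decomposition). Image fixtures are 64×64–128×128
frames, generated at run time, with count levels high enough that Poisson
error is small against the tested tolerances.

## Known limitations

* The exit-angle-unfiltered tally slightly overstates detected weight for
  very high-NA detection geometries; an acceptance-angle cut is a config
  knob, off by default.
* g at the emission wavelength is an effective value measured on thin
  sections; the simulator takes it at face value.
* The η_rel fit is only meaningful on the reference scale (see above);
  single-curve self-normalized attenuation cannot identify it.
* No joint fit of F_SHG and η_rel: the two observables (F/B, attenuation)
  are fit separately, matching how the measurements are made.
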