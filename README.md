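# nucmech

Single-cell quantification of nuclear state — 3D gross morphology, volume,
Poisson's ratio, apparent elastic modulus, chromatin condensation — and of
cytoskeletal organization, from ordinary 2D widefield epifluorescence
images, together with the population statistics that relate the two.

The package is aimed at mechanobiology labs that image adherent cells at
low magnification (a DAPI channel for the nucleus, FITC/TRITC channels for
cytoskeletal proteins) and want per-cell mechanical read-outs without
confocal z-stacks or force probes.

## The measurement model

In a widefield image of a uniformly stained nucleus, pixel intensity acts
as a readout of local axial thickness. For an ellipsoidal nucleus with
in-plane semi-axes *a* ≥ *b* and axial semi-axis *c*, the radial intensity
profile follows *I(r) = I₀·√(1 − r²)* outside the central plateau set by
the objective's depth of focus; fitting it yields the nuclear height
*2c = I₀/k*, with *k* the intensity-per-µm calibration factor. From the
projected moment ellipse and the integrated DAPI intensity *I_T* the
pipeline derives:

* undeformed radius *r = r̄ · (I_T/⟨I_T⟩)^{1/3}* and volume *V₀ = (4/3)πr³*
  (an isolated, undeformed nucleus is assumed spherical, with volume
  proportional to its DNA staining);
* measured volume *V = (4/3)πabc*;
* Poisson's ratio from *ΔV/V = (1 + ΔL/L)^{1−2ν} − 1*, with
  *ΔL/L = (√(ab) − r)/r* the mean in-plane stretch — *ν < 0* marks an
  auxetic nucleus;
* apparent elastic modulus *E_A = (R₀/A)·(CSA/ΔR)*, where cell spread area
  (CSA) proxies the unmeasured compressive force, *A* is the ellipsoid
  surface area (Thomsen approximation) and *ΔR = r − c*;
* chromatin condensation *CC*: the 0.75–2.5 µm band-passed DAPI image
  (difference of Gaussians) is summed in absolute value over the optically
  thick nuclear region and normalized by *I_T*; a peripheral variant uses
  the outermost 25% of the projected area.

Cytoskeletal channels are segmented with a bank of oriented ridge kernels,
giving per-cell CSK amount (median-normalized per protein), fibre
anisotropy (brightness-weighted resultant length of doubled orientation
angles) and main fibre orientation.

Population statistics include the rational height law
*h = a + b/(c + CSA)* and its bounds, power laws *[X] ∝ CSA^γ*, the
multiplicative global fit *Y = Y₀·Π_X (X/⟨X⟩)^{α_X}* with backward
elimination of non-significant exponents, a shared-exponent ANCOVA across
treatment groups, and axial circular statistics for nucleus–fibre
orientation differences.

Because no imaging data ships with the package, a first-class synthetic
generator renders ground-truth nuclei (thickness-proportional intensity,
~1.5 µm chromatin speckles) and fibre images, and draws tabular cell
populations from the multiplicative models — every estimator is tested by
parameter recovery.

## Worked example

```python
import nucmech as nm
from nucmech.synthetic import SyntheticPopulationSpec, generate_population

table, truth = generate_population(
    SyntheticPopulationSpec(n_cells=600, noise_cv=0.1, seed=1))

fit = nm.fit_rational_height(table)
print(f"h_isolated = {fit.h_isolated:.2f} um, h_min = {fit.h_min:.2f} um, "
      f"ratio = {fit.compression_ratio_pct:.1f}%")

pl = nm.fit_power_law(table, "csa", "vimentin")
print(f"gamma_V = {pl.gamma:.3f} +/- {pl.gamma_se:.3f}")

table2, _ = generate_population(SyntheticPopulationSpec(
    n_cells=600, noise_cv=0.1, amount_distribution="lognormal", seed=1))
gf = nm.global_fit(table2, "e_mod")
print("E model:", {k: round(v, 3) for k, v in gf.alpha.items()},
      "eliminated:", gf.eliminated, f"E0 = {gf.y0:.2f}")
```

prints

```
h_isolated = 13.06 um, h_min = 5.74 um, ratio = 44.0%
gamma_V = 0.763 +/- 0.004
E model: {'myosin': 0.176, 'tubulin': 0.238, 'vimentin': 0.454} eliminated: ('actin',) E0 = 58.37
```

The first line is the rational height law refitted to a noisy synthetic
population generated with bounds 12.9 µm (isolated nuclei) and 5.7 µm
(compressibility limit): spreading compresses nuclei to ~44% of their
isolated height. The second line recovers the generative vimentin scaling
exponent (0.76). The third line shows the backward-elimination global fit
of the apparent elastic modulus recovering its generative exponents
(0.192/0.225/0.443) and prefactor (58.39) while correctly dropping actin,
which the generative model does not contain.

A thin CLI covers the same ground for shell use: `nucmech generate`
(synthetic fixtures), `nucmech process` (TIFFs → per-cell CSV),
`nucmech fit` (CSV → fit reports), `nucmech all`.

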