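# Methods

This note documents the models implemented in `nucmech`, the assumptions
behind them, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate.

## Imaging model and nuclear morphology

The pipeline treats a widefield DAPI image of a thick, uniformly stained
nucleus as a thickness map: pixel intensity = background + k·t(x, y), with
t the local axial thickness and k a calibration factor in fluorescence
units per µm. The nucleus is modelled as a triaxial ellipsoid, so
t(x, y) = 2c·√(1 − (x′/a)² − (y′/b)²) in the frame of the in-plane axes.

Segmentation is an Otsu threshold on a median-filtered image for
*detection*, followed by a boundary *refinement* down to
background + max(3σ_bg, 2% of the peak range). The refinement exists
because the projected intensity of an ellipsoid tapers continuously to
background at the rim; a plain Otsu cut sits far up the flank and truncates
the projection by >10% in area. With refinement, projected area and the
moment-ellipse semi-axes are recovered to <1% on noise-free renders.

The radial profile uses a **normalized elliptical radius** from the
moment-equivalent ellipse of the mask (nuclei are elongated; circular
annuli would mix radii). Intensities are background-subtracted, binned
into 50 equal-width radial bins, and the height is obtained from a
least-squares fit of I(r) = I₀·√(1 − (r/R)²) over the bins outside the
central plateau, with height = I₀/k. The plateau (bins within 5% of the
profile maximum) is excluded when the plateau intensity corresponds to a
thickness above the depth of focus; otherwise the nucleus never saturates
the focal depth and all bins are used. R is left free (bounds 0.3–3) so
the fit tolerates small segmentation-scale errors.

Orientation convention: axial angles in degrees, period 180°, measured
counter-clockwise from the image x-axis with y pointing up; every
comparison between orientations goes through doubled-angle circular
arithmetic. A nucleus with in-plane aspect ratio within 0.1% of 1 has no
defined orientation; it is reported as 0° with a degenerate flag.

## Mechanics

An isolated, undeformed nucleus is assumed spherical with volume
proportional to integrated DAPI intensity I_T, anchored by the population
constant r̄ (default 12.9 µm) at the population median I_T:
r = r̄·(I_T/⟨I_T⟩)^{1/3}. Two strain measures then enter the Poisson-ratio
inversion ν = ½·(1 − ln(1+ΔV/V)/ln(1+ΔL/L)):

* ΔV/V = (V − V₀)/V₀ with V = (4/3)πabc and V₀ = (4/3)πr³;
* ΔL/L = (√(ab) − r)/r, the *mean in-plane stretch*. The geometric mean
  treats a and b symmetrically and matches the in-plane direction of
  cytoskeletal tension; it is a configurable design choice, as is
  ΔR = r − c (axial flattening) in the apparent modulus
  E_A = (r/A)·(CSA/ΔR). The inversion is withheld (and the row flagged)
  when |ln(1+ΔL/L)| ≤ 10⁻⁶, and E_A is withheld when r ≤ c (nucleus not
  axially compressed).

The ellipsoid surface area uses the Thomsen approximation with p = 1.6075,
verified against numerical quadrature to <1.1% for aspect ratios up to 5.
E_A carries arbitrary units by construction, because cell spread area
stands in for the unmeasured compressive force; only relative comparisons
and fitted exponents are meaningful.

The constant r̄ = 12.9 µm sets the overall scale of r, V₀, ν and E_A but
cancels from all fitted exponents; it is configurable.

## Chromatin condensation

Condensed chromatin appears as ~1.5 µm bright speckles and equally sized
dim spots. The band-pass passing 0.75–2.5 µm features is a difference of
Gaussians with FWHM-mapped sigmas (σ = cut/(2√(2 ln 2))), applied as a
normalized convolution inside the mask so the mask edge does not ring into
the score. CC sums |band-passed intensity| over pixels whose modelled
ellipsoid thickness exceeds the depth of focus (default 3 µm, a config
parameter for a 20×/0.5 NA setup) and divides by I_T — total, not mean,
nuclear fluorescence (configurable; the two differ by a constant area
factor per nucleus). The peripheral score uses the outermost 25% of the
projected area (by iterative erosion, exact to one erosion step) with the
same I_T denominator, and no thickness gate, since the rim is thin by
construction.

Known baseline: even a speckle-free ellipsoid has non-zero CC (~0.04 under
the default synthetic geometry) because the smooth intensity dome itself
has curvature in the pass band. The score is therefore an *ordinal*
measure — monotone in speckle amplitude and count, as the tests assert —
rather than a zero-based one.

## Cytoskeleton

Fibre segmentation runs in three steps: (1) ridge enhancement as the
maximum response over a bank of zero-mean elongated Gaussian kernels
(length 3 µm, width 0.6 µm, 12 orientations 15° apart — sized for stress
fibres at 20× magnification); (2) refinement, dropping components shorter
than 2 µm or with in-plane aspect ratio < 2; (3) subtraction of a
large-kernel (10 µm) median background from the fibre brightness.
Zero-mean kernels make flat and linearly varying backgrounds respond with
exactly zero. The per-pixel orientation is the argmax over the kernel
bank, so orientations are quantized to 15°; per-cell descriptors average
over many pixels and recover orientation to ~1–2°.

Anisotropy and main orientation are brightness-weighted doubled-angle
statistics: anisotropy = |Σ w·e^{2iθ}|/Σ w, orientation = arg(·)/2.
Weighting by brightness keeps dim noise pixels from dominating; it is a
design choice, and any monotone equivalent preserves the downstream
binned-slope analyses. CSK amounts are median-normalized per protein so
channels with different dye brightness share a scale.

Cell segmentation thresholds a lightly smoothed image at
border-background + 2σ, with σ floored at 1% of the dynamic range so
noise-free synthetic frames threshold sensibly.

## Population statistics

All multiplicative fits run as OLS in log space; p-values are standard
linear-model t-tests with no multiple-testing correction.

* **Rational height law** h = a + b/(c + CSA), nonlinear least squares
  with multi-start in c (10², 10³, 10⁴ µm²); bounds h(0) = a + b/c and
  h(∞) = a reported with delta-method standard errors.
* **Global fit** Y = Y₀·Π_X (X/⟨X⟩)^{α_X}: predictors divided by their
  population median so the intercept back-transforms directly to Y₀.
  Backward elimination removes one term per iteration — the one with the
  largest p ≥ 0.05 — and refits; removing one at a time (rather than all
  at once) keeps the procedure well-defined under correlated predictors.
  Coefficients below 10⁻¹⁰ are treated as non-significant regardless of
  their nominal p, which handles exact zero-residual fits. Eliminating
  everything is a valid outcome (Y₀ is then the geometric mean of the
  response). A condition number above 10⁶ on the log-design aborts the fit
  naming the most correlated pair. Poisson's ratio is negative, so that
  response enters as ln(−ν) with the sign restored on Y₀; rows with the
  minority sign are excluded and counted.
* **Shared-exponent ANCOVA**: one slope, per-group intercepts in log
  space, with the pooled per-group-slope residual variance reported as a
  pooling diagnostic. The absolute intercepts depend on the pooled-median
  reference of the covariate; intercept *ratios* between groups are the
  well-identified quantities.
* **Binned summaries**: equal-count bins (≥50 cells by default), geometric
  mean with Q1–Q3 for positive quantities, arithmetic mean ± SD for
  Poisson's ratio.
* **Axial circular statistics**: mean and SD on doubled angles,
  SD = √(−2 ln R)/2 converted to degrees.

## Synthetic data: what it emulates, and what it does not

The generator is the package's ground-truth source. Rendered nuclei have
strictly thickness-proportional intensity (no optical PSF by default; a
Gaussian blur is available) so the imaging model is analytic; speckles are
isotropic Gaussian blobs, FWHM 1.5 µm, half bright and half dim, with
amplitude a fraction of the local intensity, placed uniformly inside the
projected ellipse. Fibre images are anti-aliased line segments (~2–3 px
wide) with axial von Mises orientations inside an elliptical cell body
carrying a diffuse cytoplasmic level.

Tabular populations draw CSA log-uniformly on 843–18,000 µm² (log-uniform
so log–log fits have balanced leverage; the bounds are the observed
spread-area range of the reference experiments, median ≈ 5,200 µm²).
Cytoskeletal amounts follow either [X] = CSA^γ·ε (γ_A = 0.56, γ_M = 0.37,
γ_T = 1.05, γ_V = 0.76) or independent log-normals with log-sd 0.5 — the
latter used for global-fit recovery experiments, where CSA-coupled amounts
with zero noise would be exactly collinear. Nuclear responses follow the
multiplicative models with their published coefficients; all noise ε is
i.i.d. log-normal with unit median and CV 0.1 by default. The measurement
noise level of the real assay is unknown; 10% is a realistic single-cell
imaging figure and is the documented study condition for all recovery
experiments. Heights follow the rational law with the same multiplicative
noise. The linear CC–volume population uses Gaussian noise with sd 0.02,
which gives the slope fit a standard error of ≈0.003, the scale reported
for that regression.

Passing recovery tests on these populations shows that the estimators are
correct and unbiased under the stated noise model. It does *not* show
robustness to what real data add: optical blur and shading, touching
cells, mitotic or damaged nuclei (handled only by manual flags),
non-ellipsoidal nuclear shapes, chromatin texture beyond discrete
speckles, or fibre curvature.

## Numerical choices and problem sizes

Recovery experiments use 600 cells (the scale of the reference data set)
and run in seconds. Null calibrations use 20–100 seeds. Under the global
null, backward elimination removes *all* terms in ~88% of simulations (the
sequential procedure retains one spuriously significant term in the rest);
the per-term elimination rate of a single null predictor is ~95%. Tests
assert these simulated levels, not nominal ones.

## Known limitations

* The height estimate assumes uniform staining; chromatin texture biases
  I(r) slightly (mitigated by binning).
* The plateau rule (5% of profile maximum) is a reconstruction; the
  original calibration procedure against confocal stacks is out of scope,
  so calibration_k is a config input.
* ΔL and ΔR have alternative defensible definitions (e.g. major-axis
  stretch); both are isolated behind single functions and configurable.
* E_A is not an absolute modulus; cross-study comparison requires a force
  calibration this package does not attempt.
* The fibre segmenter targets straight, well-separated stress fibres;
  dense meshworks will under-segment and anisotropy will saturate low.
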