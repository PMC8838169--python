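# Methods

## Signal model and sign conventions

A B-scan is a complex matrix a(m, j) with axial index m sampled at the
optical pitch in air (dz_air µm/px) and lateral index j (dx µm/px). The
interframe phase variation of two frames is Φ = arg{a₂·a₁*} ∈ (−π, π]; the
corresponding axial displacement is U = λ₀Φ/(4πn) (positive U = motion away
from the surface, i.e. dilatation below a fixed surface), unambiguous up to
integer multiples of λ₀/(2n).

Strain is the axial derivative of U. Working in optical (in-air) depth,
ε = (λ₀/4π)·∂Φ/∂z_air; since physical in-tissue depth is z_air/n, the same
number equals (λ₀/4πn)·∂Φ/∂z_phys — strain is independent of the refractive
index, while displacement and depth scales are not. Each strain map records
its `depth_convention` tag to keep this bookkeeping auditable. Depth axes of
profiles are physical µm below the detected surface (`dz_phys = dz_air/n`);
n must be supplied as explicit container metadata (default in code: 1.4, a
typical value for hydrated collagenous tissue).

## The vector strain estimator

Per interframe product b = a₂·a₁*:

1. complex pre-averaging of b over a small window (default 3 px axial ×
   (lateral processing window + 2) px lateral). Lateral speckle cells in
   the simulator are independent, so lateral averaging is what suppresses
   amplitude nulls and fluctuation noise without flattening axial phase
   ramps;
2. axial lag products d(m, j) = b̃(m+lag, j)·b̃*(m, j), default lag 1 px;
3. complex sum of d over the processing window (default 100×100 µm,
   converted to odd pixel counts ≥ 3). Amplitude weighting is intrinsic —
   no normalization of |d| — with optional percentile clipping of |d| to
   limit specular dominance (off by default);
4. slope = arg(Σd)/lag; ε from the conversion above.

**Attenuation bias and re-referencing.** The expectation of a lag product
over speckle is E[d] = |μ|²·e^{iΔΦ} + R², where μ is the coherent
interframe mean and R the (real, non-negative) axial autocorrelation of the
speckle field at the lag. The real R² term drags arg(E[d]) toward zero: a
single-pass lag-1 estimator underestimates the slope by the factor
1/(1 + R²/|μ|²) (tens of percent when the axial PSF spans ~2 px, as here).
Pre-averaging reduces the fluctuation term ∝ 1/N_effective; one
**re-referencing iteration** (default on) removes the rest: the integrated
first-pass slope is subtracted from b, and the now nearly flat residual is
re-estimated with a long axial pre-average (half the window) and a lag of
8 px — safe from wrap because the residual is small, and free of
attenuation because the lag exceeds the pre-average correlation length.
The re-reference pass must not pre-average laterally: the de-ramp phase
carries an arbitrary random constant per column (the integral of first-pass
noise), which cancels in axial lag products but destroys a lateral complex
mean. Its lateral averaging therefore happens on the lag products.

Validity masks exclude the window/pre-average/lag margins and all-zero
windows; masked pixels are zeroed, never NaN. On a noise-free linear phase
ramp with |slope·lag| < π the estimator is exact to machine precision; on
simulated speckle the residual systematic error is ≲0.5% (part of which is
the exact Eulerian factor ε/(1+ε) of fixed-grid measurement), which is why
the estimator-bias test bounds the mean over 100 realizations at 0.5%
relative rather than at a standard-error multiple — with enough
realizations any fixed systematic exceeds 2·SE, so that formulation would
test nothing about the estimator.

**Least-squares oracle.** The cross-check estimator extracts the phase
(after the same pre-averaging), unwraps it per column along depth, and fits
the windowed least-squares slope of Φ(m). It matches the vector estimator
within 1% on 30 dB-SNR speckle. Without unwrapping it fails on ramps
steeper than π per lag — post-unwrap jumps > π mark the affected windows
invalid — which is precisely the failure mode the vector method avoids.

## Accumulation frames

Cumulative strain is by default the Eulerian (fixed pixel grid) running sum
of interframe strains — the direct summation convention. At cumulative
strains beyond ~0.1 the material under a fixed pixel changes during the
series, and the Eulerian sum of engineering-strain increments converges to
the logarithmic strain ln(1+ε) (−13% at ε = 0.3). The optional
material-tracking mode (`strain_series(..., reregister=True)`) samples each
interframe map at the current position of the material initially at each
pixel (axial shift by the accumulated displacement, integrated from the
detected surface, which is assumed fixed) and multiplies increments by the
metric factor (1+ε); it recovers ε = 0.3 within 1%. The mode stays off by
default because the two frames are indistinguishable below ε ≈ 0.05 and the
fixed-grid sum is the cheaper, more transparent convention.

## Kinetics products

Depth profiles average the cumulative map below the per-column surface
(threshold detector: lateral 5-column median smoothing, first pixel above
0.3× the column maximum; undetectable columns are filled from the nearest
neighbour and flagged). The averaging window is 80 µm axial × 800 µm
lateral; when the 95th percentile of |profile| is below 2·10⁻⁴ the axial
window widens automatically to 160 µm. Analysis depth is capped at 900 µm
by default (configurable), reflecting the practical loss of OCT signal at
depth. Each profile value is the exact mean of its averaging region
(verified to 1e-12), with windows truncated at the surface.

Extrema tracking takes the global maximum and minimum of each profile (ties
broken toward the shallower depth; an optional prominence threshold
suppresses noise-level extrema). The neutral depth is the linearly
interpolated zero crossing between the two extrema when they bracket zero
(with several crossings, the one nearest the midpoint — consistent with the
neutral line staying roughly midway between the extrema); all crossings are
exportable separately. Extrema within one averaging window of the depth
limit are flagged unreliable.

## Simulator

Concentration follows the constant-source half-space solution
C(z, t) = C₀·erfc(z/(2√(Dt))) with D defaulting to 10⁻⁹ m²/s (glycerol in
cartilage; penetration scale √(Dt) ≈ 0.55 mm at 5 min). Strain templates:

| template          | ε(z, t)                                   | emulates                          |
|-------------------|-------------------------------------------|-----------------------------------|
| uniform           | k₊·t (k₊ = rate, 1/s)                     | steady accumulation / null runs   |
| ramp              | k₊·t·z/z_ref                              | depth-linear fields               |
| single_front      | k₊·C(z,t)                                 | dilatation following the agent    |
| alternating_sign  | C·(k₊ − k₋(1−C))                          | surface dilatation + deep shrinkage, sign change where C = 1 − k₊/k₋ |
| subsurface_layer  | single_front + layer_strain·(t/T)·[z ≤ h] | thin (~60–80 µm) surface shrinkage band |

Fields with |ε| > 0.5 are rejected — outside the regime the estimator chain
is validated for. Displacement is U(z) = ∫₀ᶻ ε dz′ (zero at the surface) by
the cumulative trapezoid rule; the bundle guarantees forward differences of
U equal midpoint averages of ε exactly, the consistency a trapezoid
antiderivative can honour (central-difference agreement is limited by grid
truncation, not by construction).

Frames are rendered per column as sums of persistent point scatterers:
uniform random physical depths at 20 per axial PSF length (fully developed
speckle), unit amplitudes, phase 4πn·z/λ₀, Gaussian axial amplitude PSF
with FWHM (2 ln2/π)·λ₀²/Δλ ≈ 8.3 µm for a 1300/90 nm source, exponential
depth attenuation (default 5·10⁻⁴ /µm), and additive circular complex noise
at a set SNR relative to the mean sub-surface signal power (default 30 dB).
Motion displaces scatterers by U evaluated at their initial depth
(Lagrangian map), so a rigid sub-wavelength shift reproduces the interframe
phase 4πnU/λ₀ exactly. Default grid: 512 axial px over 2 mm in air, 256
lateral px over 4 mm, surface at 200 µm (air). One master seed drives
scatterer placement and per-frame noise through spawned substreams;
identical seeds give bit-identical series.

**What the simulator does not model:** lateral PSF (columns are independent
speckles — real systems correlate adjacent A-scans, which mainly changes
the effective number of independent lateral looks), refractive-index
evolution during agent diffusion (a bounded confounder of phase
measurements, not modelled), multiple scattering, Brownian/flow
decorrelation, and sub-resolution scatterer reshuffling. Passing recovery
tests therefore demonstrate correctness of the processing chain under
speckle, noise and motion decorrelation — not robustness to every
decorrelation mechanism of real tissue.

## Study conditions used by tests and the acceptance script

Simulation sizes are chosen to exercise the physics at realistic geometry
while keeping runs light: 400–512 axial px (full 2 mm depth), 96 lateral px
(1.5 mm), 30 dB SNR. Scenarios: cumulative 0.01 over 10×1 s intervals;
cumulative 0.3 over 60×10 s (re-registered); 10⁻⁴ over 300 s plus a
zero-strain control (detection threshold 3× the control's profile spread);
and a shrinkage-front run (alternating_sign, k₊ = 0.2, k₋ = 0.8,
D = 4.7·10⁻¹⁰ m²/s, frames at t = 53…653 s) whose imposed strain minimum
z_min ≈ 1.26·√(Dt) deepens from ~200 to ~700 µm — tracked within one
100 µm processing window. Recovery is always judged against the field the
measurement can see: the Eulerian difference ε(z, t) − ε(z, t₀).

## Known limitations

* Accuracy degrades when the per-interval strain exceeds ~0.01 (interframe
  scatterer motion approaches the PSF width; decorrelation biases the
  estimate low by several percent at 0.02). Practical series keep
  per-interval increments well below this.
* The surface is assumed fixed in the material-tracking mode; a bulk-moving
  surface would require tracking the surface itself first.
* The thin subsurface shrinkage layer (~70 µm) is below the 100 µm window
  resolution; it is generated and verified at ground-truth level but its
  recovered amplitude is window-diluted.
* Depth attenuation makes single-scale Rayleigh tests inapplicable across
  the full depth; speckle statistics are verified with attenuation disabled
  over a uniform band.
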