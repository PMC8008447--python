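# Methods

This note documents the models implemented in `nanocorona`, the assumptions
behind them, the defaults of the synthetic-data generators, and the numerical
choices that were genuinely open.

## Fluorescence quenching

The titration substrate is the nanoparticle molar concentration [Q] with the
protein held fixed; intensities are read at the emission maximum of the
quencher-free spectrum (single-wavelength convention, not a band integral).
The linear Stern–Volmer model

    F0/F = 1 + K_SV [Q]

is fitted by (weighted, 1/σ² when uncertainties exist) linear least squares;
the slope is K_SV (M⁻¹). The bimolecular quenching rate is defined as
K_q = K_SV/τ₀ and this identity is enforced on every result object. Mechanism
classification compares K_q with the diffusion-controlled limit
2 × 10¹⁰ M⁻¹ s⁻¹: above → static, below → dynamic, exact equality → an
explicit *indeterminate* flag rather than a silent side.

For static quenching the modified (double-log) Stern–Volmer analysis

    log10((F0 − F)/F) = log10 K_a + n · log10 [Q]

uses base-10 logarithms (slope n is base-independent; the intercept is
log10 K_a by construction). Points with F = F0 are excluded with a warning
because the left-hand side is undefined there.

**Precision structure of K_a.** The titration window (1:100 → 1:20
nanoparticle:protein ratios at ~3 µM protein) spans [Q] ≈ 3 × 10⁻⁸ –
1.5 × 10⁻⁷ M, i.e. log10[Q] ≈ −7.5 to −6.8. The intercept sits at
log10[Q] = 0, about 7.2 decades outside the window, so the log-scale error of
K_a is the slope error amplified by that lever arm: with 2% multiplicative
intensity noise the site number n is recovered to ~1–2% but K_a only to
~0.1–0.2 decades (25–50% linear). This is a property of the experiment
geometry, not of the estimator; the test suite asserts the slope-based
quantities at 5% and K_a at the lever-arm-derived 0.2-decade bound. Noiseless
data recover all three parameters to better than 0.5%.

**Linearity diagnostic.** Mixed static+dynamic quenching (the transferrin
case) shows a superlinear F0/F curve. The diagnostic fits the linear model and
an equal-parameter-count exponential alternative a·exp(c[Q]) and declares
superlinearity only when the exponential improves the residual sum of squares
by more than 10% — the exponential can mimic a straight line, so a raw RSS
comparison would flip on noise.

## CD thermal denaturation

The unfolded fraction is the endpoint normalization
f = (I − I₀)/(I_f − I₀) with I₀/I_f the signals at the lowest/highest
measured temperature; f runs exactly 0 → 1 and is invariant under any affine
transform of the raw CD signal. No sloping native/denatured baselines are
modeled (endpoint normalization only), matching how such melts are commonly
reduced when only midpoints are of interest.

The two-state sigmoid f(T) = 1/(1 + exp(−(T − T_m)/w)) is fitted by bounded
least squares with multi-start initialization: T_m starts at the linear
interpolation of the f = 0.5 crossing, w at a quarter of the 0.2–0.8
temperature span, plus seeded ±30% perturbations. The fraction curve must
span at least 0.2–0.8; flat or non-sigmoidal input raises instead of
returning a meaningless fit. Temperatures are °C throughout.

The endpoint normalization introduces a small, deterministic bias when the
transition is not fully saturated at the grid edges: for T_m = 73 °C, w = 3 °C
on a 10–90 °C grid, sigmoid(90) ≈ 0.9966 ≠ 1, and the refitted midpoint is
72.97 °C. This ~0.03 °C effect is inherent to normalizing by measured
endpoints and is far below the reported uncertainty of any real melt.

Synthetic melts default to endpoints −20 → −5 mdeg (a typical 222 nm
ellipticity losing magnitude on unfolding) and transition widths of 2–4 °C,
consistent with cooperative unfolding of a small globular protein; the width
is a generator choice, as only midpoints are reported for the real systems.

## Small-angle scattering

Both models assume the dilute limit, S(q) = 1 (no interparticle peak), and
report absolute intensities in cm⁻¹ via the 10⁸ Å⁻¹→cm⁻¹ conversion.

**Core–shell sphere + power law.** Amplitude
F(q) = V_c(ρ_c−ρ_sh)K(qr_c) + V_t(ρ_sh−ρ_solv)K(qr_t) with
K(x) = 3(sin x − x cos x)/x³, r_t = r_c + d; intensity
I(q) = 10⁸(φ/V_t)⟨F²⟩ + Aq^−α + bkg. The kernel switches to its Taylor series
1 − x²/10 + x⁴/280 below x = 10⁻³, where the direct form loses all precision
to cancellation. The power law models independent large-scale clusters and is
added incoherently (no cross term); its exponent defaults to 1.5 but is a free
fit parameter.

**Schultz polydispersity.** Number-weighted averaging over the core radius
with the shell thickness held fixed (the organic coating has roughly constant
thickness). The Schultz distribution with mean r̄ and index p = σ/r̄ is the
gamma distribution with shape z+1 = 1/p² and scale r̄/(z+1); the quadrature
uses ≥64 fixed Gauss–Legendre nodes on [max(0, r̄−5σ), r̄+8σ]. The reported
"polydispersity ≈ 0.6" is interpreted as σ/mean.

**Ellipsoid.** Orientation average
I(q) = 10⁸φVΔρ² ∫₀^{π/2} K(q·r_eff(θ))² sinθ dθ + bkg with
r_eff(θ) = √(r_pol²cos²θ + r_eq²sin²θ); evaluated by Gauss–Legendre in
cosθ. The free protein is treated as **oblate** (symmetry semi-axis = minor
axis 22 Å, equatorial semi-axes 72 Å): the oblate volume
(4/3)π·a·b² ≈ 4.78 × 10⁵ ų is the one consistent with the corona count
N ≈ 7 (see below); the prolate convention is implemented and selectable.

**Fitting** minimizes Σ((I_obs−I_model)/σ)², with σ falling back to I_obs
(relative residuals) when the curve carries no uncertainties, using bounded
least squares (lmfit) with seeded multi-start from ±30% perturbations.

Generator defaults not fixed by the reference models: solvent D₂O
(ρ = 6.36 × 10⁻⁶ Å⁻², nearly contrast-matching the 6.9 × 10⁻⁶ magnetite
core, as observed), particle volume fraction 10⁻³ (dilute), protein volume
fraction 5 × 10⁻³, power-law amplitude 10⁻⁷ cm⁻¹ at q = 1 Å⁻¹ (a visible
low-q rise), background 0.01 cm⁻¹. The synthetic q-grid is 100 log-spaced
points over 0.008–0.4 Å⁻¹, extending below the nominal instrument minimum so
the Guinier region and the power law are both exercised.

## Neutron reflectometry

Box model: silicon is the semi-infinite incident medium (no native-oxide box
by default; one can be added), then a thin solvent cushion (4 Å, solvent
fraction pinned at 1), inner headgroups, acyl chains, outer headgroups, and
optionally an adsorbate layer, backed by semi-infinite solvent. Each box has
thickness, intrinsic sld, solvent fraction and a Gaussian roughness assigned
to the interface with the preceding layer; the final layer/solvent interface
roughness defaults to 3 Å. The effective sld of a box is
(1−φ)ρ + φρ_solv, which ties the three contrasts (D₂O 6.36, H₂O −0.56,
SMW 2.07, all ×10⁻⁶ Å⁻²) to one structural parameter set.

Reflectivity is the Parratt recursion with Névot–Croce factors
exp(−2k_jk_{j+1}σ²) on each Fresnel coefficient, clipped to [0, 1]. The
Névot–Croce approximation degrades when roughness approaches layer thickness;
a roughness above twice the thinner adjacent layer triggers a warning but is
honored (the 40 Å roughness of the 80 Å adsorbate layer is such a case). No
instrument resolution smearing is applied by default.

**Co-refinement** shares every structural parameter across contrasts,
minimizing the summed χ². When curves carry uncertainties the residuals are
(R_model−R_obs)/σ; without them the residuals are differences of
log₁₀R — reflectivity spans ~8 decades over the measured q range, and
log-space residuals weight all decades symmetrically. This choice matters in
practice: with relative linear residuals, offset starting points in which the
adsorbate layer is nearly fully hydrated (hence nearly invisible, with
vanishing gradients) can stall in a local minimum; in log space the
refinement converged to the generating model for every multi-start seed
probed. Starting values are also clipped strictly inside the bounds for the
same reason. Multi-start uses seeded ±20% perturbations, 5 starts.

The synthetic q-grid is 200 log-spaced points over 0.008–0.25 Å⁻¹.

## Corona geometry

The bound-protein count uses the spherical-shell volume between the complex
and bare-particle radii divided by one protein volume,
N = (4/3)π(R³_complex−R³_NP)/V_protein, reported both as a real number and
rounded to the nearest integer (the headline). Two measurement routes are
exposed and both give N ≈ 7: hydrodynamic radii (8 → 11 nm) with the
oblate-ellipsoid protein volume, and the SANS core+shell radii (61 → 73 Å)
with a triangular-prism protein volume ((√3/4)·80²·35 ų ≈ 9.7 × 10⁴ ų —
the protein approximated as a flat triangle of 80 Å edge and 35 Å
thickness). The protein volume is caller-supplied with these two named
presets because no single choice is canonical.

The side-on monolayer capacity is 4πR²/A_footprint with the equilateral
triangular footprint (√3/4)·80² ≈ 2771 Ų; with the SANS radius 61 Å this
gives ≈ 17, with the DLS radius 80 Å ≈ 29 — the implementation reports the
value for whatever radius is stated and does not interpolate between them.

Stokes–Einstein (R_H = k_BT/6πηD) and Smoluchowski (ζ = ημ/ε) use SI units
with water defaults at 25 °C (η = 8.9 × 10⁻⁴ Pa·s, ε = 6.95 × 10⁻¹⁰ F/m).

## Synthetic data and what the tests show

Every generator inverts the model its fitter assumes, so generator∘fitter is
the identity at zero noise — this validates the fitting machinery, the
parameterizations and the multi-contrast bookkeeping, but not the adequacy of
the models for real instrument data (resolution smearing, incoherent
backgrounds varying with contrast, beam-footprint corrections, and deviations
from two-state unfolding or Schultz size distributions are all outside the
generators). Independent cross-checks close part of that gap: the core–shell
intensity is verified against direct numerical Fourier quadrature of the
radial sld profile (< 10⁻⁶ relative), Schultz quadrature against Monte-Carlo
sampling of the gamma distribution (< 0.5%), the ellipsoid orientation
average against stratified Monte-Carlo (< 0.5%), and the Parratt recursion
against an independent Abeles transfer-matrix implementation (< 10⁻¹⁰ on
random stacks).

All randomness flows through `numpy.random.Generator` objects seeded by the
caller; identical seeds give bit-identical data. Problem sizes used by the
tests and the acceptance script — 9–10 point titrations, 81-point melts,
100-point SANS curves, 3 × 200-point reflectivity sets, 30–100 seed recovery
studies — run in seconds to a few minutes on one CPU.

## Known limitations

- No inner-filter correction or lifetime fitting in the quenching stage; τ₀
  is an input.
- No van 't Hoff ΔH/ΔS extraction; strictly two-state melts.
- No SANS resolution smearing or structure factors; dilute, isotropic systems
  only.
- No off-specular or polarized reflectometry; Névot–Croce roughness is
  approximate for rough, thin layers (warned, not refused).
- Monolayer capacity depends strongly on the chosen radius (17 vs 29 for SANS
  vs DLS radii); the package reports, it does not arbitrate.
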