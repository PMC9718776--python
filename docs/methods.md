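# Methods

## The five-level reaction model

The photophysics of the singly hydrated chromophore is modelled as a
sequential cascade over five states: the ground-state cluster (1), the
optically bright ππ* state (2), the dark, dissociative πσ* state (3),
the vibrationally hot ground state (4) and the separated fragments (5).
The ¹La/¹Lb pair is treated as one bright state; no branching or
back-transfer is allowed. The equations of motion couple the five
populations and the single optical coherence ρ₂₁:

    dρ₁₁/dt =  (i/2) Ω₀ g(t) (ρ₁₂ − ρ₂₁)
    dρ₂₂/dt = −(i/2) Ω₀ g(t) (ρ₁₂ − ρ₂₁) − Γ₂₂ ρ₂₂
    dρ₂₁/dt = −(i/2) Ω₀ g(t) (ρ₁₁ − ρ₂₂) − (Γ₂₁ − iΔω) ρ₂₁
    dρ₃₃/dt =  Γ₂₂ ρ₂₂ − Γ₃₃ ρ₃₃
    dρ₄₄/dt =  Γ₃₃ ρ₃₃ − Γ₄₄ ρ₄₄
    dρ₅₅/dt =  Γ₄₄ ρ₄₄

with Γᵢᵢ = 1/τᵢ. The pump envelope g(t) = exp(−½ (t/τ_IRF)²) is
peak-normalised (g(0) = 1), i.e. the quoted Rabi frequency pairs with a
unit-peak envelope, and τ_IRF is taken literally as the Gaussian width
parameter of that expression. Defaults: Δω = 0 (resonant excitation) and
Γ₂₁ = Γ₂₂/2 (pure lifetime dephasing), both overridable.

Parameters and defaults:

| parameter | meaning | default | unit |
| --- | --- | --- | --- |
| τ₂ | ππ* → πσ* crossing | 445 | fs |
| τ₃ | πσ* → hot S₀ interconversion | 13 | ps |
| τ₄ | H-bond rupture (dissociation) | 96 | ps |
| Ω₀ | peak Rabi frequency | 3.4 | rad/ps |
| τ_IRF | instrument-response width | 381 | fs |
| probe FWHM | NIR intensity envelope | 70 | fs |

Ω₀ is a direct input. The advisory estimator Ω = μ₁₂E₀/ħ with
E₀ = √(2I/ϵ₀c) gives ≈ 2.8 rad/ps from I = 2·10⁹ W/cm² and
μ₁₂ = 15 e·pm — field conventions differ between sources by factors of
order √2, so a quoted Rabi frequency is trusted over the reconstruction.

### Numerics

* State vector: 7 real components (five populations + Re/Im ρ₂₁); ρ₁₂ is
  derived as the conjugate, so Hermiticity is structural and population
  conservation holds to ≲10⁻¹⁵ (the population derivatives sum to zero
  identically).
* Internal units: ps, 1/ps, rad/ps; τ₂ and τ_IRF accepted in fs at the
  interface. This keeps every fitted quantity O(0.1–100).
* Integration starts at t = −5 ps (≈13 τ_IRF, g < 10⁻³⁷) with ρ₁₁ = 1;
  a start point where g(t_start) > 10⁻⁶ is rejected.
* Adaptive stiff-capable solver (LSODA) at rtol = atol = 10⁻⁹ with the
  step capped at τ_IRF/2 so the solver cannot leap over the pulse from
  the quiescent pre-pulse region.
* Dense output: 1 fs steps for |t| < 10 ps (resolving the 70 fs probe and
  the 445 fs decay), 50 fs beyond, stitched exactly; ~18k points for a
  145 ps window.
* The default "hybrid" mode integrates the ODE only while the pulse is on
  (|t| ≤ 9 τ_IRF, g < 10⁻¹⁷) and continues with the exact closed-form
  solution of the linear cascade (superposed sequential-decay chains,
  with analytic limiting forms — t·e^{−Γt}, t²e^{−Γt} — for coincident
  rates). This is what the global fit evaluates at each iteration; a
  full-ODE mode exists and the two agree to ≤10⁻⁹, which the tests
  assert at the 10⁻⁶ level against the independent closed form.

### From populations to ion yields

Each channel is a linear combination of probe-convolved populations:
parent sums states 2–4, fragment 2–5, water is C·ρ′₅₅. The probe kernel
is an area-normalised Gaussian (FWHM 70 fs) applied per uniform grid
segment with nearest-edge padding, so constant asymptotes pass through
unchanged; sampled discontinuities carry the expected O(h²) quadrature
error, which is why the analytic step-response check runs on a 0.1 fs
grid. The parent and fragment channels are modulated by
p(t) = a + b cos(ωt + φ) with shared ω = 3.77 rad/ps (period 1.67 ps,
20 cm⁻¹) and φ = 1.77, and (a, b) = (1.04, 0.14) / (0.92, 0.11); these
four-plus-two numbers are calibrated once on a high-resolution scan
(`fit_oscillation`, frequency seeded from the periodogram, multi-start
in phase) and then frozen in the kinetics fit.

### The global fit

`ReactionKineticsModel.fit()` jointly optimises (τ₂, τ₃, τ₄, A₂..A₄,
B₂..B₅, C) by weighted Levenberg–Marquardt (lmfit/MINPACK) over all
three channels, re-integrating the density matrix at every iteration.
Time constants are fitted in log₁₀ space to enforce positivity across
three decades; coefficients are bounded at zero. Weights are the
per-point 1σ errors. 1σ uncertainties come from the covariance scaled by
the reduced χ² (lmfit convention); R² is reported jointly and per
channel, as the convention for the joint quantity is not universal.

Baseline handling: the constant negative-delay signal is estimated as
the mean over delays < −0.5 ps and subtracted. Because the model itself
is slightly nonzero at −0.7 ps (≈1.3 IRF widths before zero), the same
mean-at-negative-delays operator is applied to the model inside the
residuals; data and model are then compared in the same gauge and
noise-free data is recovered exactly. Non-uniform delay grids are
first-class: the model is interpolated from the dense internal grid onto
each channel's own scan design, never the other way around.

## TKER analysis

One fragment's kinetic energy determines the total release through
momentum conservation, TKER = E_K·m_parent/(m_parent − m_fragment), with
standard atomic weights (H 1.008, C 12.011, N 14.007, O 15.999 → indole
117.151 u, cluster 135.166 u). Input spectra are 1-D projected
kinetic-energy histograms; no image inversion is performed, the
projected energies being accepted as a proxy for the 3-D ones.

The delay-independent water-dimer contribution is estimated as the
per-bin mean of the negative-delay spectra and subtracted from all
spectra; subtraction then re-addition is exact by construction.

Maxwell–Boltzmann fits: the default form is P(E) ∝ √E·e^{−E/kT} (3-D
speed distribution in energy form, analytic mean 3kT/2); a projected
variant P(E) ∝ e^{−E/kT} (mean kT) is selectable, since the exact form
used on projected spectra is a modelling choice. The reported mean is
always the analytic mean of the fitted form, never the histogram mean.

### Ion-dipole model

After dissociation at t_d the water cation and the chromophore's
permanent dipole (μ = 1.96 D, ground-state value, assumed constant)
repel along R(t) = R_eq + v(t − t_d) (1 m/s ≡ 1 pm/ps), giving

    TKER(t) = E_pump − E_a + q μ cosθ / (4πϵ₀ R(t)²),

monotone non-increasing toward the asymptote E_pump − E_a (40 meV at the
defaults E_pump = 4.61 eV, E_a = 4.57 eV). Evaluation before t_d is
refused (or NaN-masked on request) — the model does not define it.
Ion-induced-dipole and dipole–dipole terms are neglected.

**Identifiability.** The curve depends on the five parameters only
through three combinations: E_a, and the two shape parameters of
V(t) = K(θ)/(R_eq − v·t_d + v·t)². R_eq/θ and R_eq/t_d trade off
exactly. The five-parameter fit is retained because all five are
physically meaningful, but the flat directions mean R_eq, θ and t_d
individually reflect the assumed starting values plus noise-driven
drift along the minimum manifold; the results object therefore reports
the correlation matrix and the identifiable amplitude V(R_eq, θ), and
its summary says so explicitly. The fit uses a bounded trust-region
least-squares with an *analytic* Jacobian — finite-difference Jacobian
noise otherwise leaks optimisation steps into the flat directions.
Covariances come from the pseudo-inverse of JᵀJ (rank-deficient by
construction), scaled by the reduced χ².

## Synthetic data

The generator is a pure function of (ground truth, design, seed); the
same triple is bit-identical, and every written dataset embeds its truth
and seed.

Scan designs replicate the experiment: 417 fs steps for −1.535…6.805 ps,
one 834 fs step, 1.668 ps steps beyond 7.639 ps for the parent/fragment
channels (extended to 120 ps — the reported scans run to ≈120 ps and
longer delays were reported not to alter the fit); −5.705…140.245 ps in
4.17 ps steps for the water channel. Mean-TKER curves default to
55–140 ps in 1.668 ps steps, the design of the high-statistics scan that
fed the release-evolution analysis, with 5% relative Gaussian noise.

Noise: Gaussian with σ = 3% of each channel's peak model value by
default (the study plots error bars but prints no magnitude); a
Poisson-counting mode with shots-per-point from the design is provided.
Channel baselines (0.10, 0.10, 0.05 in model units) are arbitrary
documented defaults — the analysis must work for any constant baseline.

The channel coefficients are not published, so the defaults
A = (1.0, 0.22, 0.22), B = (0.05, 0.60, 0.15, 1.0), C = 1.0 were chosen
once to (a) reproduce the qualitative channel shapes — sharp sub-ps
parent decay to a small plateau, delayed fragment rise with late growth,
slow water rise — and (b) make the synthetic scans carry about as much
information on the lifetimes as the measured data evidently did: with
these weights the expected (Fisher) 1σ of the global fit under the
experimental design and 3% noise is ≈34 fs / 0.9 ps / 4.3 ps,
commensurate with the reported ±71 fs / ±2 ps / ±10 ps. Weights with
much weaker channel contrast would make τ₂ nearly unidentifiable at
this noise level, which the reported uncertainty shows was not the
case.

Kinetic-energy spectra are histograms of draws from the static
background distribution (Maxwell–Boltzmann at kT_bg = 60 meV — an
arbitrary documented default, deliberately not read off any figure)
plus, past t_d, a Maxwell–Boltzmann component whose analytic mean equals
the ion-dipole prediction at that delay, at equal strength by default.

### What the generator does not emulate

Detector images and their inversion, deflector purity and species
contamination (beyond the single static background term), dataset
merging across campaigns, drifts and correlated noise, and any
delay-dependence of the background. Passing recovery tests therefore
demonstrate that the estimators are correct and well-conditioned under
the stated statistical model — not that real data meet that model.

## Problem sizes

The recovery protocols use 20 replicates each: 20 global fits of
three-channel scans (214 points, 11 free parameters, a few seconds per
fit) and 20 ion-dipole fits of 51-point mean-TKER curves
(milliseconds each). The test suite runs the same protocols plus the
structural invariants in a few minutes on one CPU.

## Known limitations

* The sequential five-level scheme has no branching; if a real system
  bypasses the πσ* state the fitted τ's absorb that pathway.
* Strong-field effects beyond the two-level Rabi coupling (AC Stark
  shifts, multi-photon ionisation order) are outside the model; they
  enter only phenomenologically through the channel coefficients.
* The oscillation model is a single undamped cosine; beats or damping
  would bias (a, b) if present.
* The ion-dipole model assumes constant speed, fixed geometry and a
  point dipole; its R_eq/θ/t_d outputs are start-point-dependent (see
  identifiability above) and only E_a, the curve V(t) and — given the
  assumed θ — the speed v are data-determined.
* Near-coincident (but unequal) cascade rates are evaluated with the
  general partial-fraction form, which loses precision when rates agree
  to better than ~10⁻⁷ relative; exactly equal rates use the analytic
  limiting forms.
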