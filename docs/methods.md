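# Methods

## Model

Two NMR-distinguishable states A and B interconvert by first-order
kinetics, A ⇌ B, with forward rate k_AB and reverse rate k_BA (s⁻¹).
State A is defined as the more shielded (lower-ppm) resonance; the data
model enforces this at construction, swapping labels and rates when a
system is supplied reversed, so the convention is deterministic across
all modules. Exchange is assumed strictly two-site and first-order; no
scalar coupling, no N>2 site topologies, no non-first-order kinetics.

Equilibrium populations follow from flux balance,
p_A = k_BA/(k_AB+k_BA) and p_B = k_AB/(k_AB+k_BA). Both fractions are
computed directly from the rates (not as 1 − p) so that detailed
balance p_A·k_AB = p_B·k_BA holds to machine precision even at extreme
rate ratios. With both rates zero the populations are undefined and a
typed error is raised; rate uncertainties can optionally be propagated
to the populations by first-order (delta-method) propagation, treating
the two rate errors as independent — an extension beyond the basic
formulas, exposed as `propagate_population_se`.

### Lineshape (frequency domain)

The absorption spectrum of an exchanging singlet pair is the two-site
Bloch–McConnell resolvent

    S(ω) = a · Re{ 1ᵀ [ (R₂·I + iΩ − X) − iω·I ]⁻¹ p } + baseline

with Ω = diag(ω_A, ω_B) in rad/s (2π · ppm · spectrometer frequency;
the conversion happens only here — the data model stores ppm and s⁻¹
throughout), X the exchange matrix and p the population vector. The
2×2 inverse is expanded in closed form and evaluated vectorised over
the axis; for R₂ > 0 the matrix is never singular because its Hermitian
part is positive definite. Lorentzian lines are assumed (exchange-free
FWHM = R₂/π Hz); in the no-exchange limit the populations are taken as
(½, ½), which reproduces two equal Lorentzians at the two shifts.

An independent time-domain route, s(t) = Σ a · 1ᵀ exp[(iΩ − R₂I + X)t] p,
is implemented by complex eigendecomposition and used in the test suite
as a Fourier-transform oracle: the trapezoid-corrected DFT of the FID
must match the resolvent spectrum to better than 0.5 % of peak height.
This guards both routes against sign/convention errors at once.

Several exchanging pairs (a compound can report the same rotamer event
through more than one methyl probe) share one global (k_AB, k_BA) but
have independent shifts and amplitudes; joint fitting of the whole
region is the default, with per-pair fitting available by constructing
single-pair models.

### EXSY build-up

Mixing-time-resolved intensities obey

    I(T) = exp(M·T) · diag(I_A0, I_B0),
    M = [[−R₁A − k_AB,  k_BA], [k_AB,  −R₁B − k_BA]]

where entry [i][j] is magnetisation starting in state j and detected in
state i. The matrix exponential is computed by the 2×2
eigendecomposition closed form with a first-order series fallback when
|λ₁ − λ₂| < 1e-10·max(|λ|, 1), which keeps evaluation stable as the
rates approach zero; the general-purpose `scipy.linalg.expm` serves as
the independent cross-check in tests (agreement 1e-10), never as the
implementation. With zero relaxation the generator's columns sum to
zero and total magnetisation in each channel is conserved exactly.

All 4·|T| observations are fitted jointly and unweighted — diagonal and
cross peaks are treated symmetrically, since no weighting scheme is
implied by the experiment — for the six parameters
(k_AB, k_BA, R₁A, R₁B, I_A0, I_B0). No detailed-balance constraint
links the rates to independently measured populations: the build-up
model is fitted exactly as written with six free parameters. At least
four mixing times are required; fewer raises an underdetermined-data
error.

### Thermodynamics

van't Hoff: ordinary least squares of ln K_AB on 1/T, with
K_AB = p_B/p_A = k_AB/k_BA; ΔH = −slope·R, ΔS = intercept·R.
Eyring (unit transmission coefficient): least squares of ln(k/T) on
1/T; ΔH‡ = −slope·R, ΔS‡ = R·(intercept − ln(k_B/h)). Constants:
R = 8.314 J/(mol·K), k_B = 1.380649e-23 J/K, h = 6.62607015e-34 J·s.
Linearised regression is the default because it matches the standard
linear presentation of both analyses; a direct nonlinear fit of the
exponential van't Hoff form is available behind a flag, and per-point
weights may be supplied. Standard errors come from the regression
covariance with the usual unbiased variance estimate; a two-point
series interpolates exactly and reports zero standard error.

Population ratios at arbitrary temperature use the full free energy,
p_A/p_B = exp(+(ΔH − T·ΔS)/(R·T)). With the reference D2O parameters
(ΔH = 6.0 kJ/mol, ΔS = 16.8 J/(mol·K)) this gives 1.58 at 291 K and
1.79 at 277 K, i.e. 1.6:1 and 1.8:1 after one-decimal rounding — the
rounding lives in the presentation layer only. The ΔH-only
(entropy-free) form does not reproduce these ratios; the full ΔG form
is therefore the adopted reading.

Note an internal tension in the source data that the package surfaces
rather than resolves: with k_BA > k_AB at 300 K the populations satisfy
p_A > p_B, and the van't Hoff parameters likewise imply an A-majority
across 277–320 K, whereas the narrative description of the aqueous
system calls B the more populated state at 300 K. The formulas and the
fitted parameter values are used verbatim; users drawing biological
conclusions should be aware of the discrepancy.

## Fitting: parameterisation, initialisation, uncertainties

Rates, relaxation rates and amplitudes are optimised as their
logarithms (positivity by construction, and scale-free steps); chemical
shifts are box-bounded to the spectral window; the baseline is free.
Standard errors reported on the natural scale use the delta method
(se_x = x · se_log x), and the EXSY covariance is transformed
accordingly. Optimisation uses trust-region least squares (lmfit's
`least_squares` driver) with xtol = ftol = gtol = 1e-14, so noiseless
round trips recover generating parameters to ≲1e-6 relative error.
Non-convergence is reported in a flag, not raised; a rate estimate at
the log-space box bound (1e-4–1e4 s⁻¹ for the lineshape fitter) sets an
`at_bound` warning flag.

Initial values: EXSY — initial intensities from the smallest-T
diagonals, rates from the linear build-up approximation
I_cross(T)/I₀ ≈ k·T at the earliest usable cross peak (floor 1e-4 s⁻¹
when cross peaks are absent), relaxation from the log-linear decay of
the channel sums. Lineshape — shifts from local maxima of the spectrum
(adjacent maxima paired, lower ppm = A; if unresolved, symmetric
offsets around the tallest feature), then a coarse 13-point log-spaced
scan of k over 0.01–100 s⁻¹ in which amplitudes and baseline are solved
linearly, keeping the best residual.

Spectra are assumed phased, baseline-correct absorption mode with at
most a constant offset; no phase or baseline-roll fitting, no
apodisation handling, no multiplet structure. R₂ is never fitted: it is
supplied per solvent (DMSO 3 s⁻¹, D₂O 4 s⁻¹, overridable), so linewidth
in excess of R₂/π Hz is attributed entirely to exchange — the central
identifiability assumption of the lineshape analysis.

## Synthetic data: what it emulates and what it does not

The generators emulate the statistical structure of the experiments:
a 13-point log-spaced mixing-time grid over 5–1000 ms; temperatures
280–320 K in 10 K steps; two exchanging methoxy singlets in a
3.75–3.95 ppm window at 600 MHz (1D) / 700 MHz (EXSY); additive i.i.d.
Gaussian noise on intensities and multiplicative log-normal noise on
rates. Temperature studies are generated self-consistently: k_AB(T)
from the Eyring form and k_BA(T) = k_AB(T)/K_AB(T) from the van't Hoff
form, so one series embeds both the kinetic and thermodynamic truth.

The reference preset (`COMPOUND25_D2O`) fixes the D2O parameter set —
rates 1.432/2.233 s⁻¹ and R₁ 0.936/0.842 s⁻¹ at 300 K, ΔH 6.0 kJ/mol,
ΔS 16.8 J/(mol·K), ΔH‡ 69.3 kJ/mol, ΔS‡ −11.3 J/(mol·K), R₂ 4 s⁻¹ — so
tests and the acceptance script share one source of truth. The A/B
methoxy shifts are not part of that record; the preset adopts
3.815/3.885 ppm, plausible values inside the window, and no test
asserts them against external data. True instrument noise levels are
likewise unknown; the 1–2 % defaults are documented guesses used for
robustness and coverage tests only, never for reference-value checks.

Not emulated: phase error, baseline roll, t₁ noise, temperature
miscalibration, peak-integration error from overlapping 2D peaks, or
any correlation structure in the noise. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to spectrometer artefacts.

Seeding: a single integer expands through `numpy.random.SeedSequence`
with distinct spawn keys per generator, so sub-streams are independent
and every generator is a pure function of (parameters, seed).

## Numerical and design notes

- Degenerate-eigenvalue fallback threshold 1e-10 (relative) in the 2×2
  propagator; below it a first-order series in (M − λI)T is exact to
  rounding for the 2×2 case.
- The coalescence of two equal-population lines occurs where the
  per-site rate k_AB = k_BA crosses ≈ π·Δν/√2; the property test scans
  a rate grid and also checks the two→one peak transition is monotone.
- Evaluating the Eyring form at 300 K with the reference activation
  parameters gives 1.377 s⁻¹, within 4 % of the directly measured
  300 K forward rate (1.432 s⁻¹) — consistent, since the activation
  parameters derive from a five-temperature fit rather than the single
  300 K measurement.
- Fit label order: if an optimum lands with shift_A > shift_B the
  labels (and the shared rates) are swapped back to the shielded-A
  convention before reporting, so reported k_AB always refers to the
  lower-ppm state's departure rate.
- Problem sizes used by the test suite and acceptance script — 2048-
  point spectral axes, 13-point mixing-time grids, 5 temperatures,
  50–200 Monte-Carlo replicates — are desk-scale choices that keep the
  full suite in a few seconds while leaving Monte-Carlo calibration
  statistically meaningful.

## Limitations

Two sites only; no ΔCp (van't Hoff curvature) or non-Arrhenius
behaviour; no pressure dependence; no vendor data ingestion (delimited
text and JSON only); no peak picking beyond local-maximum
initialisation; uncertainties are asymptotic (covariance-based), not
bootstrap or profile-likelihood.
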