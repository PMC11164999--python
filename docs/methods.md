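# Methods

## Scope and data

The package analyzes equilibrium mole-fraction solubilities y₂ of solid
drugs in supercritical CO₂ on a (T, P) grid. Two measured tables are
packaged: lumiracoxib (M = 293.72 g/mol; 31 points on a 4 × 8 grid over
308.15–338.15 K and 120–400 bar, with the near-critical 338.15 K/120 bar
cell absent) and a 6-point nimesulide set used to validate the gravimetric
apparatus against earlier literature measurements. Temperatures labelled
308–338 K in the source tables are interpreted as ITS-90 laboratory set
points 308.15–338.15 K, consistent with the explicit 308.15 K usage in the
EoS results. The printed uncertainty cell at (318.15 K, 280 bar),
3.12·10⁻⁵ (≈14% relative), exceeds the stated maximum relative standard
deviation of 8.69%; the fixture keeps the printed value rather than
silently correcting it.

## CO₂ densities

All correlations take the solvent density as input. The package implements
the Span–Wagner multiparameter Helmholtz equation of state for CO₂
(residual part only; 34 polynomial/exponential terms, 5 Gaussian terms, 3
non-analytic critical terms) and solves for density by bracketed root
finding, using the ancillary saturation equations to select the stable
branch below Tc. R = 8.314 J·mol⁻¹·K⁻¹ and M_CO2 = 44.01 g/mol are used
for all package-level conversions; the EoS itself is evaluated with its
native constants.

Validation, given that no independent reference implementation is
available at build or test time: (i) the second virial coefficient matches
measured CO₂ values at 273–350 K to ~1 cm³/mol; (ii) a chemical-potential
balance at the (independently parameterised) ancillary saturation pressure
holds to a 0.1–0.2% equivalent Psat shift at 290–300 K; (iii) densities on
the study grid agree with NIST-derived values commonly reprinted in
SC-CO₂ solubility work to ~0.15%. One known defect: the transcribed
equation misses the critical-point identity P(Tc, ρc) = Pc by ~1.7%, an
anomaly confined to roughly 303–306 K and 70–85 bar — far outside the
supported fitting region. Accuracy inside 308–338 K / 120–400 bar is
~0.2%; the frozen 32-point grid in the test suite is a regression pin, not
an external truth. Supported envelope: 290–350 K, 60–600 bar; outside it
the density functions raise.

## Correlations and fitting conventions

Fit quality is always reported on mole fractions: AARD% =
(100/N)·Σ|y_exp−y_calc|/y_exp, plus signed ARD%, MSE and R². The
regression loss, however, is ordinary least squares in each model's
transformed space (ln s, T·ln(y·P/Pref), ln y) — linear regression is the
fitting procedure these correlations were designed for; AARD is the
reporting metric, not the loss.

* **Chrastil.** ln s = a + b/T + c·ln ρ with s = ρ·y₂·M_solute/((1−y₂)·M_CO2).
  Predictions invert the mass-concentration conversion exactly. c is the
  association number; ΔH_total = −R·b. A fitted c outside (0, 20) is
  flagged as a warning in the fit metadata.
* **MST.** T·ln(y·P/Pref) = a + b·T + c·ρ, Pref = 1 bar exactly.
* **Bartle.** ln(y·P/Pref) = a + b/T + c·(ρ−700). The left-hand side is
  ln(·), not T·ln(·): only this reading reproduces the magnitude of the
  published fitted parameters, and the published procedure text describes
  depicting ln(y·P/Pref) against density. Stage 1 fits each isotherm
  freely and averages the slopes into c; the isotherm intercepts are then
  *recomputed at the common slope* before stage 2 regresses them on 1/T.
  With free-slope intercepts the slope scatter leaks into the intercepts
  and the final correlation degrades badly (AARD 20% instead of 11% on the
  packaged data); the fixed-slope convention also reproduces the published
  parameter values almost exactly, so it is taken as the intended
  procedure. ΔH_vap = −R·b, solvation enthalpy by Hess's law.
* **Kumar–Johnston.** ln y = a + b/T + c·ρ_molar with ρ_molar in kmol/m³.
* **Modified Chrastil.** y₂ = Q/(1+cQ), Q = W/(1+W),
  W = (R·T·D/f⁰)^(c−1)·exp(a+b/T), with f⁰ = 1 and D the CO₂ mass density
  in kg/m³. The model family is invariant to the units of D — rescaling D
  by k shifts the fitted a by (c−1)·ln k and nothing else — so the unit
  choice is a labelling convention, verified analytically in the tests.
  Fitted by the staged GA minimizing AARD% over bounds a ∈ [−80, 20],
  b ∈ [−20000, 5000] K, c ∈ (1, 15].

Enthalpies attach to the coefficient of 1/T. The source text nominally
attributes ΔH_total to the constant term, but only the 1/T coefficient is
dimensionally and numerically consistent (R·2962 K ≈ 24.6 kJ/mol here;
R·3165 K ≈ 26.3 kJ/mol with the original density table).

## Optimizers

The **staged range-narrowing GA** is the package's global fitter for the
modified Chrastil model. Each stage launches several independent real-coded
GA runs whose population size (20–100) and generation count (100–1000) are
drawn at random, mirroring a trial-and-error hyper-parameter sweep; the
next stage shrinks the search box to the envelope of the previous stage's
optima (never beyond the original bounds). Defaults: 3 stages, 5 restarts
per stage. GA internals are standard choices, recorded in the result
metadata: tournament selection (k = 3), BLX-0.5 blend crossover, Gaussian
mutation with σ = 10% of the current range, elitism 1. The unquantified
"desired deviation" stopping idea is replaced by the fixed budget.

**Differential evolution** is classic rand/1/bin with one-to-one selection,
F = 0.7, CR = 0.9, population 15 × dimension by default, stopping after 50
stagnant generations (tolerance 10⁻¹⁰). Both optimizers are seeded and
reproduce exactly for a fixed seed; both record a monotone best-so-far
trace and never evaluate outside the bounds.

## ER equation of state route

P = RT/(v−b) − a(T)/(v(v+c)+c(v−c)). Imposing a triple volume root at
(Tc, Pc) leaves a one-parameter family; the system is closed by fixing the
critical compressibility Zc and solved numerically once per Zc (cached).
The original publication's dimensionless coefficients being unavailable
here, Zc = 0.30 is the package default — over the studied CO₂ window it
gives the smallest mean density deviation from the reference EoS (~4%,
vs ~4.5% for a Patel–Teja-style 0.313 and ~7% for the SRK-like 1/3) — and
a(T) uses Soave's α with m = 0.480 + 1.574ω − 0.176ω². The acceptance
surface is the critical-point reproduction itself (exact to 10⁻⁶ by
construction for any closure), not literature constants.

Mixing is two-parameter van der Waals: quadratic a and b with (1−kij) and
(1−lij) corrections; the third parameter c, for which the source specifies
no rule, mixes linearly in mole fraction (the common practice for
non-attractive third parameters). Fugacity coefficients are analytic
(volume integral done in closed form; the attraction denominator factors
at v = (√2∓1)c) and are verified against a numerical-integration oracle to
10⁻⁵ in the tests; volume roots below the attraction-denominator
singularity are rejected as unphysical, and multi-root states resolve by
minimum Gibbs energy.

Solid solubility solves y₂·φ₂(y₂) = (Psub/P)·exp(Vs(P−Psub)/RT) by plain
successive substitution (damped on oscillation) with a bracketed
root-finding fallback in ln y₂ for strongly coupled (large negative kij)
cases; relative tolerance 10⁻¹⁰. Per-isotherm (kij, lij) ∈ [−1, 1]² are
regressed by DE on AARD%.

**Sublimation pressure.** No measured sublimation pressure exists for
lumiracoxib and the original analysis does not state the model it used, so
Psub is an explicit input: ln(Psub/Pa) = A − B/T. The packaged default
(A = 37.756, B = 14433 K → Psub(323 K) ≈ 10⁻³ Pa, ΔH_sub ≈ 120 kJ/mol) is a
*synthetic placeholder* calibrated only to the typical range of
low-volatility drugs. Consequently the published per-isotherm EoS
deviations (7.86–14.28%) are comparable only in spirit; the package's EoS
tests are property-based instead (critical reproduction, fugacity oracle,
and recovery of known (kij, lij) from synthetic isotherms to < 0.02 over
20 seeds).

**Group contributions.** Joback sums give (Tc, Pc) — with the boiling
point either supplied or Joback-estimated — and first-order
Constantinou–Gani contributions give ω = 0.4085·[ln(Σ N_k w1_k +
1.1507)]^(1/0.5050). The CG table marks per-group provenance: alkane
groups are literature transcriptions; aromatic and polar groups are
calibrated in-repo against the experimental acentric factor of a named
reference compound (benzene, toluene, chlorobenzene, fluorobenzene,
biphenyl, acetic acid, diethylamine, 1-butanol), because a complete
published table could not be transcribed with confidence. A documented
lumiracoxib assignment (two substituted aromatic rings, NH bridge, CH₂COOH
and CH₃ side groups, F and Cl) yields ω = 1.004, within 2% of the reported
group-contribution estimate 0.9875. The reported Tc = 768.76 K is
consistent with this assignment plus an external boiling-point estimate of
~602 K; Joback's own Tb estimate for so polyfunctional a molecule is far
higher (~872 K), a known failure mode of the Tb increments.

## Analyses

**Crossover pressure.** At each pressure shared by ≥ 2 isotherms the
y-vs-T sequence is classified strictly decreasing (−1), strictly
increasing (+1) or non-monotone (0; excluded). The crossover is the
highest pressure trending −1 that has a higher shared pressure trending
+1, reported as a *grid* pressure: the measurement grid is coarse (40 bar)
and interpolating fitted isotherms would manufacture precision. On the
packaged data: 120 and 160 bar trend −1, 200–400 bar trend +1 → 160 bar.

**Self-consistency.** z = T·ln(y·P/Pref) − b·T, with b from the MST fit,
is regressed on ρ pooling all isotherms; the collapse R² is the statistic
(1.0 exactly for noise-free MST data; 0.980 on the packaged lumiracoxib
table). The ≥ 0.95 threshold used in the tests is a package convention for
"acceptably linear", not a value from the source.

## Synthetic data

The generator evaluates any of the five correlation forms (or the EoS
route) on a (T, P) grid and multiplies by lognormal noise with unit mean
(σ² = ln(1+CV²), mean correction applied) — multiplicative noise matches
the way the measured uncertainties scale with y. Defaults mirror the
measured table: the 4 × 8 grid with the 338.15 K/120 bar cell dropped and
CV = 5%, mid-range of the reported 3–9% triplicate scatter. Reported
uncertainties are u_y = CV·y by construction. Ground truth is returned
alongside the table and never written into the CSV. The crossover surface
builder uses ±2%/K isobaric trends, matching the measured magnitude; at 5%
noise the boundary is recovered in ≥ 95 of 100 seeds. What the generator
does *not* emulate: temperature/pressure set-point error, depressurization
losses of the gravimetric method, or grid-cell-correlated drift — so
passing recovery tests demonstrate estimator correctness, not robustness
to those systematics.

## Reproduction fidelity and known limitations

The original analysis read CO₂ densities from a printed literature table
(not reproduced in the source); this package evaluates the reference EoS.
The consequences are systematic and therefore documented rather than
tuned away:

* Chrastil (8.06% vs 7.8), MST (9.82 vs 9.5) and Bartle (10.91 vs 10.7)
  refit within 0.3 points of the published deviations.
* Kumar–Johnston — exp-linear in density, the most density-sensitive form —
  fits *better* than published (6.74% vs 9.8), and in consequence outranks
  Chrastil here, whereas the published ranking puts Chrastil first. The
  published KJ parameters themselves (modulo an evident sign typo in the
  constant) give 11.2% on these densities, supporting the density-table
  explanation.
* The Chrastil 1/T coefficient lands at −2962 K (ΔH_total 24.63 kJ/mol)
  against −3165 K (26.31 kJ/mol) published — a 7% coefficient shift of the
  same origin.
* The GA-fitted modified Chrastil reaches AARD 6.9%, below the published
  8.7% optimum (a global optimizer on a better-conditioned density surface
  should do no worse).
* The published solvation enthalpy of 210.3 kJ/mol is not reproduced; it
  is inconsistent with Hess's law given the published Bartle coefficient
  (−R·b_Bartle ≈ 45 kJ/mol implies solvation ≈ −20 kJ/mol), and the
  package reports the Hess-consistent value.

Problem sizes in the tests are chosen to keep the full suite comfortably
interactive: 100-seed noisy-recovery studies for the OLS models, 20-seed
DE recovery for the EoS binary parameters, 10-seed GA benchmark sweeps.
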