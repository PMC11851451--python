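# Methods

## The binding models

A hairpin duplex DNA presenting one minor-groove site binds a
heterocyclic diamidine either as a 1:1 monomer complex or, at wider
grooves such as -TTAA-, as a sequential 2:1 stacked dimer.  Both cases
are described through the binding polynomial (the partition function
over ligation states at free ligand concentration *C*, in molar):

    P(C) = 1 + K_A1·C + K_A1·K_A2·C²          (two-site)
    P(C) = 1 + K_A·C                          (one-site)

with stepwise association constants in M⁻¹.  Moles of ligand bound per
DNA is r(C) = (C/P)·dP/dC, which gives the familiar hyperbola
K·C/(1+K·C) for one site and the Adair form
(K_A1·C + 2·K_A1·K_A2·C²)/P for two sites.  Species fractions (free
DNA, 1:1, 2:1) are the individual polynomial terms divided by P.

**Cooperativity index.**  Two *independent, equivalent* sites satisfy
K_A1 = 4·K_A2 on purely statistical grounds (two ways in, half the
ways out), so K_coop = 4·K_A2/K_A1 equals 1 at the non-cooperative
baseline (equivalently K_A2/K_A1 = 0.25); K_coop > 1 signals positive
cooperativity — the second ligand binds better because it stacks on
the first.  The single-number affinity for a two-step system is the
geometric mean K = √(K_A1·K_A2).  The classification band around
K_coop = 1 defaults to ±0.25 — a deliberately generous bracket for
what "indistinguishable from statistical" means given typical ~10%
replicate spread on each constant; it is configurable.

All concentrations are molar internally; nM/µM appear only at the
configuration boundary, where unit-less concentrations are rejected
outright.

## SPR simulation and kinetic fitting

Sensorgrams assume constant free-analyte concentration during the
association window (flow cell, no depletion) and C = 0 afterwards, each
injection starting from a regenerated surface (an optional single-cycle
mode chains injections without regeneration).  The 1:1 model has the
closed form R(t) = Req·(1 − e^−(ka·C+kd)·t), Req = Rmax·ka·C/(ka·C+kd),
with exponential decay after the stop time.  The sequential 2:1 model
is integrated as an ODE in surface fractions with LSODA at
rtol = 1e-10, atol = 1e-12; conservation D + DL + DL2 = Dmax is
structural (the free fraction is eliminated).  Mass-transport
limitation and bulk refractive-index artifacts are not modeled.

Global 1:1 fitting shares (ka, kd, Rmax) across all concentrations,
parameterized in log space so positivity needs no constraints, and
minimizes unweighted least squares with Levenberg–Marquardt.  Standard
errors come from the Gauss–Newton covariance on the log scale, mapped
back by the delta method.  A single curve is refused (Rmax and ka are
not separable at typical C); data containing only dissociation phases
yield kd with ka and Rmax explicitly flagged unidentifiable rather than
a silently meaningless estimate.  The 2:1 kinetic model is
simulation-only: 2:1 systems that equilibrate quickly carry little
kinetic information, so their constants are obtained from steady-state
isotherms instead — kinetic and steady-state estimates of the same
K_A are reported side by side and never forced to agree.

## Steady-state isotherms

Plateau responses are the mean over the trailing window (default last
20%) of the association phase; a linear trend steeper than 0.05 RU/s
flags the window as not at steady state.  Responses are normalized by
RUmax, the response at one ligand per DNA, so dimer saturation reads
r ≈ 2; RUmax is user-supplied by default (it depends on immobilization
level, which is instrument-specific) with co-fitting left to the
caller via the weights/initialization hooks.  Fits use bounded least
squares (lmfit) with the half-saturation initialization
K_A1 = 1/C_half, K_A2 = K_A1/4.  Replicate isotherms on a common grid
can be averaged, with the half-range reported as spread rather than a
formal confidence interval.  Model choice is by AIC; |ΔAIC| < 2 is
declared indeterminate and the plateau heuristic (max r > 1.3 ⇒
two-site) is reported alongside.

## Competition speciation and predicted spectra

For several DNAs sharing one ligand pool in a closed cell, total-ligand
conservation L_tot = L + Σ_j D_tot,j·r_j(L) has a strictly increasing
left side, so the free-ligand root is unique on [0, L_tot]; it is found
with Brent's bracketed method (same guarantee as bisection on a sign
bracket, faster convergence) at machine-level relative tolerance, and
every species concentration follows from each DNA's polynomial terms.
Predicted neutral-mass spectra place one peak per species at
mass(DNA) + n·mass(ligand) with intensity proportional to molar
concentration — equal electrospray response factors, because relative
peak heights are interpreted directly and any response-factor model
would be invented.  Oligo masses use standard average residue masses
(5′-OH or 5′-phosphate conventions); published peak labels from
deconvoluted spectra are not recomputable without the exact hairpin
sequences and adduct conventions and are never used as oracles.

## Titration breakpoints

Closed-cell titration curves are forward-simulated from the same
speciation solver at fixed DNA total and stepwise ligand additions
(post-addition concentrations; optional volume tracking applies
cumulative dilution).  The signal is w1·[DL] + w2·[DL2] with default
weights (1, 2) — proportional to bound ligand — since induced-CD
amplitudes are uncalibrated and only shape and breakpoint position are
meaningful.  The breakpoint is the intersection of the best
two-segment linear fit (every admissible split with ≥ 2 points per
segment scored by total RSS).  If the two segment slopes differ by
less than 20% of the steeper slope, the curve is declared to have no
detectable kink: weak binding (K·D_tot ≪ 1) therefore returns "absent"
instead of a spurious stoichiometry.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed) built on the
simulators above with additive i.i.d. Gaussian noise; each emits a
manifest (generator, seed, full parameter set) sufficient to
regenerate the dataset bit-for-bit.  Defaults mirror the study design
the package targets: fourteen injected concentrations from 2 nM to
1000 nM; 600 s association / 600 s dissociation windows (long enough
to plateau for kd ~ 1e-2 s⁻¹, K_A ~ 1e6–1e8 M⁻¹); competition
mixtures of two DNAs at 10 µM each with 20 µM ligand; titrations of
5 µM DNA in ten 1 µM increments.  Named presets carry the published
constants per compound/site pair (e.g. DB1003-TTAA: K_A1 = 2.6e6,
K_A2 = 7.5e7 M⁻¹).  Not emulated: baseline drift, injection spikes,
mass-transport curvature, heteroskedastic detector noise, ESI response
differences.  Recovery results on these data are therefore upper
bounds on real-instrument performance.

## Measured power of the K_coop estimator

K_coop is a ratio of two constants estimated from the same curve and
inherits both uncertainties.  Linearizing the two-site isotherm at the
DB1003-TTAA truth over the standard fourteen-point grid gives
sd(log K_coop) ≈ 0.98 per unit isotherm at σ_r = 0.05 (1.54 for
DB1992-TTAA): at that noise level no estimator can localize K_coop to
better than roughly a factor of e.  The implemented fit matches this
bound — median relative error ≈ 0.59 over 100 seeded replicates, with
the cooperativity *sign* recovered in 100/100.  Median error below 20%
requires σ_r ≲ 0.01, or equivalently averaging ~25 replicate
isotherms, or a grid extended well past 1 µM.  Practical reading:
single noisy isotherms reliably answer "is this a positive cooperative
dimer?", while quantitative K_coop values need low-noise or replicated
data.

## Numerical choices and problem sizes

Tolerances: speciation root at Brent machine tolerance (balance closes
to < 1e-9 relative); ODE integration rtol 1e-10 / atol 1e-12;
fits iterated to xtol/ftol 1e-14.  Ties in model selection fall to the
plateau heuristic; degenerate inputs (zero ligand, zero concentration,
empty mixtures) return exact limits rather than erroring.  Test and
acceptance workloads use the study-scale designs directly (14-curve
sensorgram sets at 240 points per curve, 100-replicate recovery and
breakpoint studies, 100 random mixtures for the speciation oracle),
which the package's own arithmetic completes in seconds.

## Known limitations

No mass-transport or drift modeling; no kinetic fitting of 2:1
systems; no charge-state/adduct modeling in spectra; RUmax is taken as
known rather than inferred; breakpoint analysis assumes an
approximately piecewise-linear signal, which soft (weak-binding)
curves violate by design.
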