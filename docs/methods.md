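# Methods

## Model

The theory applies to two species co-invading a virgin, well-mixed batch
environment at equal low inocula.  While nutrient drawdown is negligible,
each population grows exponentially, `N_i(t) = N_i(0) exp(mu_i t)`, at the
realised rate given by the Monod equation with Boltzmann–Arrhenius
temperature scaling of both parameters:

- `mu_i(T, S) = mu_max,i(T) S / (K_S,i(T) + S)`
- `mu_max,i(T) = B0_i exp(-E_mu,i/k (1/T - 1/T_ref))`
- `K_S,i(T) = K0_i exp(-E_K,i/k (1/T - 1/T_ref))`

Temperatures are Kelvin internally and Celsius at every file and CLI
boundary; `k = 8.617333e-5 eV/K`; `T_ref = 15 °C = 288.15 K` by default.
The competitive advantage is `R = (mu_a - mu_b) t` and its saturated limit
`R_inf = (mu_max,a - mu_max,b) t`.  The exponential Arrhenius form is only
valid inside the operational temperature range (OTR, default 15–25 °C);
above ~25–30 °C real thermal performance curves bend over, which this
package deliberately does not model (no Sharpe–Schoolfield-type unimodal
fits).

Assumptions worth stating explicitly: equal inocula; constant S over the
prediction horizon; no interference (toxins), no multi-nutrient or light
limitation; the winner is decided purely by the sign of R.  Ties are
declared at |R| < 1e-12 — with continuous traits they only arise from
identical parameterisations.

`crossing_temperature` solves `ln(B0_a/B0_b) = (E_mu,a - E_mu,b)/k (1/T* -
1/T_ref)` in closed form; it returns `None` when the activation energies
are equal (parallel curves) or the root falls at non-positive temperature,
and a flagged `'degenerate'` value when both trait pairs are identical.

## Growth-curve fitting

Specific growth rates are estimated per culture by fitting the three-phase
piecewise-linear log-density model (flat lag until `t_lag`, slope `mu`
until `t_max`, flat plateau at `Nmax`).  Fitting is done on natural-log
densities so the slope *is* the specific rate used by the theory; a log10
mode (intercepts in log10, slope converted by ln 10) exists for
cross-checks.  Continuity at `t_max` removes one degree of freedom, so the
optimiser works in (t_lag, dt, N0, mu) with `Nmax = N0 + mu dt`; the AICc
complexity penalty still counts the five named parameters.  AICc is
reported as NaN for curves with n ≤ 6 points (the small-sample correction
is undefined there); since every restart shares n and p, start selection
by lowest AICc is equivalent to lowest RSS in all cases.

Multi-start strategy: `n_starts` (default 1000) random parameter
combinations are drawn uniformly — knots over the sampling window with
t_lag ≤ t_max, mu over [0, 3] d⁻¹, intercepts within one log unit of the
observed extremes.  All candidates are scored vectorised; the best
`n_polish` (default 5) plus one data-driven start (steepest observed
two-point slope with flanking flat phases) are refined by bounded
trust-region least squares, and the best refined fit wins.  Refining only
the most promising candidates keeps the cost at a few optimiser runs per
curve while preserving the global-search character of the 1000 uniform
starts; on noiseless curves the optimum is recovered to machine precision,
and an exhaustive profiled grid search never beats it on short curves (see
the acceptance tests).

Curves whose fitted rise is under one decade (configurable) are flagged
`failed_growth` and excluded from Monod fitting, mirroring the removal of
cultures that never grew; genuinely flat curves short-circuit to an exact
mu = 0 fit.

## Trait fitting

The Monod curve is fit per species × temperature × replicate to the
(S, mu) estimates by multi-start least squares in log-parameters (which
enforces positivity).  Standard errors come from the Jacobian at the
optimum by the delta method; a singular information matrix or se(K_S) >
K_S flags an unidentifiable half-saturation constant (e.g. all phosphate
levels saturating).

The Boltzmann–Arrhenius fit regresses ln(trait) on `x = 1/(kT) -
1/(kT_ref)` by ordinary least squares — slope `-E`, back-transformed
intercept the normalisation constant — pooling all replicate-level Monod
estimates inside the OTR (≤ 9 points per species and trait with the
default design: 3 temperatures × 3 replicates).  For log-normal errors
this is the maximum-likelihood fit and is exactly the optimum a nonlinear
fit of the exponential form on the log scale reaches; the nonlinear mode
(`method='nonlinear'`) is retained as a cross-check.  At least 4 points
inside the OTR are required; a replicate-mean variant exists but refuses
designs that would leave fewer points than that.

## Synthetic-data generator

The generator emulates the study design end to end so every stage is
testable without any external dataset:

- monoculture: 5 temperatures (15–35 °C) × 13 phosphate levels × 3
  replicates, sampled every other day for 28 days, 100 cells/mL inocula.
  The 13 levels default to a log-spaced grid over 0.01–50 µmol/L, which
  spans the stated range with resolution near typical K_S values (the
  exact experimental concentrations were not published in the main text);
- competition: all 15 pairs × {15, 25} °C × {0.1, 1, 30} µmol/L × 6
  replicates, sampled at days 5, 14, 23.

Monoculture curves follow the three-phase model exactly, with the
exponential slope given by the species' realised Monod rate; competition
trials grow both species exponentially from equal inocula *without* lag
(the inocula are taken to be acclimated, exponentially growing cells — the
regime the theory describes), each capped at its own carrying capacity.

The default ("reference") panel contains six species with B0 ∈
[0.45, 0.85] d⁻¹ and E_mu ∈ [0.35, 0.75] eV arranged so that four pairs
have mu_max crossings inside the OTR, a realistic density of potential
reversals.  Half-saturation traits follow a mild gleaner–opportunist
pattern, `K_S,i(T) ∝ mu_max,i(T)^0.6`, so the ranking of realised growth
rates is the same at scarce and saturating phosphate; a consequence is
that on this panel the R and R_inf predictions agree in sign everywhere,
and a zero-noise replication is predicted perfectly by both modes.  All
six species share a carrying capacity of 10⁷ cells/mL: once both
competitors have saturated, their observed log-ratio is exactly zero (an
indeterminate tie that the evaluation excludes) instead of an arbitrary
sign the exponential-phase theory does not model.  Random panels drawn by
`sample_species_panel` are not constrained in these ways.

Noise sources:

- `sigma_log10` (default 0.05): additive Gaussian on log10 density, i.e.
  multiplicative on density — the error structure growth data are usually
  modelled with;
- `misclassification_rate`: each cell counted in a 10 µL cytometer aliquot
  is attributed to the wrong competitor with this probability (binomial
  swap on aliquot counts, densities back-computed).  0.22 mimics a
  78%-accurate discriminator.  Applying the swap to aliquot counts rather
  than per-mL numbers keeps the error magnitude realistic;
- optional phosphate drawdown: `dN_i/dt = mu_i(S) N_i`,
  `dS/dt = -Σ quota_i mu_i N_i` with a fixed per-cell phosphorus quota
  (~10⁻⁹ µmol/cell, so 1 µmol/L sustains ~10⁶ cells/mL; no Droop internal
  stores), integrated with LSODA at rtol = atol = 1e-8.  This exists to
  stress-test the constant-S assumption, not to be a full batch-culture
  model.

What the generator does *not* emulate: cytometer channel data (FSC/SSC/FL
values — true labels plus the scalar misclassification rate replace the
discriminator), unimodal thermal performance above the OTR (do not use the
30/35 °C arms to study full-TPC fitting), joint carrying capacities, light
or CO₂ limitation, and trait evolution.  Passing tests therefore certify
the estimation and prediction machinery, not the biology of any real
community.

## Evaluation

Observed advantage per replicate: `R_obs = ln((N_a + 1)/(N_b + 1))`; the
+1 keeps double extinctions finite (a tie).  Replicates whose *total*
density falls below 500 cells/mL (5× the inoculum; configurable) are
dropped as too sparse to call a winner, with every drop logged.  Winners
are compared at the replicate level; the headline table reports the
proportion correct for the full dataset and by temperature, nutrient level
and species.  The p-value against chance resamples the replicate-level
correct/incorrect indicators with replacement (B = 10000, seeded;
implemented exactly as Binomial(n, k/n) draws) and reports the one-sided
fraction of bootstrap proportions ≤ 0.5 — the simplest proportion-vs-chance
bootstrap, chosen because the original scheme is not specified in detail
and deliberately easy to swap.

Reversals: a (pair, nutrient) cell shows an observed reversal when the
median R_obs across replicates changes sign between the two temperatures;
a median of exactly zero is excluded as indeterminate rather than randomly
assigned, so headline counts cannot depend on a seed.  Predicted reversals
come from the sign of predicted R at the two temperatures.  Correlations
between predicted and observed R, and between R_obs at successive sampling
days (the persistence check for the exponential-phase assumption), are
Pearson r with Fisher-z 95% intervals.

## Problem sizes and numerical choices

- Default multi-start budget: 1000 screened starts, 5 polished, per curve;
  validation studies in the test suite use 200 screened / 2–3 polished,
  which recovers the same optima on this class of 15-point curves.
- Trait-recovery studies simulate the OTR arms only (3 temperatures × 13
  phosphate levels × 3 replicates per species): the 30/35 °C arms do not
  enter the Arrhenius fit.
- The noisy-recovery study uses 200 random species; the misclassification
  study 50 seeds × 3 rates on the 6-species reference panel; the bootstrap
  calibration 1000 datasets of 540 replicates.
- Optimiser tolerances are 1e-12 (xtol/ftol/gtol) throughout; the
  drawdown ODE uses rtol = atol = 1e-8.
- RSS is floored at 1e-30 inside AICc evaluation for numerically perfect
  fits.

## Known limitations

- The Arrhenius-only generator cannot produce realistic 30–35 °C data;
  fits over the full temperature range (e.g. GAM-style descriptions) are
  out of scope.
- The depletion simulator caps each species at its own Nmax independently;
  joint resource-limited equilibria (R*-style theory) are not implemented.
- `R` assumes constant S over the horizon.  The day-14 evaluation on
  simulated data inherits the same violations the real experiment had
  (saturation before day 14 at high S); the day-5/day-14 persistence
  correlation quantifies the consequence rather than removing it.
- Bootstrap p-values are one-sided against 0.5 and replicate-level only;
  no correction for multiple subsets is applied.
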