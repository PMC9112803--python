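# Methods

## Kinetic model and assumptions

The package models a linear folding pathway D ⇌ I ⇌ N whose intermediate I
is high-energy: it never accumulates, so every relaxation is
single-exponential and the observed rate is

k_obs(u) = [k_f⁰ e^(−m_f u/RT) + k_u⁰ e^(m_u u/RT)] / [1 + K_part e^(m_part u/RT)],

with u the urea concentration (M). The denominator is the steady-state
partitioning between the two transition states: at low urea TS1 limits the
rate; as u grows, K_part·e^(m_part u/RT) exceeds 1 and TS2 takes over,
bending the unfolding limb's log-slope from m_u/RT toward
(m_u − m_part)/RT. The explicit three-species eigenvalue treatment is
deliberately not implemented — for a never-populated intermediate the
partitioning form is the appropriate reduction, and it is the form the
parameters of the packaged reference table are defined in.

Assumptions inherited by everything downstream:

* all limb free energies are linear in denaturant (constant m-values);
* mutations perturb state free energies, not the mechanism;
* the denatured-state free energy is unaffected by mutation (the standard
  Φ-value assumption);
* rates are in 1/s, energies in kcal/mol, m-values in kcal/(mol·M).

**RT = 0.5925 kcal/mol** (R = 1.987×10⁻³ kcal/(mol·K), T = 298.15 K) is the
package default, overridable per call and via the CLI config; the
experiments the reference table comes from were run at 25 °C.

## Derived quantities

* Stability: ΔG_D-N = RT ln(k_f⁰/k_u⁰); equilibrium m-value taken
  kinetically as m_D-N = m_f + m_u (only kinetic data are in scope, so no
  separate equilibrium m-value exists in the pipeline).
* Tanford betas: β_TS1 = m_f/m_D-N, β_TS2 = 1 − (m_u − m_part)/m_D-N.
  Values outside [0, 1] are flagged with a warning but never clamped — the
  Hammond analysis needs the raw trend. Note that with the kinetic m_D-N
  definition, β values quoted from analyses using an equilibrium m-value
  will differ by the ratio of the two m_D-N estimates; this is why the
  package treats published β point values as indicative, not as targets.
* ΔΔG terms and Φ values as in the README. Φ_TS1 has two algebraically
  equivalent routes (ΔΔG_D-TS1/ΔΔG_eq and 1 − ΔΔG_TS1-N/ΔΔG_eq) when all
  terms derive from one parameter set; the first is primary. The reference
  table's "ΔΔG_TS1"/"ΔΔG_TS2" columns are unfolding-side barriers
  (RT·ln(k_u^mut/k_u^wt) reproduces the printed numbers; the folding-side
  reading does not).
* Exclusion rule: Φ is not reported when |ΔΔG_eq| < 0.4 kcal/mol
  (configurable). The absolute value is used deliberately: stabilizing
  near-neutral mutants are as unreliable as destabilizing ones. Stabilizing
  mutants beyond the threshold are reported with their (negative) Φ.
* Uncertainties are first-order delta-method propagations of the rate
  standard errors treating inputs as independent; the covariance between a
  Φ numerator and its ΔΔG_eq denominator (they share rate constants) is
  neglected, which slightly overstates Φ errors.

## Fitting

Single-trace exponential fits run Levenberg–Marquardt on
(offset, amplitude, ln k_obs); initial guesses are offset = mean of the
last 5% of samples, amplitude = first sample minus offset, k_obs =
ln 2 / (time of half signal change), with 5 perturbed restarts. A trace
whose standard deviation is below 3× the first-difference noise floor is
rejected as having no amplitude; a fitted 1/k_obs longer than half the
window triggers a warning. A Wald–Wolfowitz runs test on residual signs is
reported as a lack-of-fit diagnostic but never escalates the model to a
double exponential.

Chevron fits minimize residuals in **log₁₀ k_obs** (chevrons live in log
space and multiplicative noise is the natural error model), unweighted by
default with optional σ-weighting. Positivity of k_f⁰, k_u⁰, K_part is
enforced by fitting natural logarithms; m-values are bounded below at 0.
Single-chevron fits use an arm-regression heuristic start (log-linear fits
of the two limbs) plus 10 seeded multistart perturbations; convergence
tolerance 10⁻¹⁰ on the relative SSR change, at most 5000 residual
evaluations.

The global fit stacks all variants into one least-squares problem in which
the shared m-values appear exactly once. Constraint schemes:
`shared_all_m` (main analysis), `free_mf_mu` (shared m_part only; Hammond
analysis), `free_mf` (robustness check), and `free_all_m`, which is exposed
only to demonstrate degeneracy — with every m free the Jacobian is close to
singular and a `DegeneracyWarning` names the unreliable parameters
(detected at condition number 10⁸ via SVD). The joint fit starts from
per-variant single-chevron fits with shared values initialized at their
across-variant medians; because this start is data-driven and the joint
problem is well-conditioned under the supported schemes, randomized
restarts (same budget of 10) are attempted only when that start fails to
converge, keeping the default path deterministic and fast. Standard errors
come from s²(JᵀJ)⁺ at the solution, mapped to the natural scale by the
delta method; simulation tests check that 90% intervals built from them
cover truth at roughly the nominal rate.

## Regressions

LFER: ordinary least squares with free intercept of the transition-state
destabilization (ΔΔG_D-TS1 for TS1, ΔΔG_eq − ΔΔG_TS2-N for TS2) against
ΔΔG_eq, over variants passing the Φ exclusion rule (an extra exclusion
list is accepted). Hammond: OLS of β against ΔG_D-N; a negative slope is
the Hammond-consistent outcome and is reported, not enforced. Φ-vs-Φ:
given an externally supplied residue mapping between two homologous
domains (sequence alignment is an input, never computed here), retained
pairs are summarized by Pearson r, RMS deviation from the identity line
and the mean offset — the minimal statistics for "same mechanism, one
domain more native-like".

## Synthetic data generator

The generator emulates the reference study's design: a urea grid from 0 to
9 M (0.25 M steps by default, 11-fold-dilution style coverage of both
limbs), multiplicative lognormal noise on k_obs (Gaussian in log₁₀,
default sd 0.02 — a few percent, typical of averaged stopped-flow
estimates), and Gaussian amplitude noise on traces (default 0.01 a.u. on
unit signals; traces default to 1000 points over 10/k_obs).

The wild type is the reference table's fitted chevron: k_f⁰ = 300 s⁻¹,
k_u⁰ = 0.06 s⁻¹, K_part = 0.017, with m_u = 0.52 and m_part = 0.45
kcal/(mol·M). m_f is not printed anywhere; it is fixed once at 0.81
kcal/(mol·M) so that β_TS1 = m_f/(m_f+m_u) = 0.61 matches the quoted early
transition-state position. (The implied β_TS2 = 0.947 rather than the
quoted 0.91; the discrepancy traces to the unstated m_D-N definition
discussed above and was left as is rather than tuned.)

Mutants are constructed by inverting the Φ formulas: given (ΔΔG_eq, Φ_TS1,
Φ_TS2), k_f, k_u and K_part are scaled so the ΔΔG/Φ pipeline returns
exactly those values — this round trip is exact to 10⁻¹⁰ and is the
generator's defining contract. Default truth draws: ΔΔG_eq uniform on
[−1.3, 3.3] kcal/mol (the experimental ensemble's span), Φ_TS1 on
[0.1, 0.9], Φ_TS2 on [0.3, 1.0]. A `hammond_slope` option shifts β_TS1
linearly with stability at constant m_D-N (m_part stays shared), which by
construction moves β_TS2 in parallel — the cleanest way to manufacture a
Hammond-behaving ensemble.

What the generator does **not** emulate: instrument dead time,
photobleaching, burst phases, non-exponential phases, correlated errors
between refolding and unfolding points, or mutants that change m-values
non-linearly. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not robustness
to instrument artifacts.

## Problem sizes used in the tests

Recovery tests run at the study's scale where that is cheap (30 variants,
25-point chevrons, 2% log-noise for the headline Φ-recovery check) and at
reduced scale elsewhere (4–12 variants, 21-point grids) so the whole suite
stays fast; the scaled-down runs exercise the same code paths and their
tolerances were set from the propagated uncertainties, not from observed
outcomes.

## Known limitations

* The packaged table prints rates to 1–2 significant figures; recomputed
  ΔΔG/Φ cells can therefore sit outside the printed error bars for a few
  variants (T153S, A122G, V148A, V209A) even though every such discrepancy
  is within the uncertainty propagated from the printed inputs.
  `validate_table1` reports both comparisons explicitly.
* Φ error bars neglect numerator/denominator covariance (conservative).
* The `free_all_m` scheme is expected to be degenerate; it is a
  diagnostic, not an analysis mode.
* No support for denaturants with non-linear m-value behavior, temperature
  dependence, or double-jump experiments.
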