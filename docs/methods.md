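# Methods

This note documents the models, conventions and numerical choices behind
`ligfid`, in the order the pipeline runs.

## Branched nick-sealing mechanism

The simulator (`ligfid.mechanism`) integrates the mass-action system

    E* + S  <->  E*S          k_on (per nM per s), k_off (per s)
    E*S      ->  E·AMP-DNA    k_transfer (per s)
    E·AMP-DNA -> E + P        k_seal (per s)         nick sealing
    E·AMP-DNA -> E + I        k_abort (per s)        abortive release
    E        ->  E*           k_readenylylate (per s)

where E* is the adenylylated enzyme, S the nicked substrate, I the free
abortive AMP-DNA intermediate and P the sealed product. Assumptions, each
exposed as a switch:

- **Released AMP-DNA is terminal** (no rebinding) by default. On gels the
  released intermediate accumulates as an endpoint species; a `rebinding`
  flag re-enables re-entry at `k_on`.
- **Re-adenylylation is instantaneous** by default
  (`k_readenylylate=None`): purified ligase is isolated adenylylated and
  assays run at saturating ATP. A finite rate adds `1/k_readenylylate` to
  the turnover time.
- **Deterministic ODE integration** (LSODA, rtol 1e-8, atol 1e-10 nM):
  concentrations are nM-scale bulk, so no stochastic engine. Solver
  failure raises an explicit `IntegrationFailure`, never silent NaN.
- **Initial condition**: all enzyme free and adenylylated, no pre-bound
  complex.

Under the default contract the implied steady-state parameters have closed
forms (`scheme_steady_state`), with k_r = k_seal + k_abort:

    k_cat,total = k_transfer·k_r / (k_transfer + k_r)
    K_M         = k_r (k_off + k_transfer) / (k_on (k_transfer + k_r))
    abortive fraction = k_abort / k_r        (independent of [S])

`scheme_from_steady_state` inverts these so synthetic ground-truth schemes
can be built to match target k_cat, K_M and abortive-fraction values.
Microscopic rate constants are not measured quantities in the study this
pipeline serves; the default schemes are calibration targets whose implied
steady-state parameters mirror the measured phenotypes (wild-type k_cat
0.52 s⁻¹ and K_M 100 nM on the canonical nick, and so on).

`steady_state_summary` predicts initial rates on a substrate grid. Two
numerical points matter. First, the pre-steady-state lag includes not only
binding but the buildup of the bound AMP-DNA pool, which relaxes at
k_seal + k_abort — for strongly abortive schemes this is tens of seconds —
so the fit window starts 25 lifetimes after the slowest relaxation and a
free intercept absorbs the lag. Second, rates are probed at an enzyme
concentration low enough that total conversion stays below 2e-5 of the
substrate over the window, then scaled linearly to the requested enzyme
concentration; the mechanism is linear in enzyme while substrate is
undepleted, so the scaling is exact in the initial-rate regime.

## Gel quantification

Species fractions are band intensity over total lane intensity; fractions
times the known initial substrate concentration give species
concentrations. Enzyme-bound DNA co-migrates with substrate after
denaturing quench, so the substrate band carries S + bound and mass
conservation makes the lane total equal the loaded substrate. Mini-gel
lanes that do not resolve AMP-DNA from substrate are handled by a merged
denominator (`resolved_intermediate=False`); inputs are assumed
background-corrected band volumes (no image analysis).

## Steady-state kinetics and fidelity statistics

- **Initial rates**: unweighted straight-line fit with free intercept over
  points with species fraction below `max_fraction` (default 0.20, at
  least three points). The free intercept absorbs dead time and lag. For
  a saturating progress curve the slope over a window reaching fraction f
  underestimates the true initial rate by about f/2; the tests assert this
  bias structure against the analytic slope.
- **Michaelis–Menten fit**: unweighted nonlinear least squares on v0/[E]
  versus [S], replicate points entered individually, efficiency computed
  as k_cat/K_M, never fit separately. Optimiser tolerances are tightened
  to 1e-12 with Jacobian scaling because k_cat and K_M can differ by five
  orders of magnitude. Standard errors use an HC3 sandwich covariance:
  band noise is multiplicative, so residual variance grows with the rate
  and the plain least-squares covariance understates the k_cat
  uncertainty; the sandwich keeps the unweighted point estimates while
  restoring near-nominal confidence-interval coverage.
- **Abortive fraction**: computed from initial rates (an endpoint-based
  variant exists behind `abortive_fraction_endpoint`). In the pipeline the
  intermediate and sealed rates are pooled over substrate concentrations
  before the ratio — the branch ratio is substrate-independent under the
  no-rebinding contract, so pooling only averages noise.
- **Fidelity report**: all fold changes, relative parameters,
  discriminations, the fidelity increase and F_lig ratios are carried at
  full precision and rounded to 2 significant figures only at
  presentation (`FidelityReport.table`). Reconstructing the report from
  *rounded published inputs* can differ in the last digit from statistics
  the original analysis computed at full precision (e.g. a variant
  discrimination of 59.4 versus a printed 60).
- **Active-site titration**: continuous two-segment model y = a·min(x, x₀)
  with a hard plateau, fit by profiling the breakpoint over every interval
  between sampled concentrations with bounded scalar minimisation (the
  model is smooth in x₀ within each interval). A breakpoint outside the
  sampled range raises an unidentifiable-titration error; an active
  fraction above 1.1 is flagged. A data point exactly at the breakpoint
  belongs to the rising segment (the two segments agree there, so the fit
  value is unaffected).

## Expansion index

The index of a trace relative to a reference repeat is: (1) discard peaks
below 5% (configurable) of the tallest peak of the whole trace, with >=
at the boundary; (2) keep peaks above the reference; (3) normalise
retained heights to sum one; (4) weighted mean repeat-unit gain. Declared
conventions, each configurable:

- the threshold is relative to the tallest peak of the whole trace, not of
  the expansion tail, and is applied before the above-reference
  restriction;
- normalisation weights cover retained above-reference peaks only (a
  signed instability mode that includes contractions sits behind
  `signed=True`, off by default);
- the modal allele is the tallest peak, exact ties broken toward the
  smaller repeat;
- bp-to-repeat conversion is `round((bp − offset)/3)` with
  height-summed merging of collisions; no fractional repeats;
- cohort indices are referenced to each mouse's liver modal allele (the
  liver contains a repeat-stable population whose modal length tracks the
  inherited allele), with `self_modal` as the alternative.

The index is translation-invariant in repeats, scale-invariant in heights,
and strictly increases when an above-threshold peak is added above the
reference; the implementation is checked against a literal brute-force
implementation of steps (1)–(4).

Cohort comparisons run per age × tissue stratum: one-way ANOVA across
genotypes plus Tukey-adjusted pairwise contrasts, with significance tiers
at 0.05 / 0.01 / 0.001 / 0.0001. Strata without at least two groups of two
observations are skipped with a warning.

## Cell-assay statistics

- **Viability**: technical replicates are averaged first; each biological
  replicate is expressed as a percentage of its own untreated (dose 0)
  mean within its group × recovery stratum; mean ± SD are over biological
  replicates only. Missing untreated wells are an error naming the
  stratum.
- **Mutation frequency**: per-replicate baseline (0 µM) normalisation,
  summarised afterwards. The per-replicate choice (rather than
  normalising to the mean of all baselines) is a declared convention.
- **Two-way ANOVA**: fixed-effects model with interaction, type-II sums
  of squares, balanced designs required (empty cells raise rather than
  silently re-weighting), Tukey comparisons over cell combinations.
- **2^−ΔΔCt**: per-sample ΔCt is the target Ct minus the geometric mean of
  three housekeeping Ct values; ΔΔCt subtracts the control group's
  geometric-mean ΔCt, matching the stated procedure. A geometric mean of
  ΔCt values is undefined when they cross zero, so an arithmetic
  reference is available (`reference_mean="arithmetic"`); all-zero
  control ΔCt maps to reference 0.

## Synthetic-data generators

Every generator is seed-deterministic (one `numpy` generator per call, no
global state) and records its ground truth so downstream estimates can be
scored as recoveries.

- **Ligation lanes**: band intensities proportional to simulated species
  with a per-lane gain (uniform 0.8–1.2, recorded) and multiplicative
  lognormal noise per band (mean-1 factors; intensities are strictly
  positive, default CV 5%).
- **Titration**: product = min(active_fraction × nominal, DNA) plus
  multiplicative noise; the grid must bracket the breakpoint.
- **Repeat traces**: a `stable_fraction` of cells keeps the inherited
  repeat (~111 CAG for the knock-in allele); the rest gain repeats with a
  discretized gamma distribution (right-skewed, mean and dispersion
  parameterised separately) — the true tail distribution is not known, so
  the gamma is a stand-in chosen for its qualitative trace shape. PCR
  stutter is modelled downward only (the dominant artifact direction for
  CAG repeats) with geometric decay per unit. The exact gain mass
  function and the threshold-free true index are recorded.
- **Viability plates / MF tables / Ct tables**: known effect tables with
  multiplicative lognormal well noise (additive normal on Ct, which is a
  log-scale quantity already).

What the generators do *not* emulate: raw electropherogram signal (peaks
only), plate-edge and spatial effects, biological-replicate random
effects (noise is per-well), PCR efficiency differences between amplicons,
and sequencing-read level noise. Passing recovery tests therefore
demonstrates the correctness of the estimators under the stated noise
structure, not robustness to every artifact of real data.

## Problem sizes and calibration checks

The validation suite uses: a 6-point substrate grid (25–800 nM) bracketing
K_M, 10 post-transient time points, 3 replicates at 5% band CV with 100
seeded trials for confidence-interval coverage; 20-point titrations;
1,000 random peak tables for the expansion-index oracle; 20 mice per
genotype for the simulated ~15% genotype effect; and 200 null simulations
each for the one-way (cohort) and two-way (plate) type-I calibrations at
α = 0.05.

The two-way null calibration runs on raw plate signals. Normalising each
biological replicate by its own noisy untreated mean induces positive
correlation across doses within a replicate (a shared divisor), which
inflates the genotype main-effect F under the fixed-effects model; the
percent-of-untreated scale is the right presentation scale but not a clean
null for this ANOVA. A mixed model with a replicate random effect would
address this and is out of scope.

## Known limitations

- No global multi-curve fitting of microscopic rate constants, no
  single-turnover burst analysis, no Mg²⁺/ATP dependence.
- Gel inputs are background-corrected band volumes; no densitometry.
- Peak tables are consumed as called peaks; no size-standard calibration
  or peak calling from fluorescence curves.
- The unbalanced-design rejection in the two-way ANOVA is deliberate;
  unbalanced data need a modelling decision the package refuses to make
  silently.
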