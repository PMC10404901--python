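# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limitations of `dyadisc`.

## The dyadic ISC model

For subjects i < j and region p, the response similarity is the Pearson
correlation `r_ijp` between the two subjects' region-mean time series over
the concatenation of the runs available to *both* subjects.  Correlations
are variance-stabilized with the Fisher transform `z = arctanh(r)` and then
z-scored across retained dyads within each region (sample SD, ddof = 1), so
each region enters the model on a common scale.  Dyads whose members share
fewer than `min_overlap_runs` runs (default 1) are dropped and logged; a
run-exclusion bookkeeping (who lost which run, and why) travels with the
subject objects.

Dyadic observations are non-independent: subject i appears in n − 1 dyads.
The model follows the established doubled-data device for symmetric dyadic
outcomes: each dyad contributes two rows, (i, j) and (j, i), and the model

    z = X beta + b1[participant_1] + b2[participant_2] + eps

is fit by REML with two *crossed* random-intercept factors, one per member
role, each spanning all subjects.  The fixed part is an intercept plus
either the 3-level Anna-Karenina group factor (treatment-coded against the
NN reference) or the dyad's maximum trait value, plus optional covariates.
The response and all continuous predictors are z-scored using moments
computed over unique dyads (so the redundant doubling cannot bias the
scale, and standardizing before or after doubling is equivalent); 0/1
indicators and the group factor are left unscaled — z-scoring a 3-level
factor is ill-defined, so contrasts are reported in SD units of the
standardized response, which is the interpretable standardized-beta
reading.

### Inference on doubled data

Three corrections make tests on the redundant doubled data honest:

1. **Degrees of freedom.** All t tests use df = N − k, the number of
   *unique* dyads minus the number of fixed effects, not the doubled row
   count.
2. **Covariance of the fixed effects.** Each dyad's two rows carry an
   identical response, so the model-based covariance double-counts
   information.  The default covariance is the sandwich implied by the
   symmetric dyadic truth, `A^-1 X'W^-1 V W^-1 X A^-1` with
   `V = sa^2 G G' + se^2 (I + D)`, where G is the subject incidence over
   both roles and D pairs each row with its mirror.  When the two role
   variances are equal, `V = se^2 (I + D) W`, and for dyad-level covariates
   the sandwich reduces *exactly* to twice the model-based covariance; for
   role-attached covariates (each member's network degree) it is the
   correct generalisation.  Without this correction the nominal 5% test
   rejects ~16% of the time under the null.
3. **Planned contrasts.** LL−NN, LL−NL and NL−NN are estimated-marginal-
   mean differences; covariates are held at their means and cancel in the
   differences, so the contrast vectors act on the group dummies only.
   The standard error of a contrast c is `sqrt(c' Vcov c)`.  p-values are
   two-sided by default with the estimate's sign reported separately
   (directional one-sided output is a configuration flag), because the
   directional hypothesis (lonelier dyads → smaller ISC) is a prediction
   about the sign, not about the sidedness of the test.

REML estimation profiles the fixed effects and the residual variance out
of the criterion and optimizes the two variance *ratios* g = (s1^2/se^2,
s2^2/se^2) with L-BFGS-B on bounds [0, 1e6] from two starting points
((0.05, 0.05) and (1, 1)); non-negativity is enforced by the bounds, not by
clipping.  Every criterion evaluation uses the Woodbury identity, so its
cost is one Cholesky factorization of an (2n × 2n) matrix in the number of
subjects n, independent of the number of dyads — fitting 214 regions for 66
subjects takes seconds.  The fit is verified in the test suite against
statsmodels' MixedLM with crossed variance components (coefficients, SEs,
variance components and the REML log-likelihood agree to ~1e-4, the
optimizer tolerance of the reference), and against OLS when the variance
ratios are fixed at zero.  The estimator also accepts fixed variance
ratios, used both for that oracle and for degenerate-data handling.

### Multiplicity

BH step-up adjustment is applied across regions separately within each
contrast family (the three contrast maps are reported separately, so each
is its own family; a pooled family is a configuration choice away).
Regions skipped as degenerate (constant ISC column, singular design,
non-convergence) are excluded from the family size, so m counts performed
tests.  The adjustment is implemented directly (the explicit family-size
argument is part of the contract) and is tested against both a brute-force
step-up oracle and statsmodels' `multipletests`.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
fMRI physics.  Per region and run a unit-variance Gaussian shared signal
s(t) is drawn (independent across regions and runs, common to all subjects
within a run), and subject i's response is

    y_i(t) = w_i s(t) + sqrt(1 - w_i^2) * noise_sd * eta_i(t),

so with `noise_sd = 1` the population correlation of a dyad is exactly
`w_i w_j` — the simplest generative model whose pairwise structure shows
the Anna-Karenina pattern (similarity limited by the less attuned member),
with E[ISC] analytically known for testing.  Attunement is
`w = clip(attunement_max - attunement_slope * z(total), 0, 1)` in affected
regions and `attunement_max` elsewhere, with the trait standardized by the
generator's *target* mean/SD so the ground truth is configuration-
determined, not sample-determined.

Study-condition defaults: 66 subjects, 214 regions (200 cortical + 14
subcortical labels), 4 runs of 1,125 samples (~60 min at 0.8 s sampling),
trait totals from a truncated normal targeting mean 15.91 / SD 4.879 on the
8–32 scale (rounded; the asymmetric truncation shifts the realized moments
slightly, which the tests account for), ages 18–21, and a directed
friendship network with Poisson out-degrees (mean 5) optionally coupled
log-linearly to the trait (decoupled by default, so objective and
subjective disconnection can be manipulated independently).
`attunement_max = 0.75` and `attunement_slope = 0.15` were chosen for
statistical power at the study's size; the slope keeps w strictly below 1
across the whole 8–32 score range (a larger slope clips at w = 1 and
produces degenerate r = 1 dyads), and no published effect size exists on
this scale.  Item responses are a uniform random composition of the total
into 8 items in [1, 4], so item-total consistency is exact by construction.

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation, scanner drift, motion artifacts, cross-region dependence,
and non-Gaussian traits.  Passing tests therefore demonstrate correctness
of the statistical machinery under the assumed model, not robustness to
fMRI noise structure.

## Numerical and policy choices

- Fisher transform at |r| = 1 raises by default; an opt-in clip to
  1 − 1e-6 exists for degenerate synthetic cases.  Perfect correlation in
  real data signals a data error.
- Dyads are keyed by the sorted subject pair and kept in that canonical
  orientation until the explicit doubling step; every dyad-level
  derivation is member-order invariant (property-tested).
- Median split: "lonely" is strictly above the sample median
  (mean-of-middle-two for even n); ties at the median are nonlonely.  An
  explicit threshold reproduces a fixed published split.
- Friendship is a nomination in either direction by default
  ("reciprocal-only" is a flag); degrees count distinct nominations.
- Member-level degree covariates attach to the roles of the doubled design
  (out_degree_1 is participant_1's degree), keeping estimates invariant to
  member labelling; a dyad-sum encoding would be an alternative.
- Time-series files are tab-separated, written timepoints × parcels with a
  single header row of parcel labels, `%.17g` formatted and read with
  round-trip float parsing, so writer → reader is bit-exact.
- Degenerate regions are skipped and logged, never fatal; a zero response
  yields an all-zero fit with zero variance components.

## Problem sizes used in validation

The validation suite and the acceptance script use scaled study sizes
chosen to exercise every code path at full statistical fidelity: ~500-dyad
designs (33 subjects) for the oracle, recovery (100 replicates) and
type-I (1,000 replicates) checks; 50 replicates of 20-region null studies
(40 subjects) for the pipeline-level FDR check; T = 10,000 for the
generator's closed form; and a 40-subject, 20-region, T = 2,000 study for
end-to-end detection.

## Known limitations

- The manual df = N − k correction overstates the effective degrees of
  freedom whenever subject-level variance is material, because the
  precision of group contrasts is then governed by the number of
  *subjects*, not dyads.  The tests are well calibrated at the 5% level
  (empirical size ~0.04–0.06 under zero subject variance), but the far
  tail of the t reference is anticonservative when the shared signal is
  strong (with ~22% subject-level variance share, P(p < .0025) is ~3×
  nominal).  FDR across many regions operates in that far tail, so the
  pipeline-level false-discovery proportion on strongly shared null data
  runs above the nominal 5% (~9% in the measured configuration).
  Satterthwaite or Kenward–Roger df would repair this but are deliberately
  out of scope: the implemented df rule is the method under study.
- The two role variances are estimated separately; the symmetry of the
  doubled data makes them converge to near-equality rather than being
  constrained equal.
- Leave-one-out (one-vs-mean) ISC, intersubject functional connectivity,
  dynamic ISC, and permutation-based inference are out of scope.
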