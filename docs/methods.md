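# Methods

## Structural model

Meropenem disposition is described by a mamillary three-compartment linear
model: a central compartment (volume `V`, L) receiving zero-order infusion
input and cleared at `CL` (L/h), a non-observed peripheral compartment, and
an epithelial-lining-fluid (ELF) compartment treated as homogeneous with
volume `V_ELF` (L).  All intercompartmental transfers are first order
(`K12, K21, K13, K31`, 1/h).  The ELF compartment is assigned to the third
state and exchanges with central only; this choice makes the single ELF
volume interpretable and matches the convention that the observed site gets
its own volume.  Whether ELF exchanges exclusively with central cannot be
resolved from the data; treating it as a mamillary branch is the simplest
structure consistent with one ELF observation per subject and is the one
assumption a sensitivity analysis should revisit first.

Concentrations are totals; free fractions (0.98 plasma, 1.0 ELF) are applied
only in the pharmacodynamic layer, never in the solver.

### Solver

The system matrix is constant within any interval of constant infusion rate,
so the state is propagated exactly per segment via the eigen decomposition:

    a(t0 + dt) = P e^{Λ dt} P⁻¹ a(t0) + R · P Φ(dt) P⁻¹ e1,
    Φ_kk(dt) = (e^{λ_k dt} − 1)/λ_k   (dt as λ_k → 0)

Breakpoints are inserted at every event start/end; contiguous equal-rate
segments (back-to-back 8-h bags) are collapsed.  The propagation is
vectorized over parameter vectors, so a 1000-subject Monte Carlo population
is one batched pass.  Subjects whose eigenvector matrix has condition number
above 1e10 (nearly defective systems) fall back to adaptive numeric
integration (LSODA, rtol 1e-10); the same numeric route doubles as the
independent cross-check in the test suite, where the two solutions are
required to agree to 1e-6 relative.

Simulation grids default to 0.1 h, which resolves the 15-min loading dose;
halving the step changes PTA by well under one percentage point in the
packaged checks.  Exposure metrics use the linear trapezoid; daily exposure
is cumulative AUC normalized to 24 h; penetration is
`100·AUC_ELF/AUC_plasma`.  At CI steady state the model implies
`Css_ELF/Css_plasma = (V·K13)/(K31·V_ELF)` — 37.8% at the packaged parameter
medians — and the simulator's post-steady-state AUC ratio reproduces that
identity to 0.5%; observed patient ratios are lower (~30%), consistent with
between-subject variability and finite sampling.

## BAL / urea dilution

BAL recovers ELF diluted 1–2 orders of magnitude by instilled saline.  Urea
equilibrates freely between plasma and ELF, so the serum/BAL urea ratio
estimates the dilution: `MER_ELF = MER_BAL · Urea_ser / Urea_BAL`.  The
correction is exact when assay noise is absent (round-trip identity in the
tests).  A value at the limit of quantification counts as quantifiable
(inclusive boundary, the usual assay-validation convention); censored
analytes raise an explicit censored-result error rather than propagating
silently, and the default fitting policy excludes censored rows (LOQ/2
substitution is available as a table-level option).

## Error model and likelihood

Observations are weighted by the inverse of the estimated assay variance:
each analyte has a linear SD polynomial `sd(c) = c0 + c1·c` with defaults
anchored at LOQ/2 intercept and 15% proportional (the assays' reported
precision bound), inflated by a multiplicative process-noise scalar `gamma`
(initialized at 1, profiled over [1, 10] by golden-section search).  The
subject log-likelihood is Gaussian with SD `gamma · sd(prediction)`.

## Population estimation

The population distribution is a discrete mixture (support points +
weights) maximizing the exact mixture likelihood — the nonparametric
maximum-likelihood estimator family.  `npag_fit` approximates the adaptive
grid search as:

1. scrambled-Sobol initialization of candidate points in the log search box;
2. EM updates of the mixture weights (a concave subproblem; monotone in the
   total log-likelihood, asserted per cycle in the tests);
3. subject-anchored refinement: each subject's best candidate is locally
   optimized against that subject's own likelihood (Nelder-Mead in log
   space, started from both a data-informed moment estimate and the best
   grid point) and added to the grid;
4. cycles of: dropping points below weight 1e-6, merging near-duplicates
   (0.1% relative), perturbing high-weight points with a shrinking
   multiplicative kernel, re-running EM, profiling gamma, and polishing
   dominant points against the mixture likelihood.  The incumbent best
   solution is kept, so the reported cycle trajectory never decreases.

Default search bounds are the packaged mean ± 4 SD per parameter, floored at
1e-3.  Two numerical guards matter in practice:

- **Terminal half-life cap (default 24 h).**  The trial samples a nearly
  flat 8-h window at CI steady state; such data cannot distinguish genuine
  clearance from a no-elimination/huge-effective-volume combination that is
  still accumulating on day 3.  That degenerate corner lies inside the naive
  search box and attracts real mixture weight, biasing clearance low.  The
  study enrolled only patients with conserved renal function (GFR ≥ 50),
  where meropenem's terminal half-life is 1–3 h, so candidate support points
  are required to have terminal half-life ≤ 24 h — an order-of-magnitude
  safety margin, configurable or removable.
- **Moment-based starts.**  Local searches start from `CL ≈ rate/mean(Css)`
  and a `V_ELF` matching the observed ELF/plasma ratio, with remaining
  coordinates at the natural-scale box midpoint (the log-scale midpoint is
  meaningless when a lower bound has collapsed to the positivity floor).

Identifiability: from five plasma samples and one ELF sample per subject at
steady state, only clearance and the ELF partition ratio are strongly
identified; the remaining directions are set-identified.  Even with rich
noise-free sampling the fitted vector is only prediction-equivalent to the
generating one — the tests therefore assert recovery of the identified
functionals (CL, penetration ratio, predictions), not of all seven
coordinates.  MAP-Bayesian individual estimates are posterior modes over the
support; posterior weights follow from Bayes' rule in log space.

## Diagnostics

Bias is the mean prediction error, imprecision the bias-adjusted mean
squared prediction error; the observed-vs-predicted line is ordinary least
squares.  VPC bands are the 5th/50th/95th percentiles of 1000 simulated
datasets; a well-specified model leaves ~90% of observations inside the
5–95 band.  NPDE ranks each observation among its simulated replicates and
maps `(rank + 0.5)/(n_sim + 1)` through the normal quantile function; the
decorrelation step of the reference method is omitted because within-subject
correlation is weakly identifiable with a single ELF point per subject —
consequently NPDE-based tests use cluster-robust (per-subject) standard
errors.

## Virtual population and dosing simulations

Monte Carlo populations (n = 1000 unless stated) are drawn either from a
fitted support (weighted resampling) or parametrically: independent
log-normals per parameter, moment-matched to the packaged mean and SD.
Log-normality is chosen for positivity; parameters are sampled independently
because joint correlations are unpublished (a documented limitation — a
rank-correlation copula can be slotted in when a correlation matrix is
available).  No truncation is applied by default: symmetric ±4 SD truncation
on the natural scale would bias the matched means of the heavier-tailed
parameters by 1–2%, violating the 1% moment-matching contract; a truncation
multiple remains available.  Draws depend only on (sampler, n, seed), so
dose arms compared at a fixed seed share common random numbers and dose
responses are paired.

Regimens are ordered zero-order events; presets cover 2 g/15-min loading
plus 1 or 2 g/8 h CI, 3 g LD + 3 g/8 h CI, 8 g/8 h CI, and 1/2/3 g 4-h
extended infusions.  The efficacy metric is fT>MIC in ELF over 48–72 h
(inclusive endpoints, ties at the MIC count as attainment, linear
interpolation at crossings) against doubling MIC dilutions anchored at
16 mg/L down to 0.002 mg/L; PTA ≥ 90% is the optimality threshold.  The
toxicity metric is the fraction of subjects whose plasma concentration at
the end of ANY 8-h interval in 0–72 h reaches 64.2 mg/L — the "any trough"
reading is deliberate: a patient who ever sustains the toxic trough has
incurred the risk.

## Virtual trial generator

The generator reproduces the study design: 16 + 15 subjects on the two CI
arms; day-3 plasma samples pre-infusion and 1.5, 3, 6, 8 h after the start
of the monitored bag (pre-infusion encoded as the 48-h trough); one ELF
sample at 6 h.  The BAL dilution factor is log-uniform over [10, 100]
(conventional BAL dilution range; the study does not report one) and serum
urea is log-normal with median 40 mg/dL and 40% CV (typical ICU values;
also unpublished).  All measurements get multiplicative Gaussian noise at
the 15% assay precision and pass through LOQ censoring.  The generator
emulates design and noise structure only — it does not reproduce real-data
features such as covariate-driven kinetics, within-day clearance changes,
correlated parameters, or missed/failed samples, so passing recovery tests
demonstrates estimator correctness under the stated design, not robustness
to every clinical artifact.

## Problem sizes and determinism

Monte Carlo results use n = 1000 (matching the published simulations) on a
0.1 h grid; recovery experiments fit 31-subject trials with 256 initial
support candidates and 3 refinement cycles, sizes at which a fit takes
seconds to a few tens of seconds on one core.  Every stochastic routine
takes an explicit seed and is bit-reproducible given (seed, n); CLI runs
record seed, options and package version beside their outputs.

## Known limitations

- Parameter correlations are ignored in the parametric sampler; borderline
  MIC coverage results are sensitive to the unpublished joint distribution.
- The plasma→ELF translation in the dosing simulations uses the model's ELF
  compartment; an alternative seen in the literature (fixed penetration
  ratio applied to plasma) would give slightly different borderline PTAs.
- Below-LOQ observations are excluded from the likelihood rather than
  treated with a censored-data term.
- NPDE omits decorrelation; its null distribution is checked with
  cluster-robust errors rather than per-observation independence.
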