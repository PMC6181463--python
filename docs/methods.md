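# Methods

This note documents the model implemented in `mskpain`, the conventions it
fixes where the underlying design leaves choices open, the synthetic study
conditions, and the numerical decisions that matter for reproducing its
outputs.

## Model structure

The cohort model has four states — mild (VAS 1–3), moderate (VAS 4–6) and
severe (VAS 7–10) chronic pain, plus death from other causes — advanced in
1-month cycles over a 12-cycle horizon (configurable). Transitions are
constant in time and shared across pathologies: aetiology affects who
enters the model and what their management costs, not how severity
evolves. There is no incident inflow during the year and chronic pain
itself causes no deaths, so health loss is carried entirely by the
consequence calculators.

**No half-cycle correction.** Costs accrue on the state occupied at the
start of each cycle. With a 1-month cycle the half-cycle correction would
change annual totals by well under the parameter uncertainty, and plain
cycle accounting keeps every number reproducible by hand; this is a
declared convention, not an oversight.

## Mortality conversion

Background mortality is supplied as a crude annual rate per 1000
population (default 5.1). Treating it as a constant instantaneous hazard,
the monthly transition probability is `1 − exp(−r/12)`; for 5.1/1000 this
is 0.4249 per 1000, printed as 0.42. A separate converter
`annual_to_monthly_prob` implements the probability-to-probability form
`1 − (1 − p)^(1/12)` for inputs that are genuine annual probabilities; the
two differ in the third decimal at these magnitudes but are not
interchangeable. Mortality competes multiplicatively with severity
transitions: living rows are renormalized to 1 and scaled by
`1 − p_death`, which keeps every row stochastic whatever the elicited
numbers were.

## Expert elicitation and pooling

Six questions cover the off-diagonal living transitions (mild→moderate,
mild→severe, moderate→mild, moderate→severe, severe→mild,
severe→moderate); each row's stay-put probability is the complement of its
two exits. Each question is answered by a panel (13 experts by default) as
a normalized histogram over a 21-option probability grid. Only the number
of options is fixed by the reference design; their placement is not, so
the package adopts the **even-midpoint convention**: the grid is the
midpoints `(i + ½)/21` of an even partition of [0, 1]. Panels are
aggregated by a linear opinion pool with equal expert weights (weights are
configurable; no performance-based weighting is attempted). The pooled
object is treated as a weighted support of expert × bin options — 273 per
question — whose mean is the expected transition probability and whose
empirical distribution is resampled directly in the PSA. Resampling the
pool rather than fitting a parametric family preserves whatever
multimodality or skew the panel expressed.

Because independently elicited destination probabilities need not be
coherent, each living row is renormalized to sum to 1 before the mortality
rescaling. Negative entries are rejected rather than clipped.

## Synthetic study conditions

The generator (`mskpain.synthetic`) emulates a complete parameter table;
its defaults are the package's study conditions and are fixed once:

| Parameter | Default | Rationale |
| --- | --- | --- |
| Pathologies | knee/hip osteoarthritis, lower back pain, chronic shoulder pain, myofascial syndrome, fibromyalgia | the six-pathology reference design |
| Adult population | 13,000,000 | adult population of a Chile-sized country |
| Prevalence per pathology | uniform draw in [0.01, 0.08] | chronic-pain pathology prevalences of a few percent of adults |
| Severity split | Dirichlet around (0.45, 0.40, 0.15), concentration 50 | most prevalent cases mild/moderate; severe a minority |
| Myofascial split | consultation fractions (0.075, 0.35, 0.60) normalized | the pathology was absent from the severity survey (see below) |
| Transition truth | mild→mod 0.15, mild→sev 0.03, mod→mild 0.20, mod→sev 0.10, sev→mild 0.05, sev→mod 0.25 | monthly movements with net improvement under usual care from the severe state |
| Expert panels | 13 experts, 21 bins, concentration 30 | reference panel size; concentration gives realistic disagreement (histogram SDs ≈ 0.08) |
| Mortality | 5.1 per 1000 per year | published national crude rate |
| Cost baskets | reference baskets totalling 63.5 / 101.82 / 734.5 USD per patient-month | the published per-state management costs; severe includes the 90% emergency-visit probability and a 25% hospitalization admission share |
| Depression background | 17% of the population | national-survey-scale depression prevalence |
| Depression RR | OA 1.0 (PAF structurally zero), LBP 2.0, shoulder 1.8, myofascial 1.6, fibromyalgia 2.5 | the OA zeros are a stated assumption; the others are plausible survey cross-tab magnitudes |
| Productivity | per-pathology leave episodes/days, daily wage 25,000 CLP, system-paid fraction 0.7 | medical-leave volumes at national scale; myofascial syndrome structurally zero |

Expert histograms are discretized betas: expert *e*'s mean is drawn from
`Beta(pκ, (1−p)κ)` (so the panel-level expectation is the true value *p*),
and their histogram is the beta with that mean and concentration κ
integrated over the bin edges. As κ → ∞ every expert collapses onto the
bin containing *p*. Discretization onto 21 midpoints biases the recovered
mean by at most a few thousandths for interior *p*; the parameter-recovery
tests bound the total error at ±0.02 with 200 experts.

What the generator does **not** emulate: real prevalence gradients by age
and sex, cost heterogeneity across insurers or regions, correlation
between parameters (experts who are optimistic about one transition being
optimistic about another), or non-beta-shaped expert opinion. Passing
tests therefore demonstrate that the machinery is correct under known
ground truth, not that any specific national estimate is right.

## Interpretation conventions

**Undiagnosed scenario.** The reduced-diagnosis scenario sets diagnosed
fractions to (0.5, 0.75, 1.0) for mild/moderate/severe. Undiagnosed
patients are excluded from the cost-incurring modelled cohort (undiagnosed
= unmanaged, which is why the scenario lowers costs) but remain in the
prevalence counts, and the burden calculators (YLD, depression, anxiety)
run on the full prevalent population: disability does not vanish with
non-diagnosis.

**Myofascial consultation fractions.** The suggested consultation
fractions (7.5% mild, 35% moderate, 60% severe) are stated in the context
of that pathology's initial distribution, but the mapping to a severity
split is not given. Both readings are implemented behind
`ScenarioConfig.mfs_split_mode`: `normalized_consult` (default) uses the
normalized fractions as the severity split; `multiplier` treats them as
the cost-incurring share of each state's occupants. The default is flagged
as an interpretation, not a given.

**Depression attribution.** The PAF uses Levin's formula with exposure
prevalence = pathology prevalence × (moderate + severe) severity share, so
mild-pain patients never contribute to attribution; the fraction is then
applied to the national background depression pool. Relative risks of
exactly 1 are held fixed in the PSA — they encode the structural
assumption of zero attributable cases for osteoarthritis, not an
uncertain estimate.

**YLD convention.** Default is the prevalent-year frame: prevalent cases ×
1 year × disability weight × pain-domain fraction, consistent with the
annual expected-cost horizon. An incidence × multi-year-duration mode is
available by supplying incident counts and `duration_years` in the
bundle. The pain-domain adjustment is a single multiplicative fraction per
pathology.

**Structural zeros.** A consequence that cannot be estimated (myofascial
productivity loss, invisible to the ICD-10-coded leave database) is
carried as `None`/NaN with a `structural_zero` flag through every report,
so it can never be confused with a computed zero.

## Sensitivity analysis

PSA distributions are assigned by family convention — beta for proportions
and probabilities, gamma for costs, counts and relative risks, Dirichlet
for severity splits (concentration 100), pooled empirical densities for
transitions — moment-matched around the bundle's point values with
coefficients of variation 0.10 (beta) and 0.20 (gamma). These spreads are
the package's defaults, chosen once as typical of cost-effectiveness
practice, and are fully overridable through `CostConsequenceModel.distributions`.
All parameters are sampled independently (no correlation structure is
specified anywhere), in sorted-name order from a single seeded generator,
which is what makes a fixed seed reproduce the analysis bit for bit.

Credibility intervals are equal-tailed percentile intervals with linear
interpolation between order statistics (the numpy default); HPD intervals
are deliberately not used because they are not unique under
transformation and harder to reproduce. Both the deterministic point
estimate (model at parameter means) and the mean of samples are reported,
since published tables do not always say which convention they print; for
this nonlinear pipeline the two differ by a few percent.

One-way sensitivity analysis re-evaluates the full pipeline at low, base
and high values of a single scalar parameter (default ±20% of base);
vector parameters (severity splits) are excluded from tornado tables
because a one-dimensional swing is not well defined for them.

## Numerical and degenerate-input choices

- Row-stochasticity and conservation tolerances: 1e-9 for matrix rows and
  weight sums, 1e-6 for cohort conservation over the trace.
- Expert histograms whose discretized beta underflows (extreme means with
  high concentration) fall back to a point mass on the nearest bin.
- `beta_from_mean_sd` shrinks an infeasible variance (≥ m(1−m)) to half
  the feasible maximum; zero-spread or boundary means collapse to fixed
  (degenerate) distributions, which the PSA passes through unchanged.
- Bundle CSVs are written with full float repr and read back with
  pandas' `float_precision="round_trip"`, making the directory format
  lossless and regeneration byte-identical under a fixed seed.
- Problem sizes: the default analysis is 6 pathologies × 12 cycles with
  5000 PSA iterations (~5 s on one CPU); the test suite uses smaller
  iteration counts except where the 5000-iteration properties themselves
  are under test.

## Known limitations

- Early retirement and presenteeism are out of scope (not measurable in
  the source design), as are aetiology-specific transition matrices,
  incident inflow during the year, discounting (irrelevant at a 1-year
  horizon), and value-of-information analysis (no comparator exists in a
  cost–consequence design).
- The "21 × 21" construction behind the pooled density is underspecified
  in the reference design; the expert × bin weighted-support reading
  implemented here is an interpretation and is flagged as such.
- GDP shares are computed only against a user-supplied denominator; the
  package does not ship a GDP series.
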