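# Methods

## The model

The package implements an individual-level (micro-simulation) Markov
model for metabolic-syndrome disease progression with annual cycles and
nine mutually exclusive health states: `at_risk`, `diabetes`,
`diabetes_micro`, `diabetes_macro`, `mi`, `stroke`, `chd`, `chf`,
`dead`. Non-diabetic participants start at risk; participants with
diagnosed diabetes start in the diabetes state carrying their recorded
years-with-diabetes, which then advances by exactly one per diabetic
cycle. The packaged topology allows at-risk participants to develop
diabetes or any cardiovascular event; diabetic participants to develop
micro- or macro-vascular complications or events; event and complication
states are chronic (self-loop) until death, which is reachable from
every state. The topology is configuration data
(`statespace.HealthStateModel`), so post-event history states or other
edge sets can be expressed without code changes.

No half-cycle correction is applied: transitions and accrual happen on
annual boundaries, and the first cycle (t = 0) is undiscounted. These
are the conventions of the decision-tree software family this model
style comes from.

### Transition probabilities

Each cycle, the occupied state's permitted successors get probabilities
from the active risk-equation set evaluated at the participant's current
covariates; death receives at least the abridged-life-table probability
for current age and sex plus a per-state constant excess; the residual
mass stays. If cause-specific probabilities ever sum beyond 1 the
outgoing distribution is normalised jointly (logged); the outgoing row
is a distribution by construction, verified each cycle.

Equations whose published forms report multi-year risks (e.g. a 7.5-year
logistic incidence risk) are converted to annual probabilities by
inverting the compounding identity, `1 − (1 − p)^(1/h)`, i.e. assuming a
constant hazard within the native horizon.

Supported functional forms: `logistic`, `weibull_hazard`
(proportional-hazards cumulative risk, the UKPDS-outcome style),
`framingham_accumulator` (the Anderson-1991 accelerated-failure-time
style), and `linear` (test scaffolding). Two named sets ship:
`default` (Framingham/San Antonio/UKPDS-style forms) and `swedish`
(an alternative-source battery for the multivariate sensitivity
analysis). **Their coefficients are synthetic**: the original
evaluation's exact parameterisation lives in an unpublished technical
report, and transcribing the source publications from memory would
misrepresent them. The packaged values are calibrated only to plausible
event-rate magnitudes for a middle-aged metabolic-syndrome population
(diabetes onset ≈ 3%/year, individual CVD events ≈ 0.2–1%/year) and are
flagged as replaceable in the config files. Everything that depends on
the real parameters is therefore checked at order-of-magnitude level
only; all exact checks run on the published tables' own arithmetic.

### Simulation modes

`cohort_expectation` (the default for analyses) propagates the joint
distribution over (state, years-since-diabetes-onset) forward and
returns exact discounted expectations; tracking the onset-time
dimension keeps duration-dependent complication equations exact.
`montecarlo` samples trajectories (default 10,000 repetitions) with one
RNG stream per participant derived by stable hashing from the master
seed, so enlarging a cohort never perturbs existing participants'
draws. Common random numbers across a participant's with-study and
reference runs are on by default (one uniform per repetition per cycle,
drawn unconditionally, so the two runs consume identical streams); this
reduces the variance of within-participant differences without bias and
can be disabled. The two modes are tested against each other and against
closed forms; expectation mode is preferred for the analyses because it
computes the same estimand with zero Monte-Carlo error at lower cost.

## Economics

Per-state annual costs are stated in SEK at a declared price year across
seven components (medical treatment, institutional care,
pharmaceuticals, community care, informal care, other patient/relative
costs, productivity loss). The societal perspective sums all seven; the
health-care perspective counts medical treatment + pharmaceuticals +
community care, a strict subset, so health-care cost ≤ societal cost for
every state by construction. Costs are CPI-inflated to 2012 and
converted at 6.57 SEK/US$. Utilities are absolute per-state QALY
weights (states are mutually exclusive, so no comorbidity composition
arises); the dead state has zero cost and utility, enforced at
validation. The packaged cost/utility tables are synthetic placeholders
at plausible magnitudes, labelled as such in the config. The
"other patient/relative costs" component exists in the schema but
defaults to zero (out-of-pocket exercise costs were explicitly not
counted in the evaluation this models).

## Synthetic cohort

The generator emulates the trial's published participant table:
group-wise means/SDs for the continuous risk factors and proportions for
sex, diabetes and smoking at each of the three waves, arm sizes 71/74,
and 17% monotone attrition by year 3 (88% of dropouts already missing at
year 1, matching the published wave counts). Continuous fields are
truncated-at-zero normals per wave; an optional Gaussian-copula
cross-field correlation hook exists but defaults to independence because
only marginals are published. Sex and diabetes status are drawn at
baseline and carried (a diabetic cannot revert); smoking is re-drawn per
wave against the wave's proportion. Diabetes duration was published as
median (SD); the median serves as the location of a truncated normal for
diabetics, and durations advance with elapsed time. Ages advance
deterministically between waves and are never imputed.

What the generator does **not** emulate: within-person correlation of a
risk factor across waves (each wave is an independent draw around its
wave mean), cross-field physiological correlation (unless the copula is
configured), non-monotone item non-response, and any treatment-effect
heterogeneity beyond what the wave means encode. Consequently the
synthetic cohort reproduces the published *marginal* trajectories but
not the trial's per-participant change scores, and simulated DD
magnitudes on it are illustrative rather than estimates of the trial's
results — with independently drawn waves, per-participant differences
carry substantial noise, and the sign of a small DD can differ from the
published one. Passing tests therefore demonstrate the correctness of
the machinery (generation to marginals, LOCF/MI behaviour, simulation
closed forms, DD/bootstrap/ICER arithmetic), not recovery of the
published cost-effectiveness magnitudes, which depend on the
unavailable true parameters and real participant data.

### Missing data

Base case: last observation carried forward per field (age excepted),
idempotent, never altering observed values, requiring complete
baselines. Sensitivity: chained-equations multiple imputation
(statsmodels `MICEData`, predictive mean matching) run separately within
each arm on a wide per-participant layout; every imputation conditions
on the baseline measurements plus age and sex. Baseline-only predictor
sets keep the chained system well-posed under monotone participant-level
attrition (follow-up waves are missing together, so conditioning
follow-up on follow-up is circular); on very small arms the predictor
list is truncated, same-field baseline first, to retain residual degrees
of freedom. PMM donates observed values, so positivity is automatic and
binary fields receive observed 0/1 donations (rounded defensively);
imputed non-diabetics get duration zero. Estimates across the m
completed datasets are pooled by Rubin's rules: pooled point = mean of
points, pooled variance = mean within-variance + (1 + 1/m) ×
between-variance.

## DD and cost-effectiveness

The DD estimator is pure group-mean arithmetic over the four scenario
runs; no regression adjustment. The with-study scenario holds the
scenario wave's risk-factor levels (including its recorded diabetes
duration) from baseline age onward; effect-duration variants revert to
baseline levels k years after the 3-year intervention ends (reversion
cycle 3 + k; "immediate" reversion is cycle 3). Bootstrap CIs resample
participants with replacement within each arm (sizes preserved), 1,000
replicates, percentile 2.5/97.5. ICERs add the US$211 programme cost to
the intervention side once per participant and are reported truncated
(floored) to whole dollars — the only rounding rule consistent with all
the published ratios. Classification: negative incremental cost without
QALY loss is cost-saving (no ratio); positive ratio vs both thresholds;
QALY loss with net cost is dominated; zero QALY difference with net cost
yields an explicit "ratio undefined" signal.

The mean-value sensitivity analysis (one "average participant" per arm)
represents the categorical covariates by four weighted pseudo-participants
per arm ({male, female} × {diabetic, non-diabetic} at baseline
prevalences) rather than binarising prevalence at 50%, with smoking
entering as its fractional prevalence; this avoids knife-edge behaviour
at prevalences near one half.

## Problem sizes and numerical choices

The packaged analyses use the full 145-participant synthetic cohort in
exact expectation mode (base case ≈ 5 s; the fourteen-row battery with
m=10 imputations ≈ 3 min on one core). The test suite uses scaled-down
cohorts (4–30 per arm) and shortened horizons for orchestration tests,
and the trial's own arm sizes where the statistical property under test
needs them (bootstrap coverage at 71/74). Monte-Carlo/expectation
equivalence is verified at 50,000 repetitions on the full topology.
Occupancy conservation is asserted every cycle at 1e−9; the geometric-
series oracle is checked at 1e−10; bootstrap coverage at 95% ± 2% over
500 replicates.

## Known limitations

- Packaged risk/cost/utility parameters are synthetic; all quantitative
  claims about the real intervention rest on the published tables, which
  the package reproduces arithmetically, not on re-simulation.
- One published sensitivity row (year-1 factors held; US$836/QALY) is
  internally inconsistent with its own cost/QALY columns under any
  rounding rule; the desk-check script reports the recomputed value
  (US$2,508/QALY) and does not treat the printed one as a target.
- A published long-term CI is printed with inconsistent signs in
  different places; the abstract's version (−19,700 to −1,000) is taken
  as authoritative.
- No within-cycle event sequencing, no tunnel states beyond the diabetes
  duration counter, no half-cycle correction, single-occupancy states.
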