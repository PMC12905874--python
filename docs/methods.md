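# Methods

## Model structure

The model is a two-arm, one-year decision tree for a cohort of
75-year-old adults with heart failure (HF) and cognitive impairment.
The decision node chooses between the pictorial-medication-sheet
intervention and usual care; chance nodes then resolve, in order,
adherence status (good = pill-count adherence ≥ 80%), hospitalized HF
exacerbation, survival, and — among exacerbation survivors — worsening
versus recovery. Each arm therefore has exactly ten terminal paths:
{good, poor} × {exacerbate→die, exacerbate→survive→worsen,
exacerbate→survive→recover, no-exacerbation→survive,
no-exacerbation→die}. Path probabilities are branch products; they sum
to one by construction and the suite asserts this to 1e-12.

A plain tree (no within-year cycling, no half-cycle correction) is
adequate because all transitions are annual and the horizon is short;
nothing is discounted.

## Parameters

Eighteen tabulated inputs (seven clinical probabilities, three
health-state utilities, eight costs in 2025 USD) ship as a bundled,
schema-validated YAML file, each with a base value, a low/high range,
the range's basis (95% CI, assumed ±25% or ±50%, or a literature
min–max), and a distribution family. Constants: willingness-to-pay
$150,000/QALY, 1000 PSA iterations, death at month 6, one-month
exacerbation, hazard ratio 1.81 for hospitalization under poor
adherence, cohort age 75.

Two derived quantities are always recomputed, never stored: the
intervention arm's good-adherence probability (usual care + gain, capped
at 1) and, optionally, the poor-adherence exacerbation probability from
the good-adherence one via the hazard ratio applied multiplicatively on
the probability scale (0.232 × 1.81 = 0.420, tabulated as 0.419). The
multiplicative-on-probability convention is used because it is the one
that reproduces the tabulated pair; a rate-based conversion would give
a slightly different value and is deliberately not offered beyond the
documented switch in the PSA.

Distribution fitting is method-of-moments with every stated range read
as a central 95% interval, σ = (high − low)/3.92 — including the
assumed ±25%/±50% ranges, which have no published dispersion convention
of their own; treating them identically keeps the PSA's uncertainty
model uniform. Betas are used for probabilities and utilities
(support [0,1]), gammas for costs (positive, right-skewed). A fit whose
implied α or β would be non-positive (range too wide for the mean)
raises a validation error naming the parameter; a zero-width range
degenerates to a point mass. Every fitted mean equals its base value to
1e-6 relative, verified analytically and by 10⁶-draw sampling.

## QALY accrual

Utility values apply proportionally to time in state over the year:

- no exacerbation, survive: full year at u_stable = 0.780;
- exacerbation, survive: one month at u_exac = 0.560, eleven months at
  the destination utility (0.600 worsened, 0.780 recovered);
- any death: half a year at u_stable (0.390 QALYs).

The decedent convention deserves comment because the source analysis
states only that deaths occur mid-year. Valuing all decedents' half
year at the stable-HF utility is the unique convention among the
plausible candidates that reproduces all three published QALY figures
(0.686 usual care, 0.691 intervention, 0.0045 incremental) in closed
form over the ten paths, and is therefore the default; the two
alternatives (exacerbation month first, then stable or worsened) remain
selectable in `TimingAssumptions`.

A useful structural identity, asserted by the tests: the incremental
QALY equals gain × (Q_good − Q_poor), independent of the usual-care
adherence level. This is why the equity-focused scenario (which lowers
baseline adherence but not the gain) leaves ΔQALY exactly at 0.0045.

## Costs and calibration

The published analysis prices paths from per-event yearly frequencies
that are not printed; only three aggregate figures are: usual-care
total $24,507, incremental saving $1,949, intervention total $22,557.
The default cost engine therefore uses two calibratable aggregates:

- `exac_bundle` — expected cost per exacerbation path (hospitalization,
  emergency department, worsening medications, post-acute care);
- `base_care_annual` — cost per alive patient-year (HF medications,
  outpatient visits), with decedents accruing half a year (mirroring
  mid-year death).

Expected cost is linear in both, so anchoring the usual-care total and
the incremental saving yields a unique 2×2 linear solution (about
$71,052 and $2,385 at base case). The intervention total then *emerges*
as $22,558 — within the $1 rounding of the printed figure — which is
the non-circular consistency check on the whole cost structure. The
implied bundle is roughly twice the unit hospitalization cost,
consistent with repeat admissions and bundled post-acute care, though
the source does not itemize it. An itemized schedule (tabulated unit
costs × user-supplied frequencies) is supported and cross-checked
against the aggregates to 1e-6. The first-year intervention cost ($498;
$400 in subsequent years) is charged to every intervention-arm patient
up front, survival notwithstanding.

In sensitivity analyses the calibrated aggregates are perturbed
proportionally: `exac_bundle` scales with the sampled hospitalization
cost relative to its base, `base_care_annual` with the sampled
HF-medication + outpatient sum. This keeps hospitalization-cost
uncertainty acting on incremental cost only (never QALYs) and avoids
inventing event frequencies the source never published. The sampled
emergency-department, worsening-medication and post-acute costs
consequently do not move the one-year deltas on their own; they are
retained in the table for itemized work.

## Sensitivity analyses

**One-way:** each parameter in turn is set to its low and high bound
with everything else at base, and the full pipeline (arms, utilities,
schedule scaling) re-runs; exactly one primitive differs from base per
run.

**PSA:** 1000 iterations; every tabulated parameter drawn independently
from its fitted distribution (no correlation structure is published);
derived quantities recomputed per draw; both exacerbation probabilities
drawn from their own distributions by default, with an `hr_link` switch
to derive the poor-adherence one instead. One master seed spawns a
deterministic NumPy substream per iteration, so results are
bit-reproducible for a given seed. Samples landing exactly on a plane
axis are classified to the adjacent non-dominant quadrant and noted.
The ICER range is summarized over northeast-quadrant samples only.
Under these conditions about 95–96% of iterations are dominant and
about 99% dominant-or-cost-effective at $150,000/QALY, against the
published 97.3% and 99.3%; the residual gap is within the spread that
reasonable dispersion conventions for the assumed ranges produce.

**Scenarios:** three bundled one-year program variants — richer-better
(intervention cost to $622, gain to 0.278), cheaper-less-effective
(−$200.05, gain −0.093), equity-focused (+$279, baseline adherence
−0.139, gain unchanged) — are parameter overrides on the calibrated
base model; the schedule is not recalibrated.

## Two-year extension

Year-1 survivors re-enter an identical, undiscounted tree in year 2.
Eight scenarios vary the year-2 adherence gain, good-adherence
exacerbation probability, and subsequent-year intervention cost ($400
base) across base/upper/lower levels. Survivors who ended year 1
worsened carry the worsened utility as their alive-state utility in
year 2 but face the same transition probabilities (no state-dependent
risks are published). Year-2 adherence is re-drawn from arm-level
probabilities by default; a persistence switch carries year-1 status
forward. The intervention arm pays the year-2 cost per surviving
entrant.

This reconstruction yields two-year incremental QALYs of roughly three
times the one-year value; the published table prints larger magnitudes
(≈6.5×) whose accrual rule is not recoverable from the text. The
package therefore treats the two-year model as property-checked, not
numerically anchored: all eight scenarios remain dominant, every
two-year ΔQALY at least doubles the one-year value, the
more-effective-lower-risk scenario is extreme in both savings and
QALYs, and a zeroed year 2 collapses exactly onto the one-year result.

## Synthetic data and the microsimulation oracle

Two generators make every stage testable without external data.

*Patient-level simulator:* n independent patients are pushed through
the tree by staged Bernoulli draws and scored with the same per-path
QALY/cost formulas, giving a brute-force estimate of the cohort
expectations. At n = 200,000 the cohort model and simulator agree
within 3 Monte Carlo standard errors for the base case and for random
valid parameter sets; a degenerate tree (all probabilities 0/1) gives
zero variance.

*Synthetic adherence study:* paired pre/post pill-count fractions for
n = 27 subjects emulating the source trial (pre mean 79.7%, post 84.7%,
dichotomized at 80%). Per-subject adherence is beta-distributed matched
to (mean, sd); the default sd = 0.10 is a choice — the source reports
no per-subject spread — picked so the 80% cutoff falls inside the body
of the distribution and the dichotomized proportions land near the
tabulated 0.556/0.741 structure. Pairs share a comonotone latent (one
uniform per subject through both beta quantile functions), the simplest
paired structure; it does not emulate regression to the mean,
measurement error in pill counts, or dropout, so pipeline tests
demonstrate plumbing and convergence, not clinical realism. The
dichotomized proportions converge to the analytic beta tail probability
as n grows.

## Numerical choices and problem sizes

All computations are closed-form or small linear algebra; the only
Monte Carlo is the PSA (1000 iterations, < 1 s) and the oracle
(200,000 patients, vectorized, < 1 s). Calibration raises an error on a
singular system (zero gain or equal exacerbation probabilities) or
negative solved aggregates. Probabilities derived during sampling are
clamped to [0, 1] with a logged count rather than crashing. Reports
round dollars to whole units and QALYs to four decimals for display
while files keep full precision.

## Known limitations

- The cost engine's two-aggregate structure is an identified stand-in
  for unpublished frequency detail; itemized schedules are supported
  but their frequencies are the user's responsibility.
- The two-year accrual rule is a reconstruction validated by
  properties, not by the published two-year magnitudes (see above).
- Parameters are sampled independently in the PSA; any real correlation
  (e.g., between exacerbation probabilities) is unmodelled apart from
  the optional hazard-ratio link.
- The synthetic adherence study is a structural emulator, not a
  re-creation of the source trial's data.
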