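# hfcea

Decision-tree cost-effectiveness analysis of a **pictorial medication
sheet** versus usual care for older adults living with heart failure
(HF) and cognitive impairment.

## The problem and who this is for

Poor medication adherence in older adults with HF drives hospitalized
exacerbations, mortality, and cost. A pictorial medication sheet — a
one-page visual aid arraying pill images by time of day — raises the
share of patients with good adherence (≥ 80% by pill count). This
package implements the full health-economic evaluation of that
intervention for analysts who want to reproduce, probe, or extend it:
base-case cost/QALY comparison, dominance/ICER logic, one-way and
probabilistic sensitivity analyses, program scenarios, a two-year
extension, and an individual-level microsimulation oracle.

## The model

A one-year decision tree. Each arm (intervention vs usual care) splits a
cohort of 75-year-olds by adherence status, then by HF exacerbation,
survival, and (for exacerbation survivors) worsening vs recovery — ten
terminal paths per arm. Expected QALYs and costs are probability-weighted
sums over paths:

- adherence: P(good | usual care) = 0.556; the intervention adds a gain
  of 0.185 (capped at 1);
- exacerbation: P = 0.232 with good adherence, 0.419 with poor (the
  published hazard ratio 1.81 applied on the probability scale);
- QALY accrual: utilities 0.780 (stable), 0.560 (exacerbation month),
  0.600 (worsened, NYHA II–IV mean); deaths occur mid-year and accrue
  half a year at the stable utility; an exacerbation occupies one month;
- costs: a per-exacerbation bundle and an annual base-care cost,
  calibrated exactly (a 2×2 linear solve) to the published usual-care
  total ($24,507) and incremental saving ($1,949), plus the $498
  first-year intervention cost. Nothing is discounted.

The comparison is incremental (intervention − usual care) on the
cost-effectiveness plane: ΔC, ΔE = ΔQALY, with dominance when ΔC < 0 and
ΔE > 0, otherwise ICER = ΔC/ΔE judged against a willingness-to-pay of
$150,000/QALY. The probabilistic sensitivity analysis redraws every
parameter from method-of-moments beta (probabilities, utilities) or
gamma (costs) distributions, re-derives dependent quantities, and
re-evaluates the tree each iteration.

## Worked example

```python
import hfcea

params = hfcea.load_parameter_set()          # bundled published table
schedule = hfcea.calibrate_schedule(params)  # solve cost aggregates
ce = hfcea.base_case(params, schedule=schedule)
print(round(ce.qaly_per_arm[1], 3), round(ce.qaly_per_arm[0], 3))
print(round(ce.cost_per_arm[1]), round(ce.cost_per_arm[0]))
print(round(ce.delta_qaly, 4), round(ce.delta_cost), ce.dominant)
```

prints

```
0.686 0.691
24507 22558
0.0045 -1949 True
```

— usual care yields 0.686 QALYs at $24,507 per patient; the intervention
yields 0.691 QALYs at $22,558 (its total emerges from the calibrated
model, not from an anchor), so it gains 0.0045 QALYs while saving $1,949:
dominant, no ICER needed. Scaled to 100 patients
(`hfcea.scale_to_population(ce, 100)`) that is 0.45 QALYs gained and
about $195,000 saved per year.

The same analyses are available from the shell:

```sh
hfcea base-case --out results/
hfcea psa --n 1000 --seed 42 --out psa.csv
hfcea dsa --out tornado.csv
hfcea scenario --name richer-better
hfcea two-year --out two_year.csv
hfcea demo --seed 0        # synthetic adherence study -> full pipeline
```

Each command writes CSV/JSON artifacts plus a run log recording the
parameter-file checksum and seed.

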