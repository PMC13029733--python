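# Methods

## Model structure

The model is a discrete-time Markov cohort simulation with four states:

1. **healthy** — alive, no prior stroke;
2. **chronic** — alive after a first-ever stroke (post-acute);
3. **death_stroke** — died of stroke (absorbing);
4. **death_other** — died of any other cause (absorbing).

Each of the ten sex × age strata (men/women × 30–39 … 70–79) is a closed
cohort followed for ten annual cycles. There is no ageing between bands,
no migration, and no recovery: chronic → healthy is structurally zero.

The acute (first 28 days) phase of a stroke is folded into the onset
transition rather than modelled as a separate state: a fraction `f` of
events (the sex-specific 28-day case fatality, 0.149 for men and 0.157
for women) goes directly to `death_stroke`, and the remainder enters
`chronic` in the same cycle.

## Transition probabilities

Annual rates per 100,000 convert to per-cycle probabilities by direct
division, `p = rate / 100,000` (capped at 1). For a stratum with
first-ever incidence rate `I`, stroke mortality rate `M_s`, all-cause
mortality rate `M_a`, recurrence probability `r`, and effective relative
risk `RR_eff`:

- `p_inc = (I / 1e5) × RR_eff`
- `p_oth = (M_a − M_s) / 1e5` (other-cause death)
- healthy row: `(1 − p_inc − p_oth,  p_inc(1 − f),  p_inc·f,  p_oth)`
- chronic row: `(0,  1 − r·RR_eff·f − p_oth,  r·RR_eff·f,  p_oth)`

The relative risk scales **both** first-ever incidence and recurrence;
headline case and death counts, however, tally first-ever events only, so
cumulative deaths equal cumulative cases × `f` exactly (an identity the
test suite checks to machine precision). Non-fatal recurrent events do
not change state (chronic → chronic) but are tallied for costing.

The initial state splits each stratum's population by its stroke
prevalence rate: `chronic₀ = population × prevalence / 1e5`.

## Dose-response and scenarios

The pooled dose-response is RR 0.82 (95% CI 0.75–0.90) per 200 g/day of
milk. For a cycle with intake `d` above the stratum baseline `d₀`:

`RR_eff = 0.82^(max(0, d − d₀) / 200)`

- **base_case**: `d = d₀` every cycle, `RR_eff = 1`.
- **scenario1_immediate**: `d = 180` from cycle 1.
- **scenario2_growth**: geometric growth `d_k = d₀ · g^(k−1)` with
  `g = (180/d₀)^(1/9)`, so the first cycle is at baseline and the tenth
  reaches 180 g/day exactly. The ten stratum growth percentages range
  from 103.1% (women 70–79) to 110.3% (men 40–49).

## Costs and discounting

Costs are in USD (converted at 156.65 JPY/USD where the inputs are in
yen). Two unit costs are calibrated per stratum from published annual
aggregates:

- **inpatient cost per acute event** = annual inpatient expenditure ÷
  (first-ever + recurrent events in cycle 1 of the base case);
- **chronic cost per person-year** = annual (outpatient + drug)
  expenditure ÷ end-of-cycle-1 base-case chronic occupancy.

Each cycle then accrues `events × inpatient_unit + chronic_end ×
chronic_unit`, where `chronic_end` is the end-of-cycle chronic occupancy.
This anchors cycle-1 base-case spending to the published annual
aggregates exactly. Cycle `k` is discounted by `(1.02)^−(k−1)`: the
first year is undiscounted and the ten discount factors sum to 9.16224.
Intervention runs reuse the base-case unit costs, so savings reflect
fewer events and smaller chronic pools, not re-calibration.

A small helper derives the consumer side: average retail price per 100 g
from national sales and shipment volume (USD 3.86B ÷ 3,211,400 kL at
1.03 g/mL ≈ USD 0.12), and the extra daily purchase cost of reaching the
target intake.

## One-way sensitivity analysis

For each sex and intervention scenario, six inputs are swung one at a
time: the four epidemiological rates (incidence, prevalence, stroke
mortality, all-cause mortality — each substituted jointly across that
sex's age bands at its confidence-interval bounds), the relative risk
(0.90 / 0.75), and the discount rate (0% / 4%). Base and intervention
runs are perturbed together, bounds are reported in savings order, and
the report is sorted tornado-style (widest interval first). The relative
risk dominates every group; discounting least-to-most maps to
highest-to-lowest savings because savings accrue in later cycles.

## Synthetic parameter generator

`milkstroke.synthetic` draws internally consistent ten-stratum parameter
sets from a seed (`numpy.random.default_rng`): age-increasing rates from
sorted log-uniform draws (incidence 20–800, prevalence 300–10,000,
stroke mortality 1–300 per 100,000; all-cause mortality a 2–8× multiple
of stroke mortality, capped at 3,000), symmetric relative confidence
intervals, baseline intakes of 40–170 g/day, fatalities 0.10–0.20,
recurrence 0.15–0.35, and costs proportional to the population at risk.
Its purpose is property testing and stress testing — the generator makes
no claim of resembling any real country. A null variant (RR = 1)
verifies that no effect implies zero savings.

## Numerical choices

- Cohorts are real-valued (expected counts), propagated with plain
  float64 vector-matrix products; no stochastic simulation is involved,
  so results are bit-reproducible.
- Parameter files round-trip bit-exactly: floats are written with
  `repr()` and read with pandas' `round_trip` float parser.
- Constant-risk trajectories are cross-checked in the tests against an
  explicit `v0 @ Mᵏ` matrix-power oracle.
- Transition rows that would go negative (probabilities summing past 1)
  raise a `ValueError` naming the stratum rather than being clipped.

## Limitations

- A closed-cohort design: no ageing across band boundaries, no entry of
  new 30-year-olds, no competing improvements in stroke care over the
  horizon.
- Rates convert to probabilities by direct division rather than the
  exponential transform; at the observed magnitudes (≤ ~3% per year) the
  difference is small but not zero.
- The dose-response is extrapolated as a power law below 200 g/day and
  is assumed fully and instantly effective (no lag between intake change
  and risk change).
- Published per-stratum 10-year counts for this model class run several
  percent above a literal 10-cycle tally of the described process; the
  engine implements the stated process literally and documents the gap
  rather than adjusting parameters to fit.
- Costs beyond inpatient, outpatient, and drug expenditure (informal
  care, productivity) are out of scope, as are the costs of promoting
  milk consumption at population scale.
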