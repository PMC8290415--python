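# epicost

Lifetime Markov cohort cost-effectiveness and budget-impact modelling of
add-on anti-seizure therapy, built for health-economics analysts comparing
third-generation anti-epileptic drugs (perampanel, PER, vs lacosamide, LCM,
with zonisamide, ZNS, as a reference drug in the budget model) in patients
with partial-onset seizures.

## The model

A cohort of patients enters the model distributed over seizure-frequency
health states (≥53, 13–52, 1–12, 0 seizures/year) and, after the first
4-month treatment cycle, over six treatment-response levels: maintenance
therapy (withdrawn from the study drug), increase in seizures, <50%, 50–74%
and 75–99% seizure reduction, and seizure-free. Each cycle:

1. response levels evolve by a row-stochastic transition matrix built from
   5-year natural-history probabilities via the constant-hazard conversion
   `p_cycle = 1 − (1 − p_5yr)^(1/15)` (4 months is 1/15 of 5 years), with the
   merged "<50% → 50–99%" improvement mass split between the 50–74% and
   75–99% bands by configurable allocation weights;
2. each (baseline stratum × response level) cell is mapped to a
   seizure-frequency state — seizure-free response → seizure-free state,
   maintenance/increase → baseline state, fractional bands → baseline
   frequency reduced by the band midpoint (25% / 62% / 87%) and re-classified;
3. mortality applies as `1 − (1 − min(1, q·RR))^(1/3)`, where `q` is the
   life-table annual death probability at the cohort's age and `RR` the
   state-specific mortality relative risk (RR = 1 when seizure-free).

The loop runs until 99.9% of the cohort is dead (or a maximum age).
Seizures, life years (LY), quality-adjusted life years (QALY = utility-
weighted LY) and drug/medical costs accrue per cycle and are discounted at
5%/year. Two arms are compared by incremental values, dominance
classification, and ICERs (`ΔCost/ΔEffect`) when neither arm dominates.

On top of the base case the package provides one-way deterministic
sensitivity analysis (tornado tables), probabilistic sensitivity analysis
(Gamma costs / Beta utilities by method of moments; CE-plane samples and
cost-effectiveness acceptability curves against the 1–3× GDP-per-capita
willingness-to-pay anchors of $10,838–$32,515), a scenario analysis enabling
`P(<50% → increase) = P(increase) · (1 − P(responsive))`, and a three-year
payer budget-impact model (eligible-population funnel × market shares ×
dose-mix-weighted annual costs × reimbursement policy, before vs after
reimbursement-list admission).

See `docs/methods.md` for assumptions, parameter provenance (including which
fixture inputs are placeholders for values published only in supplementary
material) and numerical conventions.

## Worked example

The packaged fixture transcribes the published main-text input tables for
the two dose comparisons (PER 8 mg/day vs LCM 400 mg/day; PER 4 mg/day vs
LCM 200 mg/day):

```bash
epicost run-cea --config src/epicost/data/perampanel_lacosamide_cn.yaml --out out/cea
```

prints

```
[1] PER 8 mg/day vs LCM 400 mg/day
    dQALY=+0.1877  dCost=-23,379 USD  [intervention_dominant]
[2] PER 4 mg/day vs LCM 200 mg/day
    dQALY=+0.0590  dCost=-20,640 USD  [intervention_dominant]
```

i.e. under the fixture's inputs PER yields more QALYs at lower lifetime
cost than LCM in both dose comparisons — PER *dominates*, so no ICER is
reported. `out/cea/cea_1.csv` holds the full absolute/incremental table
(seizures, LYs, QALYs, drug/medical/total costs, percent change) and
`trace_1_*.csv` the cycle-by-cycle state occupancy. The budget model:

```bash
epicost run-bia --config src/epicost/data/bia_perampanel_cn.yaml --out out/bia
```

```
    2021: incremental budget +1.11 M USD, PER patients +1,935
    2022: incremental budget +4.66 M USD, PER patients +4,456
    2023: incremental budget +9.81 M USD, PER patients +9,259
```

— the payer budget increase (drug spending up, medical-service spending
partly offset by improved seizure control) and the additional patients
gaining access to PER each projection year.

Other commands: `run-dsa`, `run-psa --seed N [--mode full-model|paper]`,
`run-scenario`, `run-bia-dsa`, `gen-synthetic --seed N`, `validate-config`,
`export-tables`. Every run directory contains a `manifest.yaml` (command,
config digest, seeds, iteration counts, version) sufficient to reproduce it.

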