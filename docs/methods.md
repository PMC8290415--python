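# Methods

## Model structure

The model is a discrete-time cohort state-transition (Markov) model with a
4-month cycle (1/3 year, matching the medication-review interval) and a
lifetime horizon: the loop terminates when the cumulative dead fraction
reaches `dead_fraction_termination` (default 0.999) or the cohort reaches
`max_age` (default 100, the synthetic life table's terminal age).

States live on two layers. The *baseline seizure-frequency stratum*
(≥53, 13–52, 1–12, 0 seizures/year) is fixed for life, because response is
defined as percent reduction from each patient's own baseline — so the
cohort is a 4×6 occupancy matrix of (baseline stratum × current response
level) plus an absorbing dead fraction. Six response levels are tracked:
maintenance therapy (withdrawn from the study drug, background AEDs
continue), increase in seizures, <50%, 50–74%, 75–99% reduction, and
seizure-free.

Within a cycle the order of events is (i) response transition (cycle 1 uses
the trial-observed first-cycle response distribution, taken as an input),
(ii) mortality at the cohort's current age applied to each cell's mapped
seizure-frequency state. Trace rows record the cycle's post-mortality
survivors, so alive + dead = 1 holds exactly at every row; outcomes accrue
for the full cycle to those survivors. **No half-cycle correction** is
applied by default (an option exists): the source model describes none, and
with 4-month cycles the discretisation error is below the reporting
precision of every output.

### Response → seizure-state mapping

Seizure-free response maps to the seizure-free state; maintenance and
increase-in-seizures retain the baseline state; the fractional bands apply
the band-midpoint reduction (25%, 62%, 87%) to the stratum's representative
annual frequency and re-classify by the state bounds, with band boundaries
at 52.5 and 12.5 and half-integer values assigned downward. Representative
frequencies default to interval midpoints — 104 (open-ended top band — a
modelling choice exposed in config because seizure counts scale with it),
32.5, 6.5, 0 per year.

### Transitions

Long-term follow-up evidence supplies 5-year probabilities, converted per
cycle by `p = 1 − (1 − P_5yr)^(1/15)` (constant hazard within the interval).
The literature reports only the merged "<50% → 50–99%" improvement
probability; its converted mass is split 50–74% : 75–99% by allocation
weights, defaulting to the proportions of those two bands pooled across the
comparator trial's first-cycle rows (0.6245 : 0.3755). Residual row mass
stays on the diagonal (remain at current response level) — the standard
cohort-model convention. The same matrix applies to both arms from cycle 2;
per-arm overrides are supported in config.

The scenario analysis replaces the base-case assumption of no
"<50% → increase in seizures" transition with
`P = P(increase) · (1 − P(responsive))`, rebalancing the row diagonal. The
two probabilities are not operationally defined by the source; the default —
documented as an interpretation and overridable per arm — takes each arm's
first-cycle shares: `P(increase)` = the increase-in-seizures share,
`P(responsive)` = the 50–74% + 75–99% + seizure-free share.

### Mortality

A two-column life table (age, annual death probability; contiguous ages,
terminal probability 1) supplies background mortality; state-specific
relative risks multiply the annual probability (capped at 1) before the
per-cycle conversion `1 − (1 − q·RR)^(1/3)`. RR on the hazard scale is a
config option (`mortality_rr_scale: rate`). Seizure-free patients carry the
general-population risk (RR = 1, enforced).

## Valuation

Per cycle k at time t = k/3 years, survivors accrue LY, utility-weighted
QALYs, seizures (at the mapped state's representative frequency) and costs,
discounted by `(1 + r)^(−t)` with discrete annual compounding and r = 5%/yr
for both effects and costs (0–8% in sensitivity analyses). Seizure counts
are discounted by default for consistency with LY/QALY
(`discount_seizures` flag). Study-drug plus background-AED cost accrues per
4-month cycle to every living cell except maintenance therapy, which by
default accrues background AEDs only (those patients have withdrawn from the
study drug); a `maintenance_drug_policy: full` switch exists because the
source is silent.

Dominance: intervention dominant iff it gains QALYs at lower cost (weak
inequalities at the measure-zero boundary), symmetric for the comparator;
same-sign increments are a trade-off, with ICERs reported as positive
magnitudes `|ΔCost/ΔEffect|` — orientation is carried by the signed
increments and the label, since signed ICERs are ambiguous across
cost-effectiveness-plane quadrants.

## Sensitivity analyses

**DSA.** One parameter (or one linked group: both discount rates; the joint
±20% fluctuation of an arm's maintenance/75–99%/seizure-free first-cycle
shares with proportional renormalisation of the remaining levels) is set to
its low and high value; the whole pipeline re-runs. Relative ranges in the
config (±10%, −20–0%, …) are resolved against base values at load time,
honouring one-sided price ranges (drug prices only fall, service prices only
rise). Tornado rows are ranked by the spread of incremental net monetary
benefit at the 3×-GDP threshold ($32,515/QALY) because ICER spread is
undefined when a range crosses a dominance quadrant.

**PSA.** Costs are Gamma, utilities Beta, parameterised by method of moments
from (mean, sd); draws are independent (no correlation structure is
specified by the source). Published inputs carry ranges but not standard
deviations; the package's convention is sd = (DSA high − low)/(2·1.96),
i.e. the range treated as a 95% interval. Two modes:

* `full-model` (default): each of the 10,000 iterations re-evaluates both
  arms through the Markov pipeline. When no sampled parameter can alter the
  cohort trace (the packaged fixture samples only costs and utilities), the
  per-arm traces are computed once and re-valued per draw — an exact
  algebraic shortcut, regression-tested against the naive per-iteration
  pipeline.
* `paper`: outcome-level recombination — per-arm LY drawn from a Normal with
  the model's mean (sd defaulting to 10% of the mean, a documented
  assumption since the source does not state how its LY standard deviation
  was derived) combined with sampled unit costs and utilities against the
  base-case occupancy aggregates, without re-running the engine.

Independent draws may cross the base-case orderings (e.g. a sampled 1–12
utility exceeding the seizure-free utility); those orderings are therefore
enforced only on loaded base configurations, not on probabilistic draws.
The CEAC reports the fraction of draws with positive incremental net benefit
over a WTP grid (0–50,000 in 500-unit steps, always containing 10,838 and
32,515). All sampling is reproducible bit-for-bit under a fixed seed.

## Budget-impact model

Eligible population per projection year =
national population × insured fraction × aged-≥12 fraction ×
active-epilepsy prevalence (2013 reference value compounded at 5.2%/year to
the projection year) × partial-onset fraction × standardised-drug-treatment
fraction. Market shares per (drug, year, before/after listing) convert it to
treated patients. Per-patient annual drug cost = dose-mix-weighted study
drug (PER 4 mg share 60%, LCM 200 mg share 68.42%) + background AEDs; ZNS
background cost is the PER/LCM average (no trial data). Medical cost =
health-state mix × per-state 4-month cost × 3. Payer budgets apply
reimbursed fractions per (insurance scheme × care setting × drug class),
split 69/31 across the resident and employee schemes. All arithmetic runs in
full precision; person counts (half-up) and million-USD figures (2 dp) are
rounded only at report emission.

The "direct medical" account is genuinely ambiguous in the source; the
default `medical_mix_mode: scenario_specific` costs the before-listing
scenario at the pre-treatment state mix and the after-listing scenario at
per-drug post-treatment mixes — the only reading consistent with the
source's direction of the medical-cost offset — with `after_only` as the
alternative.

## Fixture provenance and placeholders

`src/epicost/data/perampanel_lacosamide_cn.yaml` transcribes every
main-text published input (baseline distributions, first-cycle response
distributions, drug/AED/medical costs, utilities, mortality RRs, DSA ranges,
the 6.5408 CNY/USD rate). Printed percentage rows can sum to 99.99 due to
table rounding; the loader renormalises vectors within 0.5% of unity and
rejects anything further off.

Values the publication placed only in supplementary material are shipped as
clearly labelled placeholders, chosen to be internally consistent and
demographically plausible, and all exposed in config:

* cohort starting age (33), the 5-year "<50% → 50–99%" probability (0.50),
  and the synthetic Gompertz–Makeham life table
  (`life_table_cn_synthetic.tsv`, remaining life expectancy ≈ 46.6 years at
  age 33);
* the BIA funnel fractions (insured 0.96, aged ≥12 0.85, standardised
  treatment 0.37 — consistent with the funnel arithmetic implied by the
  published market shares and patient counts), health-state mixes, and the
  reimbursement-policy table.

Because of these placeholders the packaged fixture reproduces the published
*input* tables cell-for-cell but not the published headline outputs; users
holding the supplementary values can transcribe them into the config and
re-run unchanged code.

## Synthetic data generator

`epicost.synthetic` emits complete random configurations in the same schema
the loader consumes: Gompertz–Makeham life tables, ordered utilities and
medical costs, Dirichlet response/baseline distributions, random transition
edges, and DSA/PSA sections. It emulates the *structure* of real inputs
(6 response levels × 4 states, two independent arms) so that conservation
laws, dominance classification in every cost-effectiveness-plane quadrant,
and the Monte-Carlo machinery are all testable without external data. It
does not emulate parameter correlations, trial sampling error, or
realistic drug-price structure — passing property tests demonstrates
structural and numerical correctness, not calibration to any real
population.

## Numerical conventions and limitations

* Cohort age is derived from the cycle index (no floating-point drift);
  the max-age check carries a 1e-9 tolerance.
* Probability conversions use `log1p`/`expm1`; row-stochasticity is
  validated to 1e-9; mass conservation holds to 1e-9 over hundreds of
  cycles.
* Discounting of cycle k uses its end time t = k/3.
* Problem sizes: the packaged cohort runs ≈ 200 cycles per arm; the
  acceptance script uses 10,000 PSA iterations; the property suite sweeps
  100 synthetic parameter sets.
* Limitations: no individual-level simulation, no compliance or
  adverse-event modelling, no EVPI, no uptake-curve modelling beyond the
  supplied market-share table; indirect-comparison uncertainty in the
  first-cycle response distributions is not propagated (they enter as
  fixed inputs, perturbed only by the designated DSA rows).
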