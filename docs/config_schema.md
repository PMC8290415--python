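# Configuration schema

Both analyses are driven by YAML documents. All probabilities are fractions
of 1 (the loader renormalises vectors within 0.5% of unity, covering
printed-table rounding); all monetary amounts are USD.

## Cost-effectiveness config

```yaml
settings:                      # all optional; defaults shown
  starting_age: 33             # years; must lie inside the life table
  max_age: 100
  dead_fraction_termination: 0.999
  cny_per_usd: 6.5408
  discount_seizures: true
  half_cycle_correction: false
  maintenance_drug_policy: background_only   # or: full
  mortality_rr_scale: probability            # or: rate
discount:
  annual_rate_effects: 0.05
  annual_rate_costs: 0.05
categories:                    # representative annual seizure frequencies
  ge53_per_year: 104.0         # must be strictly decreasing; seizure_free = 0
  s13_52_per_year: 32.5
  s1_12_per_year: 6.5
  seizure_free: 0.0
utilities: {<category>: weight in [0, 1]}       # seizure_free must be highest
medical_costs: {<category>: USD per 4 months}   # non-increasing
mortality:
  life_table: [[age, annual death probability], ...]   # contiguous ages,
  # ... or: life_table_file: path.tsv                  # terminal value 1
  rr_by_category: {<category>: RR >= 1}                # seizure_free: 1.0
arms:
  <arm name>:
    drug_cost_per_cycle: USD per 4 months
    background_aed_cost_per_cycle: USD per 4 months
    baseline_seizure_distribution: {<category>: fraction}
    first_cycle_response_distribution: {<level>: fraction}
comparisons:
  - {intervention: <arm>, comparator: <arm>}
transitions:
  allocation_weights: [w_50_74, w_75_99]    # >= 0, sum to 1
  five_year_probabilities:
    - {from: <level>, to: <level or response_50_99>, probability: p}
  arms: {<arm>: {five_year_probabilities: [...]}}   # optional per-arm override
scenario:
  default_from_first_cycle: true
  arms: {<arm>: {p_increase: p, p_responsive: p}}   # optional explicit values
dsa:                           # one tornado row each
  - {name: ..., path: dotted.path, low: x, high: y, basis: "..."}
  - {name: ..., path: dotted.path, rel_low: -0.2, rel_high: 0.0}  # vs base
  - {name: ..., paths: [p1, p2], per_path: [{low: ..., high: ...}, ...]}
  - {name: ..., kind: response_fluctuation, arm: <arm>, relative: 0.2}
psa:
  - {path: dotted.path, family: gamma|beta|normal, mean: m, sd: s}
  # mean defaults to the base value; sd defaults to from_dsa_range
  # (matching DSA range treated as a 95% interval)
```

Response levels: `maintenance_therapy`, `increase_in_seizures`,
`response_lt50`, `response_50_74`, `response_75_99`, `seizure_free`.
Categories: `ge53_per_year`, `s13_52_per_year`, `s1_12_per_year`,
`seizure_free`.

Life-table files are two-column delimited text (age, annual death
probability) with a mandatory header row; comma, tab or whitespace
delimiters.

## Budget-impact config

```yaml
base_year: 2020                # optional before-only reporting year
projection_years: [2021, 2022, 2023]
funnel:
  national_population: {<year>: persons}   # or a single number
  insured_fraction: f
  age_ge12_fraction: f
  ae_prevalence_2013: f
  prevalence_annual_growth: f              # compounded from the reference year
  prevalence_reference_year: 2013
  partial_onset_fraction: f
  standardized_treatment_fraction: f
market_share:
  before: {PER: {<year>: share}, LCM: {...}, ZNS: {...}}
  after:  {PER: {<year>: share}, ...}
costs:
  fraction_low_dose: {PER: 0.60, LCM: 0.6842}
  annual_drug_cost:
    PER: {low_dose: USD, high_dose: USD}   # weighted by fraction_low_dose
    ZNS: USD                               # or a single weighted figure
  annual_background_cost: {PER: USD, LCM: USD, ZNS: USD}
medical_costs: {<category>: USD per 4 months}
state_mix:
  before: {<category>: fraction}           # pre-treatment mix
  after: {PER: {...}, LCM: {...}, ZNS: {...}}
medical_mix_mode: scenario_specific        # or: after_only
policy:
  insured_split: {URRBMI: f, UEBMI: f}     # sums to 1
  setting_split: {outpatient: f, inpatient: f}
  drug_class: {PER: B, LCM: B, ZNS: B}
  drug_rates: {<insurance>: {<setting>: {A: rate, B: rate}}}
  medical_rates: {<insurance>: {<setting>: rate}}
dsa:
  - {name: ..., path: dotted.path, low: x, high: y}
  - {name: ..., paths: [p1, p2], rel_low: -0.1, rel_high: 0.1}
```
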