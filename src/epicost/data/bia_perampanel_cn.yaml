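# Budget-impact parameter set: admission of perampanel (PER) to the national
# reimbursement list, projection years 2021-2023 (2020 as pre-listing base
# year).  Market shares, dose mixes, prevalence and annual drug costs are
# transcribed from the published main-text tables.  The population-funnel
# magnitudes, health-state mixes and reimbursement policy were published only
# in supplementary material / figure sources; the values below are documented
# PLACEHOLDERS chosen to be demographically plausible and internally
# consistent with the published funnel description.

base_year: 2020
projection_years: [2021, 2022, 2023]

funnel:
  national_population:        # persons; national statistics, by year
    2020: 1412120000
    2021: 1412600000
    2022: 1411750000
    2023: 1409670000
  insured_fraction: 0.96               # PLACEHOLDER: basic-insurance coverage
  age_ge12_fraction: 0.85              # PLACEHOLDER: census >=12y share
  ae_prevalence_2013: 0.0024           # active-epilepsy prevalence, 2013
  prevalence_annual_growth: 0.052      # compounded from the 2013 reference year
  prevalence_reference_year: 2013
  partial_onset_fraction: 0.60         # share with partial-onset seizures
  standardized_treatment_fraction: 0.37  # PLACEHOLDER: standardized drug-treatment rate

market_share:                 # fractions of the eligible population
  before:
    PER:  {2020: 0.0006, 2021: 0.0014, 2022: 0.0024, 2023: 0.0034}
    LCM:  {2020: 0.0032, 2021: 0.0066, 2022: 0.0115, 2023: 0.0161}
    ZNS:  {2020: 0.0048, 2021: 0.0041, 2022: 0.0034, 2023: 0.0029}
  after:
    PER:  {2021: 0.0035, 2022: 0.0070, 2023: 0.0125}
    LCM:  {2021: 0.0062, 2022: 0.0109, 2023: 0.0142}
    ZNS:  {2021: 0.0039, 2022: 0.0031, 2023: 0.0024}

costs:
  fraction_low_dose:          # share of patients on the lower daily dose
    PER: 0.60                 # 4 mg/day
    LCM: 0.6842               # 200 mg/day
  annual_drug_cost:           # USD/year; per-dose entries are weighted by the
    PER:                      # dose mix (weighted: PER 1211, LCM 1924)
      low_dose: 865.0
      high_dose: 1730.0
    LCM:
      low_dose: 1462.23
      high_dose: 2924.46
    ZNS: 700.0
  annual_background_cost:     # USD/year, concomitant AEDs
    PER: 762.0
    LCM: 592.0
    ZNS: 670.0                # PER/LCM average (no trial data for ZNS)
  annual_cost_aeds_other: 710.0   # reference row; not used in budget arithmetic

medical_costs:                # USD per 4-month cycle, per seizure category
  ge53_per_year: 571.0
  s13_52_per_year: 441.0
  s1_12_per_year: 273.0
  seizure_free: 180.0

# Health-state mixes used to weight medical costs.  PLACEHOLDERS:
# `before` reflects the pre-treatment baseline distribution; `after` mixes
# reflect each drug's post-treatment response profile (ZNS = PER/LCM average).
state_mix:
  before:
    ge53_per_year: 0.877
    s13_52_per_year: 0.123
    s1_12_per_year: 0.0
    seizure_free: 0.0
  after:
    PER:
      ge53_per_year: 0.55
      s13_52_per_year: 0.20
      s1_12_per_year: 0.15
      seizure_free: 0.10
    LCM:
      ge53_per_year: 0.60
      s13_52_per_year: 0.22
      s1_12_per_year: 0.14
      seizure_free: 0.04
    ZNS:
      ge53_per_year: 0.575
      s13_52_per_year: 0.21
      s1_12_per_year: 0.145
      seizure_free: 0.07

medical_mix_mode: scenario_specific

# Reimbursement policy.  PLACEHOLDERS for the supplementary policy table:
# reimbursed fraction per insurance scheme x care setting x drug class,
# plus the insured split across schemes and the outpatient/inpatient split
# of annual utilisation.
policy:
  insured_split: {URRBMI: 0.69, UEBMI: 0.31}
  setting_split: {outpatient: 0.60, inpatient: 0.40}
  drug_class: {PER: B, LCM: B, ZNS: B}
  drug_rates:
    URRBMI:
      outpatient: {A: 0.55, B: 0.50}
      inpatient:  {A: 0.70, B: 0.60}
    UEBMI:
      outpatient: {A: 0.65, B: 0.60}
      inpatient:  {A: 0.85, B: 0.75}
  medical_rates:
    URRBMI: {outpatient: 0.50, inpatient: 0.65}
    UEBMI:  {outpatient: 0.60, inpatient: 0.80}

dsa:
  - {name: AE prevalence, path: funnel.ae_prevalence_2013, low: 0.0022, high: 0.0033}
  - {name: Prevalence growth rate, path: funnel.prevalence_annual_growth, rel_low: -0.30, rel_high: 0.30}
  - {name: PER low-dose share, path: costs.fraction_low_dose.PER, low: 0.50, high: 0.80}
  - {name: LCM low-dose share, path: costs.fraction_low_dose.LCM, low: 0.50, high: 0.80}
  - name: Annual cost of PER
    paths: [costs.annual_drug_cost.PER.low_dose, costs.annual_drug_cost.PER.high_dose]
    rel_low: -0.10
    rel_high: 0.10
  - {name: Annual cost of AEDs-PER, path: costs.annual_background_cost.PER, rel_low: -0.30, rel_high: 0.0}
  - name: Annual cost of LCM
    paths: [costs.annual_drug_cost.LCM.low_dose, costs.annual_drug_cost.LCM.high_dose]
    rel_low: -0.30
    rel_high: 0.0
  - {name: Annual cost of AEDs-LCM, path: costs.annual_background_cost.LCM, rel_low: -0.30, rel_high: 0.0}
  - {name: Annual cost of ZNS, path: costs.annual_drug_cost.ZNS, rel_low: -0.30, rel_high: 0.0}
  - {name: Annual cost of AEDs-ZNS, path: costs.annual_background_cost.ZNS, rel_low: -0.30, rel_high: 0.0}
  - {name: Medical cost >=53/year, path: medical_costs.ge53_per_year, rel_low: -0.30, rel_high: 0.30}
  - {name: Medical cost 13-52/year, path: medical_costs.s13_52_per_year, rel_low: -0.30, rel_high: 0.30}
  - {name: Medical cost <=12/year, path: medical_costs.s1_12_per_year, rel_low: -0.30, rel_high: 0.30}
  - {name: Medical cost seizure-free, path: medical_costs.seizure_free, rel_low: -0.30, rel_high: 0.30}
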