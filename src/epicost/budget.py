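"""Three-year budget-impact model.

Projects the payer budget for three add-on anti-seizure drugs (PER, LCM,
ZNS) before and after the newest drug's admission to the national
reimbursement list.  The eligible population is a multiplicative funnel
(national population x insured x aged >=12 x active-epilepsy prevalence
compounded from its 2013 reference year x partial-onset share x
standardised-treatment share); market shares per (drug, year, listing
scenario) convert it to treated patients; per-patient annual drug and
medical costs and the reimbursement policy (insurance scheme x care setting
x drug class) convert patients to payer budgets.  All arithmetic runs in
full precision; person counts and million-USD figures are rounded only at
report emission.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .params import (
    CATEGORY_LABELS,
    ConfigError,
    MedicalCostSet,
    get_by_path,
    set_by_path,
    _probability_vector,
)

__all__ = [
    "PopulationFunnel",
    "MarketShareTable",
    "DoseMix",
    "ReimbursementPolicy",
    "BiaParameters",
    "BiResult",
    "load_bia_config",
    "eligible_population",
    "treated_patients",
    "annual_cost_per_patient",
    "compute_budget",
    "run_bia_dsa",
    "export_bia_tables",
]

DRUGS = ("PER", "LCM", "ZNS")
SCENARIOS = ("before", "after")
INSURANCES = ("URRBMI", "UEBMI")
SETTINGS_ = ("outpatient", "inpatient")


@dataclass(frozen=True)
class PopulationFunnel:
    """Eligible-population funnel for one projection year."""

    year: int
    national_population: float
    insured_fraction: float
    age_ge12_fraction: float
    ae_prevalence_2013: float
    prevalence_annual_growth: float
    partial_onset_fraction: float
    standardized_treatment_fraction: float
    prevalence_reference_year: int = 2013

    def __post_init__(self) -> None:
        if self.year < self.prevalence_reference_year:
            raise ConfigError("funnel year precedes the prevalence reference year")
        if self.national_population < 0:
            raise ConfigError("national population must be >= 0")
        for attr in (
            "insured_fraction",
            "age_ge12_fraction",
            "ae_prevalence_2013",
            "partial_onset_fraction",
            "standardized_treatment_fraction",
        ):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"funnel {attr} must lie in [0, 1]")
        if self.prevalence_annual_growth < -1.0:
            raise ConfigError("prevalence growth below -100%")


def eligible_population(funnel: PopulationFunnel) -> float:
    """Persons eligible for add-on therapy: the funnel product with the
    prevalence compounded from its reference year to the projection year."""
    growth = (1.0 + funnel.prevalence_annual_growth) ** (
        funnel.year - funnel.prevalence_reference_year
    )
    return (
        funnel.national_population
        * funnel.insured_fraction
        * funnel.age_ge12_fraction
        * funnel.ae_prevalence_2013
        * growth
        * funnel.partial_onset_fraction
        * funnel.standardized_treatment_fraction
    )


@dataclass(frozen=True)
class MarketShareTable:
    """Market share per (drug, year, listing scenario), as fractions of the
    eligible population."""

    share: Mapping[tuple[str, int, str], float]

    def __post_init__(self) -> None:
        for (drug, year, scen), v in self.share.items():
            if drug not in DRUGS or scen not in SCENARIOS:
                raise ConfigError(f"market share: unknown key ({drug}, {year}, {scen})")
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"market share ({drug}, {year}, {scen}) outside [0, 1]")

    def get(self, drug: str, year: int, scenario: str) -> float:
        try:
            return float(self.share[(drug, year, scenario)])
        except KeyError:
            raise KeyError(f"no market share for ({drug}, {year}, {scenario})") from None


def treated_patients(
    eligible: float, shares: MarketShareTable, year: int, scenario: str
) -> dict[str, float]:
    """Treated persons per drug (full precision; round only when reporting)."""
    return {drug: eligible * shares.get(drug, year, scenario) for drug in DRUGS}


@dataclass(frozen=True)
class DoseMix:
    """Share of patients on the lower daily dose, per drug (low + high = 1)."""

    fraction_low_dose: Mapping[str, float]

    def __post_init__(self) -> None:
        for drug, v in self.fraction_low_dose.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"dose mix for {drug} outside [0, 1]")

    def low(self, drug: str) -> float:
        return float(self.fraction_low_dose.get(drug, 1.0))


@dataclass(frozen=True)
class ReimbursementPolicy:
    """Reimbursed fractions per (insurance, setting, drug class) plus the
    insured split across schemes and the outpatient/inpatient cost split."""

    drug_rates: Mapping[str, Mapping[str, Mapping[str, float]]]
    medical_rates: Mapping[str, Mapping[str, float]]
    insured_split: Mapping[str, float]
    setting_split: Mapping[str, float]
    drug_class: Mapping[str, str]

    def __post_init__(self) -> None:
        for ins in INSURANCES:
            if ins not in self.drug_rates or ins not in self.medical_rates:
                raise ConfigError(f"policy: missing rates for {ins}")
            for st in SETTINGS_:
                for cls, rate in self.drug_rates[ins][st].items():
                    if not (0.0 <= rate <= 1.0):
                        raise ConfigError(f"policy: drug rate {ins}/{st}/{cls} outside [0, 1]")
                if not (0.0 <= self.medical_rates[ins][st] <= 1.0):
                    raise ConfigError(f"policy: medical rate {ins}/{st} outside [0, 1]")
        if abs(sum(self.insured_split.values()) - 1.0) > 1e-9:
            raise ConfigError("policy: insured split must sum to 1")
        if abs(sum(self.setting_split.values()) - 1.0) > 1e-9:
            raise ConfigError("policy: setting split must sum to 1")

    def effective_drug_rate(self, drug: str, insurance: str | None = None) -> float:
        cls = self.drug_class.get(drug, "B")
        inss = [insurance] if insurance else list(INSURANCES)
        total = 0.0
        for ins in inss:
            w = self.insured_split[ins] if insurance is None else 1.0
            total += w * sum(
                self.setting_split[st] * self.drug_rates[ins][st][cls]
                for st in SETTINGS_
            )
        return total

    def effective_medical_rate(self, insurance: str | None = None) -> float:
        inss = [insurance] if insurance else list(INSURANCES)
        total = 0.0
        for ins in inss:
            w = self.insured_split[ins] if insurance is None else 1.0
            total += w * sum(
                self.setting_split[st] * self.medical_rates[ins][st] for st in SETTINGS_
            )
        return total


@dataclass(frozen=True)
class BiaParameters:
    """Validated budget-impact inputs plus the raw config for perturbation."""

    raw: Mapping[str, Any]
    years: tuple[int, ...]
    base_year: int | None
    funnels: Mapping[int, PopulationFunnel]
    shares: MarketShareTable
    dose_mix: DoseMix
    annual_drug_cost: Mapping[str, float]  # study drug, USD/year (dose-mix weighted)
    annual_background_cost: Mapping[str, float]  # background AEDs, USD/year
    medical_costs: MedicalCostSet  # USD per 4-month cycle, per category
    state_mix_before: np.ndarray
    state_mix_after: Mapping[str, np.ndarray]
    policy: ReimbursementPolicy
    medical_mix_mode: str  # "scenario_specific" | "after_only"
    cycles_per_year: int = 3

    def with_values(self, overrides: Mapping[str, Any]) -> "BiaParameters":
        raw = copy.deepcopy(dict(self.raw))
        for path, value in overrides.items():
            set_by_path(raw, path, value)
        return load_bia_config(raw)

    def with_value(self, path: str, value: Any) -> "BiaParameters":
        return self.with_values({path: value})


def load_bia_config(source: str | Path | Mapping[str, Any]) -> BiaParameters:
    """Load and validate the budget-impact configuration document."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
        if not isinstance(raw, Mapping):
            raise ConfigError("BIA config: top level must be a mapping")
        raw = copy.deepcopy(dict(raw))
    else:
        raw = copy.deepcopy(dict(source))

    for key in ("funnel", "market_share", "costs", "medical_costs", "policy", "state_mix"):
        if key not in raw:
            raise ConfigError(f"BIA config: missing required section {key!r}")

    fun = raw["funnel"]
    years = tuple(int(y) for y in raw.get("projection_years", [2021, 2022, 2023]))
    base_year = raw.get("base_year")
    base_year = int(base_year) if base_year is not None else None
    all_years = ((base_year,) if base_year is not None else ()) + years
    pops = fun["national_population"]
    funnels = {}
    for y in all_years:
        pop = pops[y] if isinstance(pops, Mapping) else pops
        funnels[y] = PopulationFunnel(
            year=y,
            national_population=float(pop),
            insured_fraction=float(fun["insured_fraction"]),
            age_ge12_fraction=float(fun["age_ge12_fraction"]),
            ae_prevalence_2013=float(fun["ae_prevalence_2013"]),
            prevalence_annual_growth=float(fun["prevalence_annual_growth"]),
            partial_onset_fraction=float(fun["partial_onset_fraction"]),
            standardized_treatment_fraction=float(fun["standardized_treatment_fraction"]),
            prevalence_reference_year=int(fun.get("prevalence_reference_year", 2013)),
        )

    share: dict[tuple[str, int, str], float] = {}
    for scen, block in raw["market_share"].items():
        if scen not in SCENARIOS:
            raise ConfigError(f"market_share: unknown scenario {scen!r}")
        for drug, by_year in block.items():
            for y, v in by_year.items():
                share[(drug, int(y), scen)] = float(v)
    shares = MarketShareTable(share)

    costs = raw["costs"]
    dose_mix = DoseMix(
        {d: float(v) for d, v in (costs.get("fraction_low_dose") or {}).items()}
    )
    annual_drug = {}
    for d in DRUGS:
        entry = costs["annual_drug_cost"][d]
        if isinstance(entry, Mapping):
            # per-dose costs weighted by the low-dose share
            w = dose_mix.low(d)
            annual_drug[d] = w * float(entry["low_dose"]) + (1.0 - w) * float(
                entry["high_dose"]
            )
        else:
            annual_drug[d] = float(entry)
    annual_bg = {d: float(costs["annual_background_cost"][d]) for d in DRUGS}
    for d in DRUGS:
        if annual_drug[d] < 0 or annual_bg[d] < 0:
            raise ConfigError(f"costs for {d} must be >= 0")

    med = MedicalCostSet(
        np.array([float(raw["medical_costs"][lab]) for lab in CATEGORY_LABELS])
    )

    mix_raw = raw["state_mix"]
    before = _probability_vector(mix_raw["before"], CATEGORY_LABELS, "state_mix.before")
    after = {
        d: _probability_vector(mix_raw["after"][d], CATEGORY_LABELS, f"state_mix.after.{d}")
        for d in DRUGS
    }

    pol = raw["policy"]
    policy = ReimbursementPolicy(
        drug_rates=pol["drug_rates"],
        medical_rates=pol["medical_rates"],
        insured_split={k: float(v) for k, v in pol["insured_split"].items()},
        setting_split={k: float(v) for k, v in pol["setting_split"].items()},
        drug_class=pol.get("drug_class", {}),
    )

    mode = raw.get("medical_mix_mode", "scenario_specific")
    if mode not in ("scenario_specific", "after_only"):
        raise ConfigError("medical_mix_mode must be scenario_specific or after_only")

    return BiaParameters(
        raw=raw,
        years=years,
        base_year=base_year,
        funnels=funnels,
        shares=shares,
        dose_mix=dose_mix,
        annual_drug_cost=annual_drug,
        annual_background_cost=annual_bg,
        medical_costs=med,
        state_mix_before=before,
        state_mix_after=after,
        policy=policy,
        medical_mix_mode=mode,
    )


def annual_cost_per_patient(
    drug: str,
    bia: BiaParameters,
    scenario: str = "after",
    low_dose_costs: Mapping[str, float] | None = None,
    high_dose_costs: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Gross (pre-reimbursement) annual cost per treated patient.

    Returns ``(drug_component, medical_component)`` in USD/year.  The drug
    component is the dose-mix-weighted annual study-drug cost (either the
    configured weighted figure, or computed from per-dose costs when given
    granularly) plus the background-AED annual cost.  The medical component
    weights per-category cycle costs by the health-state mix — the
    post-treatment mix of the drug, or the pre-treatment mix in the before
    scenario under ``scenario_specific`` accounting.
    """
    if drug not in DRUGS:
        raise KeyError(f"unknown drug {drug!r}")
    if low_dose_costs is not None and high_dose_costs is not None:
        w = bia.dose_mix.low(drug)
        study = w * float(low_dose_costs[drug]) + (1.0 - w) * float(high_dose_costs[drug])
    else:
        study = bia.annual_drug_cost[drug]
    drug_component = study + bia.annual_background_cost[drug]

    if bia.medical_mix_mode == "scenario_specific" and scenario == "before":
        mix = bia.state_mix_before
    else:
        mix = bia.state_mix_after[drug]
    if abs(float(np.sum(mix)) - 1.0) > 1e-9:
        raise ConfigError(f"state mix for {drug} does not sum to 1")
    medical_component = float(mix @ bia.medical_costs.costs) * bia.cycles_per_year
    return drug_component, medical_component


@dataclass(frozen=True)
class BiResult:
    """Per (year, scenario, drug) treated patients and payer budgets, USD."""

    table: pd.DataFrame  # columns: year, scenario, drug, treated, drug_budget, medical_budget, total_budget, plus per-insurance totals

    def totals(self, year: int, scenario: str) -> pd.Series:
        sub = self.table[(self.table.year == year) & (self.table.scenario == scenario)]
        if sub.empty:
            raise KeyError(f"no rows for ({year}, {scenario})")
        out = sub[
            ["treated", "drug_budget", "medical_budget", "total_budget"]
            + [f"total_{ins}" for ins in INSURANCES]
        ].sum()
        return out

    def incremental(self) -> pd.DataFrame:
        """After-minus-before increments per projection year."""
        rows = []
        years = sorted(
            set(self.table.loc[self.table.scenario == "after", "year"])
        )
        for y in years:
            after = self.totals(y, "after")
            before = self.totals(y, "before")
            diff = after - before
            rec = {"year": y}
            rec.update({k: float(v) for k, v in diff.items()})
            per_drug = {}
            for d in DRUGS:
                ta = self.table[
                    (self.table.year == y)
                    & (self.table.scenario == "after")
                    & (self.table.drug == d)
                ]["treated"].sum()
                tb = self.table[
                    (self.table.year == y)
                    & (self.table.scenario == "before")
                    & (self.table.drug == d)
                ]["treated"].sum()
                rec[f"treated_{d}"] = float(ta - tb)
            pc_after = after["total_budget"] / after["treated"] if after["treated"] else 0.0
            pc_before = before["total_budget"] / before["treated"] if before["treated"] else 0.0
            rec["per_capita_change"] = float(pc_after - pc_before)
            rows.append(rec)
        return pd.DataFrame(rows)

    def summary_millions(self) -> pd.DataFrame:
        """Report-precision table: budgets in millions (2 dp), persons rounded."""
        df = self.table.copy()
        for col in ["drug_budget", "medical_budget", "total_budget"] + [
            f"total_{ins}" for ins in INSURANCES
        ]:
            df[col] = (df[col] / 1e6).round(2)
        df["treated"] = np.floor(df["treated"] + 0.5).astype(int)  # half-up
        return df


def compute_budget(bia: BiaParameters) -> BiResult:
    """Payer budgets per year, scenario and drug.

    Budget = treated patients x gross annual cost x effective reimbursement
    rate, with the drug and medical components reimbursed under their own
    (insurance x setting x class) rates and split across insurance schemes.
    """
    rows = []
    year_scenarios = [(y, "before") for y in ((bia.base_year,) if bia.base_year else ())]
    for y in bia.years:
        year_scenarios += [(y, "before"), (y, "after")]
    for year, scenario in year_scenarios:
        eligible = eligible_population(bia.funnels[year])
        treated = treated_patients(eligible, bia.shares, year, scenario)
        for drug, n in treated.items():
            drug_cost, med_cost = annual_cost_per_patient(drug, bia, scenario=scenario)
            rec = {
                "year": year,
                "scenario": scenario,
                "drug": drug,
                "eligible": eligible,
                "treated": n,
                "drug_budget": 0.0,
                "medical_budget": 0.0,
            }
            for ins in INSURANCES:
                w = bia.policy.insured_split[ins]
                d_budget = n * w * drug_cost * bia.policy.effective_drug_rate(drug, ins)
                m_budget = n * w * med_cost * bia.policy.effective_medical_rate(ins)
                rec[f"total_{ins}"] = d_budget + m_budget
                rec["drug_budget"] += d_budget
                rec["medical_budget"] += m_budget
            rec["total_budget"] = rec["drug_budget"] + rec["medical_budget"]
            rows.append(rec)
    return BiResult(table=pd.DataFrame(rows))


def run_bia_dsa(
    bia: BiaParameters, specs: Sequence[Mapping[str, Any]] | None = None
) -> pd.DataFrame:
    """One-way DSA on the budget-impact model.

    ``specs`` defaults to the config's ``dsa`` section: entries with a dotted
    ``path`` plus ``low``/``high`` (absolute) or ``rel_low``/``rel_high``
    (relative to base).  Output: one row per (parameter, year) with the
    incremental total budget at the low and high value and the spread, sorted
    by spread within year.
    """
    if specs is None:
        specs = bia.raw.get("dsa", []) or []
    base_inc = compute_budget(bia).incremental().set_index("year")["total_budget"]
    rows = []
    for entry in specs:
        paths = entry.get("paths") or [entry["path"]]
        lows: dict[str, float] = {}
        highs: dict[str, float] = {}
        for p in paths:
            base = float(get_by_path(bia.raw, p))
            lows[p] = float(entry["low"]) if "low" in entry else base * (
                1.0 + float(entry["rel_low"])
            )
            highs[p] = float(entry["high"]) if "high" in entry else base * (
                1.0 + float(entry["rel_high"])
            )
        inc_lo = compute_budget(bia.with_values(lows)).incremental().set_index("year")["total_budget"]
        inc_hi = compute_budget(bia.with_values(highs)).incremental().set_index("year")["total_budget"]
        for y in base_inc.index:
            rows.append(
                {
                    "parameter": entry.get("name", ";".join(paths)),
                    "year": int(y),
                    "incremental_base": float(base_inc[y]),
                    "incremental_low": float(inc_lo[y]),
                    "incremental_high": float(inc_hi[y]),
                    "spread": abs(float(inc_hi[y]) - float(inc_lo[y])),
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["year", "spread"], ascending=[True, False], ignore_index=True)
    return df


def export_bia_tables(bia: BiaParameters) -> dict[str, pd.DataFrame]:
    """Input tables in their published layout (market shares in %, costs)."""
    ms = bia.raw["market_share"]
    years_b = sorted({int(y) for d in ms["before"].values() for y in d})
    years_a = sorted({int(y) for d in ms["after"].values() for y in d})
    rows = {}
    for drug in DRUGS:
        rows[drug] = [round(100 * float(ms["before"][drug].get(y, np.nan)), 2) for y in years_b] + [
            round(100 * float(ms["after"][drug].get(y, np.nan)), 2) for y in years_a
        ]
    cols = [f"before_{y}" for y in years_b] + [f"after_{y}" for y in years_a]
    shares = pd.DataFrame(rows, index=cols).T
    shares.loc["Total"] = shares.sum(axis=0).round(2)

    costs = bia.raw["costs"]
    inputs = pd.DataFrame(
        [
            ("AE prevalence, 2013 (%)", round(100 * float(bia.raw["funnel"]["ae_prevalence_2013"]), 2)),
            ("Annual growth rate of prevalence (%)", round(100 * float(bia.raw["funnel"]["prevalence_annual_growth"]), 2)),
            ("Proportion of patients taking PER low dose (%)", round(100 * bia.dose_mix.low("PER"), 2)),
            ("Proportion of patients taking LCM low dose (%)", round(100 * bia.dose_mix.low("LCM"), 2)),
            ("Annual cost of PER", round(bia.annual_drug_cost["PER"], 2)),
            ("Annual cost of AEDs-PER", float(costs["annual_background_cost"]["PER"])),
            ("Annual cost of LCM", round(bia.annual_drug_cost["LCM"], 2)),
            ("Annual cost of AEDs-LCM", float(costs["annual_background_cost"]["LCM"])),
            ("Annual cost of ZNS", round(bia.annual_drug_cost["ZNS"], 2)),
            ("Annual cost of AEDs-ZNS", float(costs["annual_background_cost"]["ZNS"])),
        ],
        columns=["parameter", "base_case"],
    )
    return {"market_share": shares, "bia_inputs": inputs}
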