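"""Budget-impact model: funnel arithmetic, budgets, reimbursement, DSA."""

import copy

import numpy as np
import pytest

from epicost.budget import (
    DRUGS,
    PopulationFunnel,
    annual_cost_per_patient,
    compute_budget,
    eligible_population,
    export_bia_tables,
    load_bia_config,
    run_bia_dsa,
    treated_patients,
)


def _toy_funnel(**kw):
    defaults = dict(
        year=2021,
        national_population=1e9,
        insured_fraction=0.95,
        age_ge12_fraction=0.9,
        ae_prevalence_2013=0.0024,
        prevalence_annual_growth=0.052,
        partial_onset_fraction=0.6,
        standardized_treatment_fraction=0.4,
    )
    defaults.update(kw)
    return PopulationFunnel(**defaults)


class TestEligiblePopulation:
    def test_direct_product_oracle(self):
        f = _toy_funnel()
        expected = (
            1e9 * 0.95 * 0.9 * 0.0024 * 1.052 ** (2021 - 2013) * 0.6 * 0.4
        )
        assert eligible_population(f) == pytest.approx(expected, rel=1e-12)

    def test_zero_fraction_annihilates(self):
        assert eligible_population(_toy_funnel(partial_onset_fraction=0.0)) == 0.0

    def test_zero_growth_constant_across_years(self):
        a = eligible_population(_toy_funnel(prevalence_annual_growth=0.0, year=2021))
        b = eligible_population(_toy_funnel(prevalence_annual_growth=0.0, year=2023))
        assert a == b

    def test_year_before_reference_rejected(self):
        with pytest.raises(Exception):
            _toy_funnel(year=2010)


class TestTreatedPatients:
    def test_multiplication(self, bia_pset):
        eligible = 1_000_000.0
        out = treated_patients(eligible, bia_pset.shares, 2021, "before")
        assert out["LCM"] == pytest.approx(1_000_000 * 0.0066)

    def test_zero_share(self, bia_pset):
        out = treated_patients(0.0, bia_pset.shares, 2021, "after")
        assert all(v == 0.0 for v in out.values())

    def test_missing_key_is_lookup_error(self, bia_pset):
        with pytest.raises(KeyError):
            bia_pset.shares.get("PER", 2019, "after")
        with pytest.raises(KeyError):
            bia_pset.shares.get("PER", 2020, "after")  # no after-scenario in 2020


class TestAnnualCost:
    def test_zns_drug_component(self, bia_pset):
        drug, _ = annual_cost_per_patient("ZNS", bia_pset)
        assert drug == pytest.approx(700.0 + 670.0)

    def test_dose_weighted_drug_costs(self, bia_pset):
        per, _ = annual_cost_per_patient("PER", bia_pset)
        assert per == pytest.approx(0.6 * 865.0 + 0.4 * 1730.0 + 762.0)
        assert per == pytest.approx(1211.0 + 762.0)
        lcm, _ = annual_cost_per_patient("LCM", bia_pset)
        assert lcm == pytest.approx(1924.0 + 592.0, abs=0.01)

    def test_medical_component_all_seizure_free(self, bia_pset):
        b = bia_pset.with_value(
            "state_mix.after.ZNS",
            {
                "ge53_per_year": 0.0,
                "s13_52_per_year": 0.0,
                "s1_12_per_year": 0.0,
                "seizure_free": 1.0,
            },
        )
        _, med = annual_cost_per_patient("ZNS", b, scenario="after")
        assert med == pytest.approx(180.0 * 3)

    def test_before_scenario_uses_pretreatment_mix(self, bia_pset):
        _, before = annual_cost_per_patient("PER", bia_pset, scenario="before")
        mix = bia_pset.state_mix_before
        assert before == pytest.approx(float(mix @ bia_pset.medical_costs.costs) * 3)


class TestComputeBudget:
    def test_components_reconcile(self, bia_pset):
        result = compute_budget(bia_pset)
        t = result.table
        assert np.allclose(t["total_budget"], t["drug_budget"] + t["medical_budget"], atol=1e-6)
        assert np.allclose(
            t["total_budget"], t["total_URRBMI"] + t["total_UEBMI"], atol=1e-6
        )

    def test_identical_shares_zero_increment(self, bia_pset):
        raw = copy.deepcopy(dict(bia_pset.raw))
        for drug, by_year in raw["market_share"]["after"].items():
            for y in by_year:
                by_year[y] = raw["market_share"]["before"][drug][y]
        # pre-treatment medical mix differs by scenario; align modes first
        raw["medical_mix_mode"] = "after_only"
        b = load_bia_config(raw)
        inc = compute_budget(b).incremental()
        assert np.allclose(inc["total_budget"], 0.0, atol=1e-6)
        for d in DRUGS:
            assert np.allclose(inc[f"treated_{d}"], 0.0, atol=1e-9)

    def test_full_reimbursement_single_scheme_is_pass_through(self, bia_pset):
        raw = copy.deepcopy(dict(bia_pset.raw))
        raw["policy"]["insured_split"] = {"URRBMI": 1.0, "UEBMI": 0.0}
        for ins in ("URRBMI", "UEBMI"):
            raw["policy"]["medical_rates"][ins] = {"outpatient": 1.0, "inpatient": 1.0}
            for st in ("outpatient", "inpatient"):
                raw["policy"]["drug_rates"][ins][st] = {"A": 1.0, "B": 1.0}
        b = load_bia_config(raw)
        result = compute_budget(b)
        year, scen = 2021, "before"
        sub = result.table[(result.table.year == year) & (result.table.scenario == scen)]
        eligible = sub.iloc[0]["eligible"]
        gross = 0.0
        for d in DRUGS:
            n = eligible * b.shares.get(d, year, scen)
            dc, mc = annual_cost_per_patient(d, b, scenario=scen)
            gross += n * (dc + mc)
        assert result.totals(year, scen)["total_budget"] == pytest.approx(gross, rel=1e-12)

    def test_homogeneous_degree_one_in_population(self, bia_pset):
        raw = copy.deepcopy(dict(bia_pset.raw))
        for y in raw["funnel"]["national_population"]:
            raw["funnel"]["national_population"][y] *= 2.0
        doubled = compute_budget(load_bia_config(raw))
        base = compute_budget(bia_pset)
        assert np.allclose(
            doubled.table["total_budget"], 2.0 * base.table["total_budget"], rtol=1e-12
        )
        assert np.allclose(
            doubled.incremental()["total_budget"],
            2.0 * base.incremental()["total_budget"],
            rtol=1e-9,
        )

    def test_incremental_is_after_minus_before(self, bia_pset):
        result = compute_budget(bia_pset)
        inc = result.incremental().set_index("year")
        for y in bia_pset.years:
            diff = (
                result.totals(y, "after")["total_budget"]
                - result.totals(y, "before")["total_budget"]
            )
            assert inc.loc[y, "total_budget"] == pytest.approx(diff, abs=1e-6)

    def test_report_rounding_only_at_emission(self, bia_pset):
        result = compute_budget(bia_pset)
        summary = result.summary_millions()
        # full-precision table unrounded, report in whole persons / 2dp millions
        assert summary["treated"].dtype.kind == "i"
        assert (summary["total_budget"] * 100 % 1 < 1e-9).all()
        assert result.table["treated"].dtype.kind == "f"


class TestBiaDsa:
    def test_zero_width_range_zero_spread(self, bia_pset):
        specs = [
            {
                "name": "degenerate",
                "path": "funnel.ae_prevalence_2013",
                "low": 0.0024,
                "high": 0.0024,
            }
        ]
        df = run_bia_dsa(bia_pset, specs)
        assert np.allclose(df["spread"], 0.0, atol=1e-9)

    def test_prevalence_scales_increment_linearly(self, bia_pset):
        specs = [
            {
                "name": "prevalence",
                "path": "funnel.ae_prevalence_2013",
                "low": 0.0012,
                "high": 0.0048,
            }
        ]
        df = run_bia_dsa(bia_pset, specs).set_index("year")
        for y in bia_pset.years:
            row = df.loc[y]
            assert row["incremental_low"] == pytest.approx(
                0.5 * row["incremental_base"], rel=1e-9
            )
            assert row["incremental_high"] == pytest.approx(
                2.0 * row["incremental_base"], rel=1e-9
            )

    def test_fixture_dsa_includes_drug_price_rows(self, bia_pset):
        df = run_bia_dsa(bia_pset)
        assert "Annual cost of PER" in set(df["parameter"])
        assert (df.groupby("year")["spread"].apply(lambda s: (s.diff().dropna() <= 1e-9).all())).all()


class TestExport:
    def test_published_cells(self, bia_pset):
        tables = export_bia_tables(bia_pset)
        shares = tables["market_share"]
        assert shares.loc["PER", "after_2023"] == 1.25
        assert shares.loc["LCM", "before_2022"] == 1.15
        assert shares.loc["ZNS", "before_2020"] == 0.48
        inputs = tables["bia_inputs"].set_index("parameter")["base_case"]
        assert inputs["Annual cost of PER"] == 1211.0
        assert inputs["Annual cost of ZNS"] == 700.0
        assert inputs["AE prevalence, 2013 (%)"] == 0.24
        assert inputs["Proportion of patients taking PER low dose (%)"] == 60.0
        assert inputs["Proportion of patients taking LCM low dose (%)"] == 68.42
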