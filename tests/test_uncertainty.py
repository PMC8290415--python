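"""DSA, PSA, CEAC and scenario analysis."""

import numpy as np
import pytest

from epicost.params import ConfigError
from epicost.pipeline import run_comparison
from epicost.uncertainty import (
    CeacCurve,
    DsaParameterSpec,
    PsaDistribution,
    PsaResult,
    ceac,
    default_wtp_grid,
    load_dsa_specs,
    load_psa_distributions,
    run_dsa,
    run_psa,
    run_scenario,
    sample_parameters,
)

COMPARISON = ("PER 8 mg/day", "LCM 400 mg/day")


class TestDsa:
    def test_empty_spec_list_gives_empty_table(self, cea_pset):
        df = run_dsa(cea_pset, [], *COMPARISON)
        assert df.empty

    def test_zero_width_range_reproduces_base(self, cea_pset):
        base = run_comparison(cea_pset, *COMPARISON).comparison
        path = "arms.PER 8 mg/day.drug_cost_per_cycle"
        spec = DsaParameterSpec(
            name="degenerate", paths=(path,), low=(1754.0,), high=(1754.0,)
        )
        df = run_dsa(cea_pset, [spec], *COMPARISON)
        row = df.iloc[0]
        assert row["spread"] == pytest.approx(0.0, abs=1e-9)
        assert row["d_qaly_low"] == pytest.approx(base.d_qalys, abs=1e-12)
        assert row["d_cost_low"] == pytest.approx(base.d_total_costs, abs=1e-9)

    def test_fixture_specs_resolve_relative_ranges(self, cea_pset):
        specs = {s.name: s for s in load_dsa_specs(cea_pset)}
        per8 = specs["Drug cost, PER 8 mg/day"]
        assert per8.low[0] == pytest.approx(1754.0 * 0.9)
        assert per8.high[0] == pytest.approx(1754.0 * 1.1)
        lcm = specs["Drug cost, LCM 400 mg/day"]
        assert lcm.low[0] == pytest.approx(2968.0 * 0.8)
        assert lcm.high[0] == pytest.approx(2968.0)
        discount = specs["Discount rate (0-8%)"]
        assert discount.paths == (
            "discount.annual_rate_effects",
            "discount.annual_rate_costs",
        )
        assert discount.low == (0.0, 0.0) and discount.high == (0.08, 0.08)

    def test_tornado_sorted_by_spread(self, cea_pset):
        specs = load_dsa_specs(cea_pset)[:6]
        df = run_dsa(cea_pset, specs, *COMPARISON)
        assert (df["spread"].diff().dropna() <= 1e-9).all()

    def test_response_fluctuation_keeps_distribution_stochastic(self, cea_pset):
        from epicost.uncertainty import _fluctuate_response

        for delta in (-0.2, 0.2):
            p = _fluctuate_response(cea_pset, "PER 8 mg/day", delta)
            dist = p.arm("PER 8 mg/day").first_cycle_response_distribution
            assert abs(dist.sum() - 1.0) < 1e-9
            base = cea_pset.arm("PER 8 mg/day").first_cycle_response_distribution
            # moved shares scaled by (1 + delta): maintenance, 75-99, free
            for idx in (0, 4, 5):
                assert dist[idx] == pytest.approx(base[idx] * (1 + delta), rel=1e-9)


class TestSampling:
    def test_zero_sd_returns_base_exactly(self, cea_pset):
        dists = [
            PsaDistribution("utilities.seizure_free", "beta", 0.711, 0.0),
            PsaDistribution("medical_costs.ge53_per_year", "gamma", 571.0, 0.0),
        ]
        sampled = sample_parameters(cea_pset, dists, 5)
        assert sampled.raw["utilities"]["seizure_free"] == 0.711
        assert sampled.raw["medical_costs"]["ge53_per_year"] == 571.0

    def test_same_seed_identical_sets(self, cea_pset):
        dists = load_psa_distributions(cea_pset)
        a = sample_parameters(cea_pset, dists, 42)
        b = sample_parameters(cea_pset, dists, 42)
        assert a.raw == b.raw

    def test_gamma_method_of_moments_mean(self):
        # law-of-large-numbers check at a fixed seed
        dist = PsaDistribution("medical_costs.ge53_per_year", "gamma", 571.0, 57.1)
        rng = np.random.default_rng(7)
        draws = np.array([dist.draw(rng) for _ in range(10_000)])
        assert abs(draws.mean() - 571.0) / 571.0 < 0.01
        assert abs(draws.std() - 57.1) / 57.1 < 0.05

    def test_beta_moments_and_bounds(self):
        dist = PsaDistribution("utilities.seizure_free", "beta", 0.711, 0.05)
        rng = np.random.default_rng(3)
        draws = np.array([dist.draw(rng) for _ in range(5_000)])
        assert ((draws > 0) & (draws < 1)).all()
        assert abs(draws.mean() - 0.711) < 0.01

    def test_infeasible_beta_moments_rejected(self):
        with pytest.raises(ConfigError, match="too large"):
            PsaDistribution("utilities.seizure_free", "beta", 0.9, 0.5)

    def test_fixture_sd_derived_from_dsa_range(self, cea_pset):
        dists = {d.path: d for d in load_psa_distributions(cea_pset)}
        d = dists["arms.PER 8 mg/day.drug_cost_per_cycle"]
        assert d.family == "gamma"
        assert d.sd == pytest.approx((1754.0 * 1.1 - 1754.0 * 0.9) / (2 * 1.959963984540054))
        u = dists["utilities.seizure_free"]
        assert u.family == "beta" and u.sd == 0.0714


class TestPsa:
    def test_degenerate_distributions_collapse_to_base(self, cea_pset):
        base = run_comparison(cea_pset, *COMPARISON).comparison
        dists = [
            PsaDistribution("utilities.seizure_free", "beta", 0.711, 0.0),
            PsaDistribution("arms.PER 8 mg/day.drug_cost_per_cycle", "gamma", 1754.0, 0.0),
        ]
        result, curve = run_psa(cea_pset, dists, *COMPARISON, iterations=20, seed=1)
        assert np.allclose(result.d_qalys, base.d_qalys, atol=1e-9)
        assert np.allclose(result.d_costs, base.d_total_costs, atol=1e-6)
        # dominant at every sample -> CEAC = 1 everywhere
        assert (curve.probability_cost_effective == 1.0).all()

    def test_seed_reproducibility_bitwise(self, cea_pset):
        dists = load_psa_distributions(cea_pset)
        r1, c1 = run_psa(cea_pset, dists, *COMPARISON, iterations=50, seed=11)
        r2, c2 = run_psa(cea_pset, dists, *COMPARISON, iterations=50, seed=11)
        assert np.array_equal(r1.samples, r2.samples)
        assert np.array_equal(
            c1.probability_cost_effective, c2.probability_cost_effective
        )

    def test_trace_reuse_matches_naive_pipeline(self, cea_pset):
        # the static-trace shortcut must agree with re-running the full
        # pipeline on identically sampled parameter sets
        dists = load_psa_distributions(cea_pset)
        result, _ = run_psa(cea_pset, dists, *COMPARISON, iterations=5, seed=99)
        rng = np.random.default_rng(99)
        for it in range(5):
            overrides = {d.path: d.draw(rng) for d in dists}
            p = cea_pset.with_values(overrides, strict_ordering=False)
            comp = run_comparison(p, *COMPARISON).comparison
            assert result.samples[it, 0] == pytest.approx(comp.d_total_costs, rel=1e-12)
            assert result.samples[it, 1] == pytest.approx(comp.d_qalys, rel=1e-12)

    def test_paper_mode_runs_and_is_reproducible(self, cea_pset):
        dists = load_psa_distributions(cea_pset)
        r1, _ = run_psa(cea_pset, dists, *COMPARISON, iterations=200, seed=5, mode="paper")
        r2, _ = run_psa(cea_pset, dists, *COMPARISON, iterations=200, seed=5, mode="paper")
        assert np.array_equal(r1.samples, r2.samples)
        base = run_comparison(cea_pset, *COMPARISON).comparison
        # unbiased around the base-case increments (loose stochastic check)
        assert abs(r1.d_qalys.mean() - base.d_qalys) < 0.1
        assert np.isfinite(r1.samples).all()

    def test_iterations_must_be_positive(self, cea_pset):
        with pytest.raises(ValueError):
            run_psa(cea_pset, [], *COMPARISON, iterations=0, seed=1)


class TestCeac:
    def _result(self, d_costs, d_qalys):
        s = np.column_stack([d_costs, d_qalys])
        return PsaResult(samples=s, iterations=len(s), seed=0, mode="full-model")

    def test_at_zero_wtp_equals_cost_saving_fraction(self):
        res = self._result([-10.0, 5.0, -1.0, 2.0], [0.1, 0.2, -0.1, 0.3])
        curve = ceac(res, np.array([0.0]))
        assert curve.probability_cost_effective[0] == 0.5

    def test_monotone_when_all_gains_nonnegative(self):
        rng = np.random.default_rng(0)
        res = self._result(rng.normal(0, 100, 500), np.abs(rng.normal(0.05, 0.02, 500)))
        curve = ceac(res, default_wtp_grid())
        assert (np.diff(curve.probability_cost_effective) >= -1e-12).all()

    def test_grid_contains_gdp_anchors(self):
        grid = default_wtp_grid()
        assert 10_838.0 in grid and 32_515.0 in grid

    def test_curve_lookup(self):
        res = self._result([-1.0], [0.1])
        curve = ceac(res, default_wtp_grid())
        assert curve.at(32_515.0) == 1.0
        with pytest.raises(KeyError):
            curve.at(123.456)


class TestScenario:
    def test_zero_increase_probability_reproduces_base(self, cea_pset):
        overrides = {
            "scenario": {
                "arms": {
                    name: {"p_increase": 0.0, "p_responsive": 0.5}
                    for name in cea_pset.arms
                }
            }
        }
        import copy

        raw = copy.deepcopy(dict(cea_pset.raw))
        raw.update(overrides)
        from epicost.params import load_parameter_set

        pset = load_parameter_set(raw)
        base = run_comparison(pset, *COMPARISON).comparison
        scen = run_scenario(pset, *COMPARISON).comparison
        assert scen.d_qalys == pytest.approx(base.d_qalys, abs=1e-12)
        assert scen.d_total_costs == pytest.approx(base.d_total_costs, abs=1e-9)

    def test_scenario_defaults_derived_from_first_cycle(self, cea_pset):
        from epicost.transitions import scenario_spec_for_arm

        spec = scenario_spec_for_arm(cea_pset, "PER 8 mg/day")
        r = cea_pset.arm("PER 8 mg/day").first_cycle_response_distribution
        assert spec.p_increase == pytest.approx(r[1])
        assert spec.p_responsive == pytest.approx(r[3] + r[4] + r[5])

    def test_scenario_worsens_low_responders(self, cea_pset):
        # enabling the <50% -> increase transition moves mass into a state
        # that retains the baseline frequency, so seizure burden cannot fall
        base_i = run_comparison(cea_pset, *COMPARISON).intervention_trace
        scen_i = run_scenario(cea_pset, *COMPARISON).intervention_trace
        base_free = base_i.to_frame()["category_seizure_free"].iloc[-1]
        scen_free = scen_i.to_frame()["category_seizure_free"].iloc[-1]
        assert scen_free <= base_free + 1e-12
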