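"""Random but internally consistent parameter-set generation.

The generator is the test bed's data source: it emits complete model
configurations — two arms, transition inputs, mortality, utilities, costs,
settings — that pass the loader's validation unchanged, so every pipeline
stage is property-testable without any external input file.  Sets are
structurally shaped like the packaged fixture (six response levels, four
seizure categories, two-arm comparison); arbitrary state spaces are a
non-goal.

Arms are drawn independently of one another, so across seeds the comparison
lands in every quadrant of the cost-effectiveness plane (either arm
dominant, or a trade-off).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Any

import numpy as np

from .params import (
    CATEGORY_LABELS,
    LEVEL_LABELS,
    ConfigError,
    ParameterSet,
    load_parameter_set,
)

__all__ = ["SyntheticSpec", "generate_config", "generate_parameter_set", "perturb_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs for the generator; a fixed seed makes generation bit-reproducible."""

    seed: int = 0
    cost_scale: float = 1000.0
    utility_bounds: tuple[float, float] = (0.35, 0.95)
    mortality_intensity: float = 1.0
    starting_age: float = 40.0
    max_age: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.utility_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError("utility bounds must satisfy 0 <= low < high <= 1")
        if self.cost_scale <= 0 or self.mortality_intensity <= 0:
            raise ConfigError("cost_scale and mortality_intensity must be positive")


def _life_table(rng: np.random.Generator, spec: SyntheticSpec) -> list[list[float]]:
    """Gompertz–Makeham annual death probabilities, ages 0..max_age."""
    ages = np.arange(0, int(spec.max_age) + 1)
    makeham = 4e-4 * (1.0 + 0.5 * rng.random())
    b = 3e-5 * (1.0 + 0.5 * rng.random())
    c = 0.09 + 0.02 * rng.random()
    hazard = spec.mortality_intensity * (makeham + b * np.exp(c * ages))
    q = 1.0 - np.exp(-hazard)
    q[-1] = 1.0
    return [[int(a), float(p)] for a, p in zip(ages, q)]


def _arm(rng: np.random.Generator, spec: SyntheticSpec) -> dict[str, Any]:
    baseline = rng.dirichlet([6.0, 3.0, 1.0, 0.3])
    response = rng.dirichlet(np.full(len(LEVEL_LABELS), 1.5))
    return {
        "drug_cost_per_cycle": float(spec.cost_scale * rng.uniform(0.5, 3.0)),
        "background_aed_cost_per_cycle": float(spec.cost_scale * rng.uniform(0.2, 1.0)),
        "baseline_seizure_distribution": {
            lab: float(v) for lab, v in zip(CATEGORY_LABELS, baseline)
        },
        "first_cycle_response_distribution": {
            lab: float(v) for lab, v in zip(LEVEL_LABELS, response)
        },
    }


def generate_config(spec: SyntheticSpec) -> dict[str, Any]:
    """Generate a raw configuration document (same schema the loader consumes)."""
    rng = np.random.default_rng(spec.seed)

    lo, hi = spec.utility_bounds
    utils = np.sort(rng.uniform(lo, hi, size=4))  # ascending: worst state first
    med = np.sort(rng.gamma(3.0, spec.cost_scale / 6.0, size=4))[::-1]
    rr = np.sort(1.0 + rng.gamma(2.0, 3.0, size=3))[::-1]

    config: dict[str, Any] = {
        "settings": {
            "starting_age": float(spec.starting_age),
            "max_age": float(spec.max_age),
            "dead_fraction_termination": 0.999,
            "cny_per_usd": 6.5408,
            "discount_seizures": True,
        },
        "discount": {"annual_rate_effects": 0.05, "annual_rate_costs": 0.05},
        "categories": {
            "ge53_per_year": 104.0,
            "s13_52_per_year": 32.5,
            "s1_12_per_year": 6.5,
            "seizure_free": 0.0,
        },
        "utilities": {lab: float(u) for lab, u in zip(CATEGORY_LABELS, utils)},
        "medical_costs": {lab: float(c) for lab, c in zip(CATEGORY_LABELS, med)},
        "mortality": {
            "life_table": _life_table(rng, spec),
            "rr_by_category": {
                "ge53_per_year": float(rr[0]),
                "s13_52_per_year": float(rr[1]),
                "s1_12_per_year": float(rr[2]),
                "seizure_free": 1.0,
            },
        },
        "arms": {"arm_a": _arm(rng, spec), "arm_b": _arm(rng, spec)},
        "comparisons": [{"intervention": "arm_a", "comparator": "arm_b"}],
        "transitions": {
            "allocation_weights": [float(w) for w in rng.dirichlet([2.0, 2.0])],
            "five_year_probabilities": [
                {
                    "from": "response_lt50",
                    "to": "response_50_99",
                    "probability": float(rng.uniform(0.1, 0.8)),
                },
                {
                    "from": "increase_in_seizures",
                    "to": "response_lt50",
                    "probability": float(rng.uniform(0.0, 0.4)),
                },
            ],
        },
        "scenario": {"default_from_first_cycle": True},
        "dsa": [
            {
                "name": "arm_a drug cost",
                "path": "arms.arm_a.drug_cost_per_cycle",
                "rel_low": -0.2,
                "rel_high": 0.2,
                "basis": "±20%",
            },
            {
                "name": "utility ge53",
                "path": "utilities.ge53_per_year",
                "low": float(max(0.0, utils[0] - 0.1)),
                "high": float(min(utils[3], utils[0] + 0.1)),
                "basis": "±0.1",
            },
        ],
        "psa": [
            {
                "path": "arms.arm_a.drug_cost_per_cycle",
                "family": "gamma",
                "sd": float(0.1 * spec.cost_scale),
            },
            {
                "path": "medical_costs.ge53_per_year",
                "family": "gamma",
                "sd": float(0.1 * med[0]),
            },
            {
                "path": "utilities.seizure_free",
                "family": "beta",
                "sd": 0.03,
            },
        ],
    }
    return config


def generate_parameter_set(spec: SyntheticSpec) -> ParameterSet:
    """Generate and validate a full parameter set (rejection-free)."""
    return load_parameter_set(generate_config(spec))


def perturb_fixture(
    base: ParameterSet, relative_scale: float, seed: int = 0
) -> ParameterSet:
    """Multiplicative jitter on costs, utilities and probability vectors.

    Each perturbed value is scaled by ``1 + relative_scale * U(-1, 1)``;
    probability vectors are renormalised, utilities re-sorted and clipped to
    [0, 1] to preserve validity.  ``relative_scale == 0`` returns the base
    set unchanged.
    """
    if not (0.0 <= relative_scale < 1.0):
        raise ValueError("relative_scale must lie in [0, 1)")
    if relative_scale == 0.0:
        return base
    rng = np.random.default_rng(seed)
    raw = copy.deepcopy(dict(base.raw))

    def jitter(x: float) -> float:
        return float(x) * (1.0 + relative_scale * rng.uniform(-1.0, 1.0))

    for arm in raw["arms"].values():
        arm["drug_cost_per_cycle"] = jitter(arm["drug_cost_per_cycle"])
        arm["background_aed_cost_per_cycle"] = jitter(arm["background_aed_cost_per_cycle"])
        for key in ("baseline_seizure_distribution", "first_cycle_response_distribution"):
            vec = {k: jitter(v) for k, v in arm[key].items()}
            total = sum(vec.values())
            arm[key] = {k: v / total for k, v in vec.items()}
    med = [jitter(raw["medical_costs"][lab]) for lab in CATEGORY_LABELS]
    med = sorted(med, reverse=True)
    raw["medical_costs"] = {lab: v for lab, v in zip(CATEGORY_LABELS, med)}
    utils = sorted(min(1.0, max(0.0, jitter(raw["utilities"][lab]))) for lab in CATEGORY_LABELS)
    raw["utilities"] = {lab: v for lab, v in zip(CATEGORY_LABELS, utils)}
    return load_parameter_set(raw)
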