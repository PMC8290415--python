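import numpy as np
import pytest

from epicost.budget import load_bia_config
from epicost.fixtures import bia_fixture_path, cea_fixture_path
from epicost.params import load_parameter_set


@pytest.fixture(scope="session")
def cea_pset():
    """The packaged perampanel-vs-lacosamide parameter set."""
    return load_parameter_set(cea_fixture_path())


@pytest.fixture(scope="session")
def bia_pset():
    """The packaged budget-impact parameter set."""
    return load_bia_config(bia_fixture_path())


@pytest.fixture()
def flat_mortality_config():
    """Minimal single-arm configuration with a flat, low-mortality life table.

    Handy for closed-form checks: constant 1% annual death probability at
    every age below the terminal age, one baseline stratum, everyone in
    maintenance therapy, no transitions.
    """
    ages = list(range(0, 111))
    table = [[a, 0.01] for a in ages]
    table[-1][1] = 1.0
    return {
        "settings": {"starting_age": 30.0, "max_age": 110.0},
        "discount": {"annual_rate_effects": 0.0, "annual_rate_costs": 0.0},
        "categories": {
            "ge53_per_year": 104.0,
            "s13_52_per_year": 32.5,
            "s1_12_per_year": 6.5,
            "seizure_free": 0.0,
        },
        "utilities": {
            "ge53_per_year": 0.6,
            "s13_52_per_year": 0.6,
            "s1_12_per_year": 0.6,
            "seizure_free": 0.6,
        },
        "medical_costs": {
            "ge53_per_year": 100.0,
            "s13_52_per_year": 50.0,
            "s1_12_per_year": 20.0,
            "seizure_free": 10.0,
        },
        "mortality": {
            "life_table": table,
            "rr_by_category": {
                "ge53_per_year": 1.0,
                "s13_52_per_year": 1.0,
                "s1_12_per_year": 1.0,
                "seizure_free": 1.0,
            },
        },
        "arms": {
            "solo": {
                "drug_cost_per_cycle": 300.0,
                "background_aed_cost_per_cycle": 100.0,
                "baseline_seizure_distribution": {
                    "ge53_per_year": 1.0,
                    "s13_52_per_year": 0.0,
                    "s1_12_per_year": 0.0,
                    "seizure_free": 0.0,
                },
                "first_cycle_response_distribution": {
                    "maintenance_therapy": 0.0,
                    "increase_in_seizures": 1.0,
                    "response_lt50": 0.0,
                    "response_50_74": 0.0,
                    "response_75_99": 0.0,
                    "seizure_free": 0.0,
                },
            }
        },
        "comparisons": [],
        "transitions": {"allocation_weights": [0.5, 0.5], "five_year_probabilities": []},
    }
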