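"""Packaged input fixtures.

``perampanel_lacosamide_cn.yaml`` transcribes the published main-text input
tables for the perampanel-vs-lacosamide comparison (baseline seizure
distributions, first-cycle response distributions, drug and medical costs,
utilities, mortality relative risks, discounting).  Inputs the publication
relegated to supplementary material — the 5-year response-transition
probabilities, the cohort starting age, the budget-impact population funnel,
health-state mixes and reimbursement policy — are shipped as clearly
labelled placeholder values (see the fixture files and docs/methods.md);
the packaged life table is synthetic.
"""

from __future__ import annotations

from pathlib import Path

from .budget import BiaParameters, load_bia_config
from .params import ParameterSet, load_parameter_set

__all__ = [
    "cea_fixture_path",
    "bia_fixture_path",
    "life_table_path",
    "load_cea_fixture",
    "load_bia_fixture",
]

_DATA = Path(__file__).parent / "data"


def cea_fixture_path() -> Path:
    return _DATA / "perampanel_lacosamide_cn.yaml"


def bia_fixture_path() -> Path:
    return _DATA / "bia_perampanel_cn.yaml"


def life_table_path() -> Path:
    return _DATA / "life_table_cn_synthetic.tsv"


def load_cea_fixture() -> ParameterSet:
    """The packaged cost-effectiveness parameter set."""
    return load_parameter_set(cea_fixture_path())


def load_bia_fixture() -> BiaParameters:
    """The packaged budget-impact parameter set."""
    return load_bia_config(bia_fixture_path())
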