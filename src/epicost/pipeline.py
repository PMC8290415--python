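"""Convenience glue: parameter set -> matrix -> trace -> results.

Every analysis stage (base case, DSA, PSA, scenario) re-runs arms through
these helpers, so a perturbed parameter set flows through the identical
pipeline as the base case.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import transitions
from .economics import ArmResult, Comparison, EconInputs, accumulate, compare
from .engine import Trace, run_cohort
from .params import ParameterSet

__all__ = ["ComparisonReport", "econ_inputs", "run_arm", "run_comparison"]


def econ_inputs(pset: ParameterSet) -> EconInputs:
    return EconInputs(
        utilities=pset.utilities.utilities,
        medical_costs=pset.medical_costs.costs,
        discount=pset.discount,
        category_frequencies=pset.category_frequencies,
    )


def run_arm(
    pset: ParameterSet, arm_name: str, scenario: bool = False
) -> tuple[Trace, ArmResult]:
    """Simulate one arm and accumulate its discounted outcomes."""
    arm = pset.arm(arm_name)
    matrix = transitions.matrix_for_arm(pset, arm_name, scenario=scenario)
    trace = run_cohort(
        arm, matrix, pset.mortality, pset.settings, pset.category_frequencies
    )
    result = accumulate(trace, arm, econ_inputs(pset), pset.settings)
    return trace, result


@dataclass(frozen=True)
class ComparisonReport:
    intervention_trace: Trace
    comparator_trace: Trace
    comparison: Comparison


def run_comparison(
    pset: ParameterSet,
    intervention: str,
    comparator: str,
    scenario: bool = False,
) -> ComparisonReport:
    """Run both arms of a comparison through the full pipeline."""
    ti, ri = run_arm(pset, intervention, scenario=scenario)
    tc, rc = run_arm(pset, comparator, scenario=scenario)
    return ComparisonReport(
        intervention_trace=ti,
        comparator_trace=tc,
        comparison=compare(ri, rc),
    )
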