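"""Per-cycle response-level transition matrix construction.

Long-term natural-history data report probabilities of moving between
response bands over five years; the model runs on 4-month cycles, so each
5-year probability p is converted to a per-cycle probability via

    p_cycle = 1 - (1 - p)**(1/15)

(4 months is 1/15 of 5 years; equivalently constant-hazard interval
splitting).  The follow-up literature reports only a merged "<50% -> 50-99%"
improvement probability; that mass is split between the 50-74% and 75-99%
bands by configurable allocation weights.  Unassigned mass in each row stays
on the diagonal (patients remain at their current response level).

The scenario analysis replaces the assumed-zero "<50% -> increase in
seizures" entry with p_increase * (1 - p_responsive), rebalancing the
diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .params import (
    ConfigError,
    LEVEL_LABELS,
    N_LEVELS,
    ParameterSet,
    ResponseLevel,
)

__all__ = [
    "InfeasibleRowError",
    "ScenarioSpec",
    "TransitionInputs",
    "ResponseTransitionMatrix",
    "convert_interval_probability",
    "build_transition_matrix",
    "apply_scenario",
    "transition_inputs_for_arm",
    "scenario_spec_for_arm",
]

#: Pseudo-target label for the merged improvement probability reported in
#: the follow-up literature.
MERGED_UPPER = "response_50_99"

_LT50 = ResponseLevel.RESPONSE_LT50.index
_R50_74 = ResponseLevel.RESPONSE_50_74.index
_R75_99 = ResponseLevel.RESPONSE_75_99.index
_INCREASE = ResponseLevel.INCREASE_IN_SEIZURES.index


class InfeasibleRowError(ConfigError):
    """Converted off-diagonal mass of a transition row exceeds 1."""


def convert_interval_probability(p_long: float, n_subintervals: int) -> float:
    """Convert a probability over a long interval to one per subinterval.

    Assumes a constant hazard across the interval:
    ``1 - (1 - p_long)**(1/n)``.  ``p_long == 1`` maps to 1 (certainty is
    interval-invariant, taken as the limit).
    """
    if n_subintervals < 1:
        raise ValueError("n_subintervals must be >= 1")
    if not (0.0 <= p_long <= 1.0):
        raise ValueError(f"probability {p_long} outside [0, 1]")
    if p_long == 1.0:
        return 1.0
    # log1p/expm1 keep precision for small probabilities
    return -math.expm1(math.log1p(-p_long) / n_subintervals)


@dataclass(frozen=True)
class ScenarioSpec:
    """Scenario-analysis inputs: per-cycle probabilities of seizure increase
    and of being responsive, combined as p_increase * (1 - p_responsive)."""

    p_increase: float
    p_responsive: float

    def __post_init__(self) -> None:
        for attr in ("p_increase", "p_responsive"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"scenario {attr} must lie in [0, 1]")


@dataclass(frozen=True)
class TransitionInputs:
    """5-year transition probabilities plus the <50%->upper-band split.

    ``five_year_probabilities`` maps ``(from_label, to_label)`` to a 5-year
    probability; ``to_label`` may be the merged pseudo-target
    ``"response_50_99"``.  ``allocation_weights`` split that merged mass
    between the 50-74% and 75-99% bands.
    """

    five_year_probabilities: Mapping[tuple[str, str], float]
    allocation_weights: tuple[float, float]
    scenario: ScenarioSpec | None = None

    def __post_init__(self) -> None:
        w = self.allocation_weights
        if len(w) != 2 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ConfigError("allocation weights must be >= 0 and sum to 1")
        for (src, dst), p in self.five_year_probabilities.items():
            if src not in LEVEL_LABELS:
                raise ConfigError(f"transitions: unknown source level {src!r}")
            if dst not in LEVEL_LABELS + (MERGED_UPPER,):
                raise ConfigError(f"transitions: unknown target level {dst!r}")
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"transition {src}->{dst}: probability {p} outside [0, 1]")


@dataclass(frozen=True)
class ResponseTransitionMatrix:
    """Row-stochastic per-cycle transition matrix over the six response levels."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (N_LEVELS, N_LEVELS):
            raise ConfigError("transition matrix must be 6x6")
        if np.any((m < -1e-12) | (m > 1 + 1e-12)):
            raise ConfigError("transition entries must lie in [0, 1]")
        rows = m.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ConfigError(f"transition rows must sum to 1 (got {rows})")
        m = np.clip(m, 0.0, 1.0)
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    def entry(self, src: ResponseLevel, dst: ResponseLevel) -> float:
        return float(self.matrix[src.index, dst.index])


def build_transition_matrix(
    inputs: TransitionInputs, n_subintervals: int = 15
) -> ResponseTransitionMatrix:
    """Build the per-cycle matrix from 5-year probabilities.

    Each supplied probability is interval-converted, the merged
    "<50% -> 50-99%" mass is split by the allocation weights, and each row's
    residual mass is assigned to self-transition.  Raises
    :class:`InfeasibleRowError` if a row's converted off-diagonal mass
    exceeds 1.
    """
    m = np.zeros((N_LEVELS, N_LEVELS))
    w50, w75 = inputs.allocation_weights
    for (src, dst), p5 in inputs.five_year_probabilities.items():
        p = convert_interval_probability(p5, n_subintervals)
        i = LEVEL_LABELS.index(src)
        if dst == MERGED_UPPER:
            m[i, _R50_74] += p * w50
            m[i, _R75_99] += p * w75
        else:
            j = LEVEL_LABELS.index(dst)
            if i == j:
                raise ConfigError(
                    f"transition {src}->{dst}: self-transitions are implicit residuals"
                )
            m[i, j] += p
    off = m.sum(axis=1)
    for i, total in enumerate(off):
        if total > 1.0 + 1e-12:
            raise InfeasibleRowError(
                f"row {LEVEL_LABELS[i]!r}: off-diagonal mass {total:.6g} exceeds 1"
            )
    np.fill_diagonal(m, np.maximum(0.0, 1.0 - off))
    return ResponseTransitionMatrix(m)


def apply_scenario(
    matrix: ResponseTransitionMatrix, spec: ScenarioSpec
) -> ResponseTransitionMatrix:
    """Set the <50% -> increase-in-seizures entry to p_inc*(1-p_resp).

    The row's self-transition absorbs the difference so the row stays
    stochastic; all other rows are unchanged.
    """
    m = np.array(matrix.matrix)
    new_entry = spec.p_increase * (1.0 - spec.p_responsive)
    delta = new_entry - m[_LT50, _INCREASE]
    if m[_LT50, _LT50] - delta < -1e-12:
        raise InfeasibleRowError(
            "scenario entry would drive the <50% self-transition negative"
        )
    m[_LT50, _INCREASE] = new_entry
    m[_LT50, _LT50] = max(0.0, m[_LT50, _LT50] - delta)
    return ResponseTransitionMatrix(m)


# ---------------------------------------------------------------------------
# config plumbing

def transition_inputs_for_arm(pset: ParameterSet, arm_name: str) -> TransitionInputs:
    """Assemble transition inputs for one arm from the raw config.

    Both arms share the natural-history transition block by default;
    ``transitions.arms.<name>`` may override the edge list per arm.
    """
    trans = dict(pset.raw.get("transitions", {}))
    edges = trans.get("five_year_probabilities", [])
    per_arm = trans.get("arms", {}) or {}
    if arm_name in per_arm and "five_year_probabilities" in per_arm[arm_name]:
        edges = per_arm[arm_name]["five_year_probabilities"]
    weights = trans.get("allocation_weights", [0.5, 0.5])
    probs = {(e["from"], e["to"]): float(e["probability"]) for e in edges}
    return TransitionInputs(
        five_year_probabilities=probs,
        allocation_weights=(float(weights[0]), float(weights[1])),
        scenario=scenario_spec_for_arm(pset, arm_name, required=False),
    )


def scenario_spec_for_arm(
    pset: ParameterSet, arm_name: str, required: bool = True
) -> ScenarioSpec | None:
    """Scenario spec for an arm: explicit config values, or the documented
    default derived from the arm's first-cycle response distribution
    (p_increase = increase-in-seizures share; p_responsive = combined
    >=50%-response and seizure-free share)."""
    block = pset.raw.get("scenario", {}) or {}
    arm_block = (block.get("arms") or {}).get(arm_name, {})
    if "p_increase" in arm_block and "p_responsive" in arm_block:
        return ScenarioSpec(
            p_increase=float(arm_block["p_increase"]),
            p_responsive=float(arm_block["p_responsive"]),
        )
    if block.get("default_from_first_cycle", True):
        r = pset.arm(arm_name).first_cycle_response_distribution
        p_inc = float(r[ResponseLevel.INCREASE_IN_SEIZURES.index])
        p_resp = float(
            r[ResponseLevel.RESPONSE_50_74.index]
            + r[ResponseLevel.RESPONSE_75_99.index]
            + r[ResponseLevel.SEIZURE_FREE.index]
        )
        return ScenarioSpec(p_increase=p_inc, p_responsive=p_resp)
    if required:
        raise ConfigError(f"no scenario specification available for arm {arm_name!r}")
    return None


def matrix_for_arm(
    pset: ParameterSet, arm_name: str, scenario: bool = False
) -> ResponseTransitionMatrix:
    """Build the (optionally scenario-adjusted) per-cycle matrix for an arm."""
    inputs = transition_inputs_for_arm(pset, arm_name)
    n_sub = round(5.0 / pset.settings.cycle_length_years)
    matrix = build_transition_matrix(inputs, n_subintervals=n_sub)
    if scenario:
        spec = scenario_spec_for_arm(pset, arm_name, required=True)
        matrix = apply_scenario(matrix, spec)
    return matrix
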