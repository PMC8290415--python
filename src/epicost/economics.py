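"""Discounted outcome accumulation and incremental cost-effectiveness.

Accumulates per-capita seizures, life years, QALYs and costs from a cohort
trace, then compares two arms: incremental values, dominance classification
and ICERs.  Discounting uses discrete annual compounding, ``(1 + r)**(-t)``
with t continuous in years; cycle k is discounted at its end time
``t = k * cycle_length``.

Dominance convention: the intervention *dominates* when it gains QALYs at
lower cost (and symmetrically for the comparator); same-sign increments —
more effect at more cost, or less effect at savings — are a genuine
trade-off and carry ICERs, reported as positive magnitudes
``|dCost / dEffect|`` with orientation given by the signed increments and
the dominance label (signed ICERs are ambiguous across quadrants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    ArmSpec,
    DiscountSpec,
    ModelSettings,
    ResponseLevel,
)
from .engine import Trace

__all__ = [
    "discount_factor",
    "EconInputs",
    "ArmResult",
    "Comparison",
    "accumulate",
    "compare",
    "comparison_table",
]

_MAINT = ResponseLevel.MAINTENANCE_THERAPY.index


def discount_factor(rate: float, time: float) -> float:
    """Discrete-compounding discount factor ``(1 + rate)**(-time)``."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if time < 0:
        raise ValueError("time must be >= 0")
    return (1.0 + rate) ** (-time)


@dataclass(frozen=True)
class EconInputs:
    """Bundle of valuation inputs used by :func:`accumulate`."""

    utilities: np.ndarray
    medical_costs: np.ndarray
    discount: DiscountSpec
    category_frequencies: np.ndarray


@dataclass(frozen=True)
class ArmResult:
    """Discounted per-capita outcomes for one arm."""

    arm_name: str
    seizures: float
    life_years: float
    qalys: float
    drug_costs: float
    medical_costs: float

    @property
    def total_costs(self) -> float:
        return self.drug_costs + self.medical_costs

    def __post_init__(self) -> None:
        for attr in ("seizures", "life_years", "qalys", "drug_costs", "medical_costs"):
            v = getattr(self, attr)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{attr} must be finite and >= 0")
        if self.qalys > self.life_years + 1e-9:
            raise ValueError("QALYs cannot exceed life years")


def accumulate(
    trace: Trace, arm: ArmSpec, econ: EconInputs, settings: ModelSettings
) -> ArmResult:
    """Accumulate discounted outcomes over a trace.

    Per cycle k at time t = k*cycle_length: survivors accrue a full cycle of
    life-time, utility-weighted time, seizures (at the mapped category's
    representative annual frequency) and costs.  Study-drug plus background
    AED cost accrues to every alive cell except maintenance therapy, which by
    default accrues background AEDs only (those patients have withdrawn from
    the study drug).  With the half-cycle option, cells dying within the
    cycle accrue half a cycle instead of none.
    """
    if trace.arm_name != arm.name:
        raise ValueError(
            f"trace is for arm {trace.arm_name!r}, parameters for {arm.name!r}"
        )
    clen = settings.cycle_length_years
    k = np.arange(1, len(trace) + 1)
    t = k * clen
    df_eff = (1.0 + econ.discount.annual_rate_effects) ** (-t)
    df_cost = (1.0 + econ.discount.annual_rate_costs) ** (-t)

    occ = trace.occupancies
    if settings.half_cycle_correction:
        occ = occ + 0.5 * trace.deaths
    cat_occ = trace.category_occupancies(occ)  # (K, 4)
    alive = occ.sum(axis=(1, 2))

    life_years = float(np.sum(alive * clen * df_eff))
    qalys = float(np.sum((cat_occ @ econ.utilities) * clen * df_eff))
    seiz_weights = df_eff if settings.discount_seizures else np.ones_like(df_eff)
    seizures = float(
        np.sum((cat_occ @ econ.category_frequencies) * clen * seiz_weights)
    )

    maint = occ[:, :, _MAINT].sum(axis=1)
    on_drug = alive - maint
    full_cost = arm.drug_cost_per_cycle + arm.background_aed_cost_per_cycle
    maint_cost = (
        arm.background_aed_cost_per_cycle
        if settings.maintenance_drug_policy == "background_only"
        else full_cost
    )
    drug_costs = float(np.sum((on_drug * full_cost + maint * maint_cost) * df_cost))
    medical_costs = float(np.sum((cat_occ @ econ.medical_costs) * df_cost))

    return ArmResult(
        arm_name=arm.name,
        seizures=seizures,
        life_years=life_years,
        qalys=qalys,
        drug_costs=drug_costs,
        medical_costs=medical_costs,
    )


@dataclass(frozen=True)
class Comparison:
    """Incremental results of intervention vs. comparator.

    ``dominance`` is one of ``intervention_dominant``, ``comparator_dominant``,
    ``tradeoff`` or ``indifferent``.  ICERs are positive magnitudes and only
    populated for trade-offs (None otherwise, or when the effect increment is
    zero).
    """

    intervention: ArmResult
    comparator: ArmResult
    d_seizures: float
    d_life_years: float
    d_qalys: float
    d_drug_costs: float
    d_medical_costs: float
    d_total_costs: float
    dominance: str
    icer_per_qaly: float | None
    icer_per_ly: float | None
    icer_per_seizure_avoided: float | None

    @property
    def seizures_avoided(self) -> float:
        return -self.d_seizures


def _ratio(d_cost: float, d_effect: float) -> float | None:
    if d_effect == 0.0:
        return None
    return abs(d_cost / d_effect)


def compare(
    intervention: ArmResult, comparator: ArmResult, wtp: float | None = None
) -> Comparison:
    """Compare two arm results (intervention minus comparator).

    ``wtp`` is accepted for interface symmetry with acceptability analyses
    but does not influence the classification.
    """
    dq = intervention.qalys - comparator.qalys
    dly = intervention.life_years - comparator.life_years
    ds = intervention.seizures - comparator.seizures
    d_drug = intervention.drug_costs - comparator.drug_costs
    d_med = intervention.medical_costs - comparator.medical_costs
    dc = intervention.total_costs - comparator.total_costs

    icer_q = icer_ly = icer_s = None
    if dq == 0.0 and dc == 0.0:
        dominance = "indifferent"
    elif dq >= 0.0 and dc <= 0.0:
        dominance = "intervention_dominant"
    elif dq <= 0.0 and dc >= 0.0:
        dominance = "comparator_dominant"
    else:
        dominance = "tradeoff"
        icer_q = _ratio(dc, dq)
        icer_ly = _ratio(dc, dly)
        icer_s = _ratio(dc, ds)

    return Comparison(
        intervention=intervention,
        comparator=comparator,
        d_seizures=ds,
        d_life_years=dly,
        d_qalys=dq,
        d_drug_costs=d_drug,
        d_medical_costs=d_med,
        d_total_costs=dc,
        dominance=dominance,
        icer_per_qaly=icer_q,
        icer_per_ly=icer_ly,
        icer_per_seizure_avoided=icer_s,
    )


def net_monetary_benefit(comp: Comparison, wtp: float) -> float:
    """Incremental net monetary benefit ``wtp * dQALY - dCost``."""
    return wtp * comp.d_qalys - comp.d_total_costs


def comparison_table(comp: Comparison) -> pd.DataFrame:
    """Absolute / incremental / percent-change table for a comparison.

    Mirrors the conventional base-case layout: one row per outcome, columns
    for each arm's absolute value, the increment, and percent change
    relative to the comparator.
    """
    i, c = comp.intervention, comp.comparator
    rows = [
        ("seizures", i.seizures, c.seizures),
        ("life_years", i.life_years, c.life_years),
        ("qalys", i.qalys, c.qalys),
        ("drug_costs", i.drug_costs, c.drug_costs),
        ("medical_costs", i.medical_costs, c.medical_costs),
        ("total_costs", i.total_costs, c.total_costs),
    ]
    records = []
    for name, vi, vc in rows:
        inc = vi - vc
        pct = (inc / vc * 100.0) if vc != 0 else float("nan")
        records.append((name, vi, vc, inc, pct))
    df = pd.DataFrame(
        records,
        columns=["outcome", i.arm_name, c.arm_name, "incremental", "change_pct"],
    )
    return df
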