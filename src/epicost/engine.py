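"""Cycle-by-cycle cohort simulation.

The living cohort is tracked as a fraction matrix over
(baseline seizure category x current response level); the baseline stratum is
fixed for life because response bands are defined relative to each patient's
own pre-treatment frequency.  Within every 4-month cycle the order of events
is: response-level transition (from cycle 2 on; cycle 1 uses the
trial-observed first-cycle distribution), then mortality, applied to the
seizure category each cell maps to at the cohort's current age.  A trace row
records the cycle's post-mortality survivors together with the cumulative
dead fraction, so alive + dead always sums to 1.  No half-cycle correction is
applied by default: full-cycle membership is credited to the survivors of
each cycle (a half-cycle option credits those who die mid-cycle with half a
cycle).

The loop stops when the dead fraction reaches the configured termination
threshold (99.9% by default) or the cohort reaches ``max_age``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    ArmSpec,
    CATEGORY_LABELS,
    LEVEL_LABELS,
    ModelSettings,
    MortalityInputs,
    N_CATEGORIES,
    N_LEVELS,
    ResponseLevel,
    SeizureCategory,
)
from .transitions import ResponseTransitionMatrix

__all__ = [
    "MIDPOINT_REDUCTIONS",
    "map_response_to_seizure",
    "category_index_matrix",
    "cycle_death_probability",
    "CohortState",
    "Trace",
    "run_cohort",
]

#: Band-midpoint seizure reductions for the fractional response levels.
MIDPOINT_REDUCTIONS = {
    ResponseLevel.RESPONSE_LT50: 0.25,
    ResponseLevel.RESPONSE_50_74: 0.62,
    ResponseLevel.RESPONSE_75_99: 0.87,
}


def map_response_to_seizure(
    baseline: SeizureCategory,
    level: ResponseLevel,
    category_frequencies: np.ndarray,
) -> SeizureCategory:
    """Map a (baseline category, response level) cell to a seizure category.

    Seizure-free response maps to the seizure-free category; maintenance
    therapy and increase-in-seizures retain the baseline category; the
    fractional bands reduce the baseline's representative annual frequency by
    the band midpoint and reclassify by the category bounds.
    """
    if level is ResponseLevel.SEIZURE_FREE:
        return SeizureCategory.SEIZURE_FREE
    if level in (ResponseLevel.MAINTENANCE_THERAPY, ResponseLevel.INCREASE_IN_SEIZURES):
        return baseline
    freq = float(category_frequencies[baseline.index]) * (1.0 - MIDPOINT_REDUCTIONS[level])
    return SeizureCategory.from_annual_frequency(freq)


def category_index_matrix(category_frequencies: np.ndarray) -> np.ndarray:
    """(4, 6) matrix of mapped seizure-category indices per occupancy cell."""
    out = np.empty((N_CATEGORIES, N_LEVELS), dtype=np.intp)
    for cat in SeizureCategory:
        for lev in ResponseLevel:
            out[cat.index, lev.index] = map_response_to_seizure(
                cat, lev, category_frequencies
            ).index
    out.setflags(write=False)
    return out


def cycle_death_probability(
    age: float,
    category: SeizureCategory,
    mortality: MortalityInputs,
    settings: ModelSettings,
) -> float:
    """Per-cycle death probability at a given age and seizure category.

    On the default probability scale the relative risk multiplies the annual
    death probability (capped at 1) before interval conversion:
    ``1 - (1 - min(1, q*rr))**cycle_length``.  On the rate scale the RR
    multiplies the hazard: ``1 - exp(-rr * H * cycle_length)`` with
    ``H = -ln(1 - q)``.
    """
    q = mortality.life_table.annual_probability(age)
    rr = mortality.rr_for(category)
    if settings.mortality_rr_scale == "rate":
        if q >= 1.0:
            return 1.0
        hazard = -math.log1p(-q)
        return -math.expm1(-rr * hazard * settings.cycle_length_years)
    q_adj = min(1.0, q * rr)
    if q_adj >= 1.0:
        return 1.0
    return -math.expm1(math.log1p(-q_adj) * settings.cycle_length_years)


@dataclass(frozen=True)
class CohortState:
    """One cycle of the trace.

    ``occupancy`` holds the post-mortality survivors of the cycle (fractions
    over baseline category x response level); ``deaths`` the fractions that
    died during the cycle; ``dead_fraction`` the cumulative dead share at the
    cycle's end, so ``occupancy.sum() + dead_fraction == 1``.
    """

    occupancy: np.ndarray
    deaths: np.ndarray
    dead_fraction: float
    cohort_age: float
    cycle_index: int


@dataclass(frozen=True)
class Trace:
    """Ordered per-cycle cohort states for one arm, plus the cell->category map."""

    arm_name: str
    states: tuple[CohortState, ...]
    category_index: np.ndarray

    def __len__(self) -> int:
        return len(self.states)

    @property
    def occupancies(self) -> np.ndarray:
        """(K, 4, 6) survivor occupancy per cycle."""
        return np.stack([s.occupancy for s in self.states])

    @property
    def deaths(self) -> np.ndarray:
        return np.stack([s.deaths for s in self.states])

    @property
    def dead_fractions(self) -> np.ndarray:
        return np.array([s.dead_fraction for s in self.states])

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.cohort_age for s in self.states])

    def category_onehot(self) -> np.ndarray:
        """(4, 6, 4) indicator tensor: cell (i, j) -> mapped category c."""
        return (self.category_index[..., None] == np.arange(N_CATEGORIES)).astype(float)

    def category_occupancies(self, occupancies: np.ndarray | None = None) -> np.ndarray:
        """(K, 4) occupancy aggregated onto mapped seizure categories."""
        occ = self.occupancies if occupancies is None else occupancies
        return np.einsum("kij,ijc->kc", occ, self.category_onehot())

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready table: cycle, age, per-level and per-category occupancy, dead."""
        occ = self.occupancies
        level_occ = occ.sum(axis=1)
        cat_occ = self.category_occupancies(occ)
        data = {"cycle": [s.cycle_index for s in self.states], "age": self.ages}
        for j, lab in enumerate(LEVEL_LABELS):
            data[f"level_{lab}"] = level_occ[:, j]
        for c, lab in enumerate(CATEGORY_LABELS):
            data[f"category_{lab}"] = cat_occ[:, c]
        data["dead_fraction"] = self.dead_fractions
        return pd.DataFrame(data)


def run_cohort(
    arm: ArmSpec,
    matrix: ResponseTransitionMatrix,
    mortality: MortalityInputs,
    settings: ModelSettings,
    category_frequencies: np.ndarray,
) -> Trace:
    """Simulate the cohort for one arm until termination.

    Cycle 1 occupancy is the outer product of the baseline seizure
    distribution and the first-cycle response distribution, survival-adjusted
    by mortality at the starting age; later cycles apply the response
    transition matrix within each baseline stratum, then mortality at the
    cohort's current age.
    """
    cat_idx = category_index_matrix(category_frequencies)
    rr_cells = mortality.rr[cat_idx]
    clen = settings.cycle_length_years
    rate_scale = settings.mortality_rr_scale == "rate"

    occupancy = np.outer(
        arm.baseline_seizure_distribution, arm.first_cycle_response_distribution
    )
    dead = 0.0
    m = matrix.matrix
    states: list[CohortState] = []
    cycle = 1
    while True:
        # age derived from the cycle index to avoid floating-point drift
        age = settings.starting_age + (cycle - 1) * clen
        if cycle > 1:
            occupancy = occupancy @ m
        q = mortality.life_table.annual_probability(age)
        if rate_scale:
            if q >= 1.0:
                p_cycle = np.ones_like(rr_cells)
            else:
                p_cycle = -np.expm1(-rr_cells * (-math.log1p(-q)) * clen)
        else:
            q_adj = np.minimum(1.0, q * rr_cells)
            p_cycle = 1.0 - (1.0 - q_adj) ** clen
        deaths = occupancy * p_cycle
        occupancy = occupancy - deaths
        dead += float(deaths.sum())
        states.append(
            CohortState(
                occupancy=occupancy.copy(),
                deaths=deaths,
                dead_fraction=dead,
                cohort_age=age,
                cycle_index=cycle,
            )
        )
        if dead >= settings.dead_fraction_termination:
            break
        if settings.starting_age + cycle * clen >= settings.max_age - 1e-9:
            break
        cycle += 1
    return Trace(arm_name=arm.name, states=tuple(states), category_index=cat_idx)
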