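"""Sensitivity and scenario analyses.

* One-way deterministic sensitivity analysis (DSA): each parameter is set to
  its low and high value in turn, the full pipeline re-runs, and a tornado
  table is emitted.  Because ICERs are undefined in dominance quadrants, rows
  are ranked by the spread of incremental net monetary benefit at a reference
  willingness-to-pay threshold (3x GDP per capita by default).
* Probabilistic sensitivity analysis (PSA): Monte-Carlo sampling of costs
  (Gamma) and utilities (Beta), parameterised by method of moments from
  (mean, sd).  Two modes: ``full-model`` re-evaluates the Markov pipeline per
  draw; ``paper`` samples outcome-level quantities (per-arm life years as a
  Normal, unit costs and utilities) and recombines them against base-case
  occupancy aggregates without re-running the cohort engine.
* Cost-effectiveness acceptability curve (CEAC): fraction of PSA draws with
  positive incremental net benefit across a WTP grid.
* Scenario analysis: re-runs the pipeline with the "<50% -> increase in
  seizures" transition enabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import transitions
from .economics import net_monetary_benefit
from .params import (
    CATEGORY_LABELS,
    ConfigError,
    ParameterSet,
    ResponseLevel,
    get_by_path,
)
from .pipeline import ComparisonReport, econ_inputs, run_arm, run_comparison
from .economics import accumulate

__all__ = [
    "DsaParameterSpec",
    "PsaDistribution",
    "PsaResult",
    "CeacCurve",
    "load_dsa_specs",
    "load_psa_distributions",
    "run_dsa",
    "sample_parameters",
    "run_psa",
    "ceac",
    "default_wtp_grid",
    "run_scenario",
]

#: 1x and 3x Chinese GDP per capita (2019, USD) — conventional WTP anchors.
WTP_LOW = 10_838.0
WTP_HIGH = 32_515.0

#: Config paths whose perturbation changes the cohort trace itself (not just
#: the valuation of a fixed trace).
_TRACE_AFFECTING = (
    "mortality",
    "transitions",
    "settings",
    "categories",
    "scenario",
)
_TRACE_ARM_FIELDS = ("baseline_seizure_distribution", "first_cycle_response_distribution")


def _affects_trace(path: str) -> bool:
    head = path.split(".", 1)[0]
    if head in _TRACE_AFFECTING:
        return True
    return any(f in path for f in _TRACE_ARM_FIELDS)


@dataclass(frozen=True)
class DsaParameterSpec:
    """One tornado row: parameter path(s) with low/high values.

    ``kind`` is ``"value"`` for ordinary dotted-path parameters (``paths``,
    ``low`` and ``high`` run in parallel, so multi-path rows move several
    inputs together, e.g. both discount rates), or ``"response_fluctuation"``
    for the joint perturbation of an arm's maintenance / 75-99% /
    seizure-free first-cycle shares with proportional renormalisation of the
    remaining levels.
    """

    name: str
    paths: tuple[str, ...]
    low: tuple[float, ...]
    high: tuple[float, ...]
    kind: str = "value"
    basis: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("value", "response_fluctuation"):
            raise ConfigError(f"DSA spec {self.name!r}: unknown kind {self.kind!r}")
        if not (len(self.paths) == len(self.low) == len(self.high)):
            raise ConfigError(f"DSA spec {self.name!r}: paths/low/high length mismatch")


@dataclass(frozen=True)
class PsaDistribution:
    """Sampling distribution for one parameter, method-of-moments form."""

    path: str
    family: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "beta", "normal"):
            raise ConfigError(f"PSA {self.path}: unknown family {self.family!r}")
        if self.sd < 0:
            raise ConfigError(f"PSA {self.path}: sd must be >= 0")
        if self.family == "gamma" and self.mean <= 0 and self.sd > 0:
            raise ConfigError(f"PSA {self.path}: gamma needs mean > 0")
        if self.family == "beta":
            if not (0.0 < self.mean < 1.0):
                raise ConfigError(f"PSA {self.path}: beta needs mean in (0, 1)")
            if self.sd > 0:
                nu = self.mean * (1.0 - self.mean) / self.sd**2 - 1.0
                if nu <= 0:
                    raise ConfigError(
                        f"PSA {self.path}: beta sd {self.sd} too large for mean {self.mean}"
                    )

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0.0:
            return self.mean
        if self.family == "gamma":
            shape = (self.mean / self.sd) ** 2
            scale = self.sd**2 / self.mean
            return float(rng.gamma(shape, scale))
        if self.family == "beta":
            nu = self.mean * (1.0 - self.mean) / self.sd**2 - 1.0
            return float(rng.beta(self.mean * nu, (1.0 - self.mean) * nu))
        return float(rng.normal(self.mean, self.sd))


@dataclass(frozen=True)
class PsaResult:
    """Monte-Carlo draws of (incremental cost, incremental QALYs)."""

    samples: np.ndarray  # (iterations, 2): d_cost, d_qaly
    iterations: int
    seed: int
    mode: str

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, float)
        if s.shape != (self.iterations, 2):
            raise ValueError("samples must have shape (iterations, 2)")
        object.__setattr__(self, "samples", s)

    @property
    def d_costs(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def d_qalys(self) -> np.ndarray:
        return self.samples[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=["d_cost", "d_qaly"])


@dataclass(frozen=True)
class CeacCurve:
    """P(cost-effective) across willingness-to-pay thresholds."""

    wtp_grid: np.ndarray
    probability_cost_effective: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.wtp_grid,
                "probability_cost_effective": self.probability_cost_effective,
            }
        )

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        if abs(self.wtp_grid[idx] - wtp) > 1e-9:
            raise KeyError(f"wtp {wtp} not on the grid")
        return float(self.probability_cost_effective[idx])


def default_wtp_grid(
    upper: float = 50_000.0, step: float = 500.0
) -> np.ndarray:
    """0..upper in ``step`` increments, always containing the GDP anchors."""
    grid = np.arange(0.0, upper + step / 2, step)
    grid = np.union1d(grid, [WTP_LOW, WTP_HIGH])
    return grid


# ---------------------------------------------------------------------------
# DSA

def _resolve_bound(base: float, entry: Mapping[str, Any], which: str) -> float:
    if which in entry:
        return float(entry[which])
    rel_key = f"rel_{which}"
    if rel_key in entry:
        return base * (1.0 + float(entry[rel_key]))
    raise ConfigError(f"DSA entry {entry.get('name', '?')!r}: missing {which}/rel_{which}")


def load_dsa_specs(pset: ParameterSet) -> list[DsaParameterSpec]:
    """Parse the config's ``dsa`` section, resolving relative ranges
    (e.g. ±20%) against the base values at load time."""
    specs: list[DsaParameterSpec] = []
    for entry in pset.raw.get("dsa", []) or []:
        name = entry.get("name") or ".".join(
            entry.get("paths", [entry.get("path", "?")])
            if isinstance(entry.get("paths"), list)
            else [entry.get("path", "?")]
        )
        kind = entry.get("kind", "value")
        if kind == "response_fluctuation":
            rel = float(entry.get("relative", 0.2))
            specs.append(
                DsaParameterSpec(
                    name=name,
                    paths=(entry["arm"],),
                    low=(-rel,),
                    high=(rel,),
                    kind="response_fluctuation",
                    basis=entry.get("basis", f"±{rel:.0%} joint fluctuation"),
                )
            )
            continue
        paths = entry.get("paths") or [entry["path"]]
        lows: list[float] = []
        highs: list[float] = []
        for i, p in enumerate(paths):
            base = float(get_by_path(pset.raw, p))
            sub = entry
            if "per_path" in entry:
                sub = entry["per_path"][i]
            lo = _resolve_bound(base, sub, "low")
            hi = _resolve_bound(base, sub, "high")
            if not (min(lo, hi) <= base <= max(lo, hi)):
                raise ConfigError(
                    f"DSA {name!r}: base {base} outside range [{lo}, {hi}] for {p}"
                )
            lows.append(lo)
            highs.append(hi)
        specs.append(
            DsaParameterSpec(
                name=name,
                paths=tuple(paths),
                low=tuple(lows),
                high=tuple(highs),
                basis=entry.get("basis", ""),
            )
        )
    return specs


def _fluctuate_response(
    pset: ParameterSet, arm_name: str, delta: float
) -> ParameterSet:
    """Scale an arm's maintenance / 75-99% / seizure-free first-cycle shares
    by (1 + delta) and renormalise the remaining levels proportionally."""
    dist = dict(pset.raw["arms"][arm_name]["first_cycle_response_distribution"])
    moved = ("maintenance_therapy", "response_75_99", "seizure_free")
    total = sum(float(v) for v in dist.values())
    scaled_sum = sum(float(dist[k]) for k in moved) * (1.0 + delta)
    others = [k for k in dist if k not in moved]
    others_sum = sum(float(dist[k]) for k in others)
    residual = total - scaled_sum
    if residual < 0 or others_sum <= 0:
        raise ConfigError(
            f"response fluctuation {delta:+.0%} infeasible for arm {arm_name!r}"
        )
    new = {k: float(dist[k]) * (1.0 + delta) for k in moved}
    for k in others:
        new[k] = float(dist[k]) * residual / others_sum
    return pset.with_value(
        f"arms.{arm_name}.first_cycle_response_distribution", new
    )


def _apply_spec(
    pset: ParameterSet, spec: DsaParameterSpec, which: str
) -> ParameterSet:
    values = spec.low if which == "low" else spec.high
    if spec.kind == "response_fluctuation":
        return _fluctuate_response(pset, spec.paths[0], values[0])
    return pset.with_values(dict(zip(spec.paths, values)))


def run_dsa(
    pset: ParameterSet,
    specs: Sequence[DsaParameterSpec],
    intervention: str,
    comparator: str,
    scenario: bool = False,
    reference_wtp: float = WTP_HIGH,
) -> pd.DataFrame:
    """One-way DSA tornado table.

    For each spec the pipeline re-runs with only that parameter at its low
    and high value.  Rows are sorted by the spread of incremental net
    monetary benefit at ``reference_wtp`` (descending).
    """
    rows = []
    for spec in specs:
        out: dict[str, Any] = {"parameter": spec.name, "basis": spec.basis}
        for which in ("low", "high"):
            p = _apply_spec(pset, spec, which)
            comp = run_comparison(p, intervention, comparator, scenario=scenario).comparison
            out[f"d_cost_{which}"] = comp.d_total_costs
            out[f"d_qaly_{which}"] = comp.d_qalys
            out[f"dominance_{which}"] = comp.dominance
            out[f"icer_{which}"] = (
                comp.icer_per_qaly if comp.icer_per_qaly is not None else comp.dominance
            )
            out[f"nmb_{which}"] = net_monetary_benefit(comp, reference_wtp)
        out["spread"] = abs(out["nmb_high"] - out["nmb_low"])
        rows.append(out)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("spread", ascending=False, ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# PSA

def load_psa_distributions(pset: ParameterSet) -> list[PsaDistribution]:
    """Parse the config's ``psa`` section.

    ``mean`` defaults to the base value at ``path``.  ``sd`` may be given
    directly, or derived from the matching DSA range by treating it as a 95%
    interval (``sd = (high - low) / (2 * 1.96)``) when ``sd: from_dsa_range``.
    """
    dsa_by_path: dict[str, tuple[float, float]] = {}
    for spec in load_dsa_specs(pset):
        if spec.kind == "value" and len(spec.paths) == 1:
            dsa_by_path[spec.paths[0]] = (spec.low[0], spec.high[0])
    dists: list[PsaDistribution] = []
    for entry in pset.raw.get("psa", []) or []:
        path = entry["path"]
        base = float(get_by_path(pset.raw, path))
        mean = float(entry.get("mean", base))
        sd_raw = entry.get("sd", "from_dsa_range")
        if sd_raw == "from_dsa_range":
            if path not in dsa_by_path:
                raise ConfigError(f"PSA {path}: no DSA range to derive sd from")
            lo, hi = dsa_by_path[path]
            sd = (hi - lo) / (2.0 * 1.959963984540054)
        else:
            sd = float(sd_raw)
        dists.append(
            PsaDistribution(path=path, family=entry["family"], mean=mean, sd=sd)
        )
    return dists


def sample_parameters(
    pset: ParameterSet,
    distributions: Sequence[PsaDistribution],
    rng: np.random.Generator | int,
) -> ParameterSet:
    """Draw one perturbed parameter set (independent draws, fixed order)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    overrides = {d.path: d.draw(rng) for d in distributions}
    if not overrides:
        return pset
    # independent draws may legitimately cross the base-case table orderings
    return pset.with_values(overrides, strict_ordering=False)


def _draw_overrides(
    distributions: Sequence[PsaDistribution], rng: np.random.Generator
) -> dict[str, float]:
    return {d.path: d.draw(rng) for d in distributions}


def run_psa(
    pset: ParameterSet,
    distributions: Sequence[PsaDistribution],
    intervention: str,
    comparator: str,
    iterations: int = 10_000,
    seed: int = 0,
    mode: str = "full-model",
    wtp_grid: np.ndarray | None = None,
    scenario: bool = False,
    ly_sd_fraction: float = 0.1,
) -> tuple[PsaResult, CeacCurve]:
    """Monte-Carlo PSA returning draws and the acceptability curve.

    ``full-model`` mode runs both arms through the Markov pipeline per draw.
    When no sampled path can change the cohort trace (the common case: only
    costs and utilities are sampled), the per-arm traces are computed once
    and re-valued per draw — algebraically identical to re-running the
    engine, since the trace does not depend on valuation inputs.

    ``paper`` mode instead samples per-arm life years from a Normal whose
    mean comes from the model (sd = ``ly_sd_fraction`` of the mean by
    default) together with unit costs and utilities, and recombines them
    against the base-case occupancy aggregates.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if mode not in ("full-model", "paper"):
        raise ValueError(f"unknown PSA mode {mode!r}")
    rng = np.random.default_rng(seed)
    samples = np.empty((iterations, 2))

    if mode == "full-model":
        trace_static = not any(_affects_trace(d.path) for d in distributions)
        if trace_static:
            traces = {
                name: run_arm(pset, name, scenario=scenario)[0]
                for name in (intervention, comparator)
            }
            for it in range(iterations):
                p = pset.with_values(
                    _draw_overrides(distributions, rng), strict_ordering=False
                )
                econ = econ_inputs(p)
                ri = accumulate(traces[intervention], p.arm(intervention), econ, p.settings)
                rc = accumulate(traces[comparator], p.arm(comparator), econ, p.settings)
                samples[it] = (ri.total_costs - rc.total_costs, ri.qalys - rc.qalys)
        else:
            for it in range(iterations):
                p = pset.with_values(
                    _draw_overrides(distributions, rng), strict_ordering=False
                )
                comp = run_comparison(p, intervention, comparator, scenario=scenario).comparison
                samples[it] = (comp.d_total_costs, comp.d_qalys)
    else:
        samples = _run_psa_paper_mode(
            pset, distributions, intervention, comparator, iterations, rng,
            scenario=scenario, ly_sd_fraction=ly_sd_fraction,
        )

    result = PsaResult(samples=samples, iterations=iterations, seed=seed, mode=mode)
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    return result, ceac(result, grid)


def _run_psa_paper_mode(
    pset: ParameterSet,
    distributions: Sequence[PsaDistribution],
    intervention: str,
    comparator: str,
    iterations: int,
    rng: np.random.Generator,
    scenario: bool,
    ly_sd_fraction: float,
) -> np.ndarray:
    """Outcome-level recombination mode.

    Base-case traces supply, per arm, the discounted category-time aggregates
    (for utility weighting and medical costs) and on-/off-study-drug cycle
    counts; each draw then rescales them with sampled life years, utilities
    and unit costs.
    """
    agg = {}
    for name in (intervention, comparator):
        trace, result = run_arm(pset, name, scenario=scenario)
        clen = pset.settings.cycle_length_years
        k = np.arange(1, len(trace) + 1)
        df_e = (1.0 + pset.discount.annual_rate_effects) ** (-(k * clen))
        df_c = (1.0 + pset.discount.annual_rate_costs) ** (-(k * clen))
        occ = trace.occupancies
        cat = trace.category_occupancies(occ)
        maint = occ[:, :, ResponseLevel.MAINTENANCE_THERAPY.index].sum(axis=1)
        alive = occ.sum(axis=(1, 2))
        agg[name] = {
            "ly": result.life_years,
            "tcat_eff": (cat * (clen * df_e)[:, None]).sum(axis=0),  # utility-time
            "ccat_cost": (cat * df_c[:, None]).sum(axis=0),  # medical cycle counts
            "on_drug": float(((alive - maint) * df_c).sum()),
            "maint": float((maint * df_c).sum()),
        }

    samples = np.empty((iterations, 2))
    background_only = pset.settings.maintenance_drug_policy == "background_only"
    for it in range(iterations):
        overrides = _draw_overrides(distributions, rng)
        vals: dict[str, float] = {}
        for name in (intervention, comparator):
            a = agg[name]
            ly = rng.normal(a["ly"], ly_sd_fraction * a["ly"]) if ly_sd_fraction > 0 else a["ly"]
            scale = max(0.0, ly / a["ly"]) if a["ly"] > 0 else 0.0
            raw_arm = pset.raw["arms"][name]
            drug = overrides.get(
                f"arms.{name}.drug_cost_per_cycle", float(raw_arm["drug_cost_per_cycle"])
            )
            bg = overrides.get(
                f"arms.{name}.background_aed_cost_per_cycle",
                float(raw_arm["background_aed_cost_per_cycle"]),
            )
            u = np.array(
                [
                    overrides.get(f"utilities.{lab}", float(pset.raw["utilities"][lab]))
                    for lab in CATEGORY_LABELS
                ]
            )
            med = np.array(
                [
                    overrides.get(
                        f"medical_costs.{lab}", float(pset.raw["medical_costs"][lab])
                    )
                    for lab in CATEGORY_LABELS
                ]
            )
            qaly = scale * float(a["tcat_eff"] @ np.clip(u, 0.0, 1.0))
            maint_cost = bg if background_only else drug + bg
            cost = (
                a["on_drug"] * (drug + bg)
                + a["maint"] * maint_cost
                + float(a["ccat_cost"] @ np.maximum(med, 0.0))
            )
            vals[name] = (cost, qaly)
        ci, qi = vals[intervention]
        cc, qc = vals[comparator]
        samples[it] = (ci - cc, qi - qc)
    return samples


def ceac(result: PsaResult, wtp_grid: np.ndarray) -> CeacCurve:
    """Acceptability curve: share of draws with positive incremental net
    benefit ``wtp * dQALY - dCost`` at each threshold."""
    grid = np.asarray(wtp_grid, float)
    nb = grid[:, None] * result.d_qalys[None, :] - result.d_costs[None, :]
    prob = (nb > 0).mean(axis=1)
    return CeacCurve(wtp_grid=grid, probability_cost_effective=prob)


# ---------------------------------------------------------------------------
# scenario

def run_scenario(
    pset: ParameterSet, intervention: str, comparator: str
) -> ComparisonReport:
    """Re-run the pipeline with the scenario-adjusted transition matrices."""
    return run_comparison(pset, intervention, comparator, scenario=True)
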