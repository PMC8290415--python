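"""Parameter model for a lifetime Markov cohort cost-effectiveness analysis.

The model compares two add-on anti-seizure regimens in a cohort of patients
with partial-onset seizures.  Health states are defined on two layers:

* a *response level* — the percent reduction in seizure frequency relative to
  the patient's own baseline (six bands, from "maintenance therapy" — patients
  withdrawn from the study drug — through "increase in seizures", "<50%",
  "50–74%", "75–99%", to fully seizure-free); and
* a *seizure-frequency category* — the absolute seizure frequency band
  (≥53/year, 13–52/year, 1–12/year, seizure-free) that utilities, medical
  costs and excess mortality attach to.

This module holds the validated domain types for every model input, the
structured-text (YAML) configuration loader, currency conversion, and the
verbatim export of the packaged input tables.  Monetary amounts are stored in
USD internally; CNY appears only at the conversion boundary.
"""

from __future__ import annotations

import copy
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "NormalizationError",
    "ResponseLevel",
    "SeizureCategory",
    "RESPONSE_LEVELS",
    "SEIZURE_CATEGORIES",
    "ArmSpec",
    "LifeTable",
    "MortalityInputs",
    "UtilitySet",
    "MedicalCostSet",
    "DiscountSpec",
    "ModelSettings",
    "ParameterSet",
    "load_parameter_set",
    "load_life_table",
    "convert_currency",
    "get_by_path",
    "set_by_path",
    "export_tables",
    "collect_errors",
]

#: Tolerance within which a probability vector is silently renormalised.
#: Published tables are rounded to two decimals, so printed rows can sum to
#: e.g. 99.99%; anything further from 1 is treated as a genuine input error.
NORMALIZATION_TOLERANCE = 5e-3


class ConfigError(ValueError):
    """A configuration document violates the input schema."""


class NormalizationError(ConfigError):
    """A probability vector does not sum to 1 beyond rounding tolerance."""


class ResponseLevel(enum.Enum):
    """Treatment-response band: percent seizure reduction from baseline."""

    MAINTENANCE_THERAPY = "maintenance_therapy"
    INCREASE_IN_SEIZURES = "increase_in_seizures"
    RESPONSE_LT50 = "response_lt50"
    RESPONSE_50_74 = "response_50_74"
    RESPONSE_75_99 = "response_75_99"
    SEIZURE_FREE = "seizure_free"

    @property
    def index(self) -> int:
        return _LEVEL_INDEX[self]


RESPONSE_LEVELS: tuple[ResponseLevel, ...] = tuple(ResponseLevel)
_LEVEL_INDEX = {lev: i for i, lev in enumerate(RESPONSE_LEVELS)}
LEVEL_LABELS = tuple(lev.value for lev in RESPONSE_LEVELS)


class SeizureCategory(enum.Enum):
    """Absolute seizure-frequency band; bounds [53, inf), [13, 52], [1, 12], {0}."""

    GE53 = "ge53_per_year"
    S13_52 = "s13_52_per_year"
    S1_12 = "s1_12_per_year"
    SEIZURE_FREE = "seizure_free"

    @property
    def index(self) -> int:
        return _CATEGORY_INDEX[self]

    @classmethod
    def from_annual_frequency(cls, frequency: float) -> "SeizureCategory":
        """Classify an annual seizure count into a category.

        Band boundaries fall halfway between adjacent integer bounds
        (52.5, 12.5) and a half-integer boundary is assigned downward, so
        e.g. 12.5 seizures/year lands in the 1–12 band.
        """
        if frequency > 52.5:
            return cls.GE53
        if frequency > 12.5:
            return cls.S13_52
        if frequency > 0:
            return cls.S1_12
        return cls.SEIZURE_FREE


SEIZURE_CATEGORIES: tuple[SeizureCategory, ...] = tuple(SeizureCategory)
_CATEGORY_INDEX = {cat: i for i, cat in enumerate(SEIZURE_CATEGORIES)}
CATEGORY_LABELS = tuple(cat.value for cat in SEIZURE_CATEGORIES)

N_LEVELS = len(RESPONSE_LEVELS)
N_CATEGORIES = len(SEIZURE_CATEGORIES)


def _readonly(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    a.setflags(write=False)
    return a


def _probability_vector(
    mapping: Mapping[str, float], labels: Sequence[str], name: str
) -> np.ndarray:
    """Build a validated probability vector ordered by ``labels``.

    Vectors whose entries sum to 1 within :data:`NORMALIZATION_TOLERANCE`
    (printed-table rounding) are renormalised exactly; anything further off
    raises :class:`NormalizationError` naming the offending vector.
    """
    missing = [lab for lab in labels if lab not in mapping]
    if missing:
        raise ConfigError(f"{name}: missing entries for {missing}")
    extra = [k for k in mapping if k not in labels]
    if extra:
        raise ConfigError(f"{name}: unknown entries {extra}")
    vec = np.array([float(mapping[lab]) for lab in labels], dtype=float)
    if np.any(vec < 0) or not np.all(np.isfinite(vec)):
        raise ConfigError(f"{name}: entries must be finite and >= 0")
    total = vec.sum()
    if abs(total - 1.0) > NORMALIZATION_TOLERANCE:
        raise NormalizationError(f"{name}: probabilities sum to {total:.6g}, not 1")
    return _readonly(vec / total)


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: per-cycle drug costs and initial distributions.

    Costs are USD per 4-month cycle.  ``baseline_seizure_distribution`` is
    over the four seizure-frequency categories; ``first_cycle_response_distribution``
    is over the six response levels (the trial-observed first-cycle outcome).
    """

    name: str
    drug_cost_per_cycle: float
    background_aed_cost_per_cycle: float
    baseline_seizure_distribution: np.ndarray
    first_cycle_response_distribution: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("drug_cost_per_cycle", "background_aed_cost_per_cycle"):
            v = getattr(self, attr)
            if not (math.isfinite(v) and v >= 0):
                raise ConfigError(f"arm {self.name!r}: {attr} must be finite and >= 0")
        b = np.asarray(self.baseline_seizure_distribution, float)
        r = np.asarray(self.first_cycle_response_distribution, float)
        if b.shape != (N_CATEGORIES,) or r.shape != (N_LEVELS,):
            raise ConfigError(f"arm {self.name!r}: distribution shapes invalid")
        for name, vec in (("baseline", b), ("first-cycle response", r)):
            if abs(vec.sum() - 1.0) > 1e-9 or np.any(vec < 0):
                raise NormalizationError(
                    f"arm {self.name!r}: {name} distribution invalid"
                )
        object.__setattr__(self, "baseline_seizure_distribution", _readonly(b))
        object.__setattr__(self, "first_cycle_response_distribution", _readonly(r))


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities over a contiguous age range.

    The terminal age must carry probability 1 (everyone dies by the table's
    end); lookups beyond the terminal age return 1.
    """

    start_age: int
    annual_q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.annual_q, float)
        if q.ndim != 1 or q.size < 2:
            raise ConfigError("life table needs at least two ages")
        if np.any((q < 0) | (q > 1)) or not np.all(np.isfinite(q)):
            raise ConfigError("life-table probabilities must lie in [0, 1]")
        if q[-1] != 1.0:
            raise ConfigError("life table must end with probability 1 at terminal age")
        object.__setattr__(self, "annual_q", _readonly(q))

    @property
    def terminal_age(self) -> int:
        return self.start_age + len(self.annual_q) - 1

    def annual_probability(self, age: float) -> float:
        """Annual death probability at ``floor(age)``; 1 beyond the table."""
        idx = int(math.floor(age)) - self.start_age
        if idx < 0:
            raise ConfigError(f"age {age} below life-table range")
        if idx >= len(self.annual_q):
            return 1.0
        return float(self.annual_q[idx])

    def to_pairs(self) -> list[list[float]]:
        return [[self.start_age + i, float(q)] for i, q in enumerate(self.annual_q)]


@dataclass(frozen=True)
class MortalityInputs:
    """Life table plus per-category mortality relative risks.

    ``rr`` is ordered like :data:`SEIZURE_CATEGORIES`; the seizure-free
    category carries the general-population risk (RR exactly 1).
    """

    life_table: LifeTable
    rr: np.ndarray

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr, float)
        if rr.shape != (N_CATEGORIES,):
            raise ConfigError("mortality RR vector must cover all four categories")
        if rr[SeizureCategory.SEIZURE_FREE.index] != 1.0:
            raise ConfigError("rr(seizure_free) must equal 1 exactly")
        if np.any(rr < 1.0) or not np.all(np.isfinite(rr)):
            raise ConfigError("mortality RRs must be finite and >= 1")
        object.__setattr__(self, "rr", _readonly(rr))

    def rr_for(self, category: SeizureCategory) -> float:
        return float(self.rr[category.index])


@dataclass(frozen=True)
class UtilitySet:
    """Per-category health-state utility weights (per-year, applied pro rata)."""

    utilities: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.utilities, float)
        if u.shape != (N_CATEGORIES,):
            raise ConfigError("utility vector must cover all four categories")
        if np.any((u < 0) | (u > 1)):
            raise ConfigError("utilities must lie in [0, 1]")
        object.__setattr__(self, "utilities", _readonly(u))


@dataclass(frozen=True)
class MedicalCostSet:
    """Per-category medical-service costs, USD per 4-month cycle."""

    costs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, float)
        if c.shape != (N_CATEGORIES,):
            raise ConfigError("medical-cost vector must cover all four categories")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ConfigError("medical costs must be finite and >= 0")
        object.__setattr__(self, "costs", _readonly(c))


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rates for health effects and for costs."""

    annual_rate_effects: float = 0.05
    annual_rate_costs: float = 0.05

    def __post_init__(self) -> None:
        for attr in ("annual_rate_effects", "annual_rate_costs"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 0.5):
                raise ConfigError(f"discount {attr} must lie in [0, 0.5]")


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings.

    The cycle length is fixed at 4 months (1/3 year, the medication-review
    interval); the cohort loop terminates once 99.9% of the cohort is dead or
    ``max_age`` is reached.  ``maintenance_drug_policy`` controls whether the
    maintenance-therapy level (patients withdrawn from the study drug) still
    accrues the study-drug cost (``"full"``) or background AEDs only
    (``"background_only"``, the default).  ``mortality_rr_scale`` selects
    whether relative risks multiply the annual death probability
    (``"probability"``) or the hazard rate (``"rate"``).
    """

    cycle_length_years: float = 1.0 / 3.0
    dead_fraction_termination: float = 0.999
    starting_age: float = 33.0
    max_age: float = 100.0
    cny_per_usd: float = 6.5408
    discount_seizures: bool = True
    half_cycle_correction: bool = False
    maintenance_drug_policy: str = "background_only"
    mortality_rr_scale: str = "probability"

    def __post_init__(self) -> None:
        if self.cycle_length_years * 3.0 != 1.0:
            raise ConfigError("cycle_length_years must be exactly one third of a year")
        if not (0.0 < self.dead_fraction_termination < 1.0):
            raise ConfigError("dead_fraction_termination must lie in (0, 1)")
        if not self.starting_age < self.max_age:
            raise ConfigError("starting_age must be below max_age")
        if self.cny_per_usd <= 0:
            raise ConfigError("cny_per_usd must be positive")
        if self.maintenance_drug_policy not in ("background_only", "full"):
            raise ConfigError("maintenance_drug_policy must be background_only or full")
        if self.mortality_rr_scale not in ("probability", "rate"):
            raise ConfigError("mortality_rr_scale must be probability or rate")

    @property
    def cycles_per_year(self) -> int:
        return round(1.0 / self.cycle_length_years)


def convert_currency(amount_cny: float, settings: ModelSettings) -> float:
    """Convert a CNY amount to USD at the configured fixed exchange rate."""
    if not math.isfinite(amount_cny):
        raise ValueError("currency amount must be finite")
    return amount_cny / settings.cny_per_usd


# ---------------------------------------------------------------------------
# dotted-path access into raw config mappings (used by DSA/PSA perturbation)

def get_by_path(mapping: Mapping[str, Any], path: str) -> Any:
    node: Any = mapping
    for part in path.split("."):
        if isinstance(node, Mapping):
            if part not in node:
                raise KeyError(f"path {path!r}: no key {part!r}")
            node = node[part]
        elif isinstance(node, list):
            node = node[int(part)]
        else:
            raise KeyError(f"path {path!r}: cannot descend into {type(node).__name__}")
    return node


def set_by_path(mapping: dict, path: str, value: Any) -> None:
    parts = path.split(".")
    node: Any = mapping
    for part in parts[:-1]:
        if isinstance(node, Mapping):
            if part not in node:
                raise KeyError(f"path {path!r}: no key {part!r}")
            node = node[part]
        elif isinstance(node, list):
            node = node[int(part)]
        else:
            raise KeyError(f"path {path!r}: cannot descend into {type(node).__name__}")
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    elif isinstance(node, dict):
        if last not in node:
            raise KeyError(f"path {path!r}: no key {last!r}")
        node[last] = value
    else:
        raise KeyError(f"path {path!r}: cannot set on {type(node).__name__}")


# ---------------------------------------------------------------------------
# loader

@dataclass(frozen=True)
class ParameterSet:
    """Immutable, validated model-input bundle.

    ``raw`` keeps the (life-table-inlined) configuration document so that
    sensitivity analyses can perturb any input by dotted path and re-validate,
    and so that serialisation round-trips exactly.
    """

    raw: Mapping[str, Any]
    settings: ModelSettings
    discount: DiscountSpec
    category_frequencies: np.ndarray
    utilities: UtilitySet
    medical_costs: MedicalCostSet
    mortality: MortalityInputs
    arms: Mapping[str, ArmSpec]
    comparisons: tuple[tuple[str, str], ...]

    def arm(self, name: str) -> ArmSpec:
        try:
            return self.arms[name]
        except KeyError:
            raise ConfigError(f"unknown arm {name!r}") from None

    def with_values(
        self, overrides: Mapping[str, Any], strict_ordering: bool = True
    ) -> "ParameterSet":
        """Return a new validated set with dotted-path overrides applied.

        ``strict_ordering=False`` skips the cross-parameter ordering checks
        (seizure-free utility highest, medical costs monotone) that describe
        the base-case tables but may legitimately be crossed by independent
        probabilistic draws.
        """
        raw = copy.deepcopy(dict(self.raw))
        for path, value in overrides.items():
            set_by_path(raw, path, value)
        return load_parameter_set(raw, strict_ordering=strict_ordering)

    def with_value(self, path: str, value: Any) -> "ParameterSet":
        return self.with_values({path: value})

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(
            _plain(copy.deepcopy(dict(self.raw))), sort_keys=False, width=100
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays for clean YAML emission."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    return obj


def load_life_table(source: str | Path) -> LifeTable:
    """Read a two-column delimited life table (age, annual death probability).

    A header row is required; comma, tab or whitespace delimiters accepted.
    """
    path = Path(source)
    rows: list[tuple[int, float]] = []
    lines = path.read_text().strip().splitlines()
    if not lines:
        raise ConfigError(f"life table {path} is empty")
    for line in lines[1:]:  # skip header
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ConfigError(f"life table {path}: malformed line {line!r}")
        rows.append((int(float(parts[0])), float(parts[1])))
    return _life_table_from_pairs(rows, str(path))


def _life_table_from_pairs(pairs: Sequence[Sequence[float]], name: str) -> LifeTable:
    if not pairs:
        raise ConfigError(f"life table {name}: empty")
    ages = [int(a) for a, _ in pairs]
    if ages != list(range(ages[0], ages[0] + len(ages))):
        raise ConfigError(f"life table {name}: ages must be contiguous integers")
    return LifeTable(start_age=ages[0], annual_q=np.array([q for _, q in pairs]))


def _category_mapping(section: Mapping[str, Any], name: str) -> np.ndarray:
    missing = [lab for lab in CATEGORY_LABELS if lab not in section]
    if missing:
        raise ConfigError(f"{name}: missing categories {missing}")
    return np.array([float(section[lab]) for lab in CATEGORY_LABELS])


def load_parameter_set(
    source: str | Path | Mapping[str, Any], strict_ordering: bool = True
) -> ParameterSet:
    """Load and validate a full parameter set from YAML or a mapping.

    External life-table files referenced by ``mortality.life_table_file`` are
    resolved relative to the config file and inlined, so the returned set is
    self-contained (serialisable and perturbable without filesystem access).
    ``strict_ordering`` additionally enforces the base-case table orderings
    (seizure-free utility highest; medical costs non-increasing with falling
    seizure frequency); probabilistic sampling disables it.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = copy.deepcopy(dict(raw))
        base_dir = path.parent
    else:
        raw = copy.deepcopy(dict(source))
        base_dir = Path(".")

    for key in ("arms", "utilities", "medical_costs", "mortality", "categories"):
        if key not in raw:
            raise ConfigError(f"config: missing required section {key!r}")

    settings = ModelSettings(**raw.get("settings", {}))
    discount = DiscountSpec(**raw.get("discount", {}))

    freqs = _category_mapping(raw["categories"], "categories")
    if freqs[SeizureCategory.SEIZURE_FREE.index] != 0.0:
        raise ConfigError("categories: seizure_free frequency must be 0")
    nonfree = freqs[: N_CATEGORIES - 1]
    if np.any(nonfree <= 0) or np.any(np.diff(nonfree) >= 0):
        raise ConfigError(
            "categories: representative frequencies must be positive and strictly decreasing"
        )

    utilities = UtilitySet(_category_mapping(raw["utilities"], "utilities"))
    medical = MedicalCostSet(_category_mapping(raw["medical_costs"], "medical_costs"))
    if strict_ordering:
        u = utilities.utilities
        if u[SeizureCategory.SEIZURE_FREE.index] < u.max() - 1e-12:
            raise ConfigError("utilities: seizure-free utility must be the highest")
        if np.any(np.diff(medical.costs) > 1e-9):
            raise ConfigError(
                "medical_costs: must be non-increasing from the highest-frequency category"
            )

    mort_raw = dict(raw["mortality"])
    if "life_table" in mort_raw:
        table = _life_table_from_pairs(mort_raw["life_table"], "mortality.life_table")
    elif "life_table_file" in mort_raw:
        table = load_life_table(base_dir / mort_raw["life_table_file"])
        mort_raw.pop("life_table_file")
        mort_raw["life_table"] = table.to_pairs()
        raw["mortality"] = mort_raw
    else:
        raise ConfigError("mortality: needs life_table or life_table_file")
    rr = _category_mapping(mort_raw["rr_by_category"], "mortality.rr_by_category")
    mortality = MortalityInputs(life_table=table, rr=rr)

    if settings.starting_age < table.start_age:
        raise ConfigError("starting_age below the life table's age range")

    arms: dict[str, ArmSpec] = {}
    arms_raw = raw["arms"]
    if not isinstance(arms_raw, Mapping) or not arms_raw:
        raise ConfigError("arms: must be a non-empty mapping of arm name -> spec")
    for name, spec in arms_raw.items():
        arms[name] = ArmSpec(
            name=name,
            drug_cost_per_cycle=float(spec["drug_cost_per_cycle"]),
            background_aed_cost_per_cycle=float(spec["background_aed_cost_per_cycle"]),
            baseline_seizure_distribution=_probability_vector(
                spec["baseline_seizure_distribution"],
                CATEGORY_LABELS,
                f"arm {name!r} baseline_seizure_distribution",
            ),
            first_cycle_response_distribution=_probability_vector(
                spec["first_cycle_response_distribution"],
                LEVEL_LABELS,
                f"arm {name!r} first_cycle_response_distribution",
            ),
        )

    comparisons: list[tuple[str, str]] = []
    for entry in raw.get("comparisons", []):
        i, c = entry["intervention"], entry["comparator"]
        for nm in (i, c):
            if nm not in arms:
                raise ConfigError(f"comparisons: unknown arm {nm!r}")
        comparisons.append((i, c))

    # transition inputs are parsed by epicost.transitions; validate references here
    trans = raw.get("transitions", {})
    for edge in trans.get("five_year_probabilities", []):
        if edge["from"] not in LEVEL_LABELS:
            raise ConfigError(f"transitions: unknown level {edge['from']!r}")
        if edge["to"] not in LEVEL_LABELS + ("response_50_99",):
            raise ConfigError(f"transitions: unknown level {edge['to']!r}")

    return ParameterSet(
        raw=raw,
        settings=settings,
        discount=discount,
        category_frequencies=_readonly(freqs),
        utilities=utilities,
        medical_costs=medical,
        mortality=mortality,
        arms=arms,
        comparisons=tuple(comparisons),
    )


def collect_errors(source: str | Path | Mapping[str, Any]) -> list[str]:
    """Validate a config document, returning *all* section-level failures.

    Used by the CLI's ``validate-config`` so a malformed file produces an
    itemised report rather than stopping at the first error.
    """
    try:
        if isinstance(source, (str, Path)):
            raw = yaml.safe_load(Path(source).read_text())
        else:
            raw = dict(source)
        if not isinstance(raw, Mapping):
            return ["top level must be a mapping"]
    except Exception as exc:  # unreadable document
        return [f"unreadable config: {exc}"]

    errors: list[str] = []

    def attempt(label: str, fn) -> None:
        try:
            fn()
        except Exception as exc:
            errors.append(f"{label}: {exc}")

    attempt("settings", lambda: ModelSettings(**raw.get("settings", {})))
    attempt("discount", lambda: DiscountSpec(**raw.get("discount", {})))
    if "utilities" in raw:
        attempt("utilities", lambda: UtilitySet(_category_mapping(raw["utilities"], "utilities")))
    else:
        errors.append("utilities: missing section")
    if "medical_costs" in raw:
        attempt(
            "medical_costs",
            lambda: MedicalCostSet(_category_mapping(raw["medical_costs"], "medical_costs")),
        )
    else:
        errors.append("medical_costs: missing section")
    for name, spec in (raw.get("arms") or {}).items():
        attempt(
            f"arm {name!r}",
            lambda spec=spec, name=name: (
                _probability_vector(
                    spec["baseline_seizure_distribution"], CATEGORY_LABELS, "baseline"
                ),
                _probability_vector(
                    spec["first_cycle_response_distribution"], LEVEL_LABELS, "response"
                ),
                ArmSpec(
                    name=name,
                    drug_cost_per_cycle=float(spec["drug_cost_per_cycle"]),
                    background_aed_cost_per_cycle=float(
                        spec["background_aed_cost_per_cycle"]
                    ),
                    baseline_seizure_distribution=_probability_vector(
                        spec["baseline_seizure_distribution"], CATEGORY_LABELS, "baseline"
                    ),
                    first_cycle_response_distribution=_probability_vector(
                        spec["first_cycle_response_distribution"], LEVEL_LABELS, "response"
                    ),
                ),
            ),
        )
    # re-validate the whole document from its original source so relative
    # life-table paths resolve against the config file's directory
    attempt("full document", lambda: load_parameter_set(source))
    # deduplicate while keeping order
    seen: set[str] = set()
    out = []
    for e in errors:
        if e not in seen:
            seen.add(e)
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# verbatim table export

def export_tables(pset: ParameterSet) -> dict[str, pd.DataFrame]:
    """Export the model-input tables in their published layout.

    Percentages and dollar figures are rounded to the printed precision so
    the packaged fixture reproduces its source tables cell for cell.
    """
    cat_cols = ["≥53 times/year", "13–52 times/year", "1–12 times/year", "Seizures free"]
    lev_cols = [
        "Maintenance therapy",
        "Increase in seizure",
        "<50% Response",
        "50–74% Response",
        "75–99% Response",
        "Seizure free",
    ]
    arm_names = list(pset.arms)
    baseline = pd.DataFrame(
        [
            [
                round(100 * float(pset.raw["arms"][n]["baseline_seizure_distribution"][lab]), 2)
                for lab in CATEGORY_LABELS
            ]
            for n in arm_names
        ],
        index=arm_names,
        columns=cat_cols,
    )
    response = pd.DataFrame(
        [
            [
                round(100 * float(pset.raw["arms"][n]["first_cycle_response_distribution"][lab]), 2)
                for lab in LEVEL_LABELS
            ]
            for n in arm_names
        ],
        index=arm_names,
        columns=lev_cols,
    )
    rows = []
    for lab, col in zip(CATEGORY_LABELS, cat_cols):
        rows.append(("Relative risk of mortality", col, float(pset.raw["mortality"]["rr_by_category"][lab])))
    for n in arm_names:
        rows.append(("Drug costs per 4 months ($)", n, float(pset.raw["arms"][n]["drug_cost_per_cycle"])))
        rows.append(("Drug costs per 4 months ($)", f"AEDs – {n} group", float(pset.raw["arms"][n]["background_aed_cost_per_cycle"])))
    for lab, col in zip(CATEGORY_LABELS, cat_cols):
        rows.append(("Medical costs per 4 months ($)", col, float(pset.raw["medical_costs"][lab])))
    for lab, col in zip(CATEGORY_LABELS, cat_cols):
        rows.append(("Health utilities per 4 months", col, float(pset.raw["utilities"][lab])))
    inputs = pd.DataFrame(rows, columns=["block", "parameter", "base_case"])
    return {"baseline_distribution": baseline, "first_cycle_response": response, "model_inputs": inputs}
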