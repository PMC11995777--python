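"""Core domain types for the dietary health-impact assessment pipeline.

Everything in the model is stratified by single year of age (0–95, closed;
age 95 is terminal) and by sex (female, male).  Rates are annual
probabilities (risks), not hazards; producers of input data are responsible
for any hazard-to-risk conversion.  Arrays are indexed ``[age, sex]`` with
sex 0 = female, 1 = male, and, where exposure enters, a trailing category
axis in the order the :class:`ExposureModel` declares its categories.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

AGE_MAX = 95
N_AGES = AGE_MAX + 1
AGES = np.arange(N_AGES)
SEXES = ("female", "male")
N_SEXES = 2

__all__ = [
    "AGE_MAX",
    "N_AGES",
    "AGES",
    "SEXES",
    "N_SEXES",
    "PopulationStructure",
    "DiseaseEpidemiology",
    "RuleKind",
    "GuidelineComponent",
    "ExposureCategory",
    "ExposureModel",
    "RelativeRiskTable",
    "SimulationConfig",
    "InputBundle",
    "validate_bundle",
]


def _as_age_sex(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.shape != (N_AGES, N_SEXES):
        raise ValueError(f"{name} must have shape ({N_AGES}, {N_SEXES}), got {arr.shape}")
    return arr


@dataclass
class PopulationStructure:
    """Population counts, annual newborn inflow and total mortality.

    ``count[age, sex]`` is the number of persons alive at the start of the
    simulation; ``newborns[sex]`` the persons entering at age 0 each
    simulated year (no migration is modeled); ``total_mortality[age, sex]``
    the all-cause annual death probability.  Age 95 is terminal: everyone
    reaching it dies within the year.
    """

    count: np.ndarray
    newborns: np.ndarray
    total_mortality: np.ndarray

    def __post_init__(self) -> None:
        self.count = _as_age_sex(self.count, "count")
        self.total_mortality = _as_age_sex(self.total_mortality, "total_mortality")
        self.newborns = np.asarray(self.newborns, dtype=float)
        if self.newborns.shape != (N_SEXES,):
            raise ValueError(f"newborns must have shape ({N_SEXES},)")

    def violations(self) -> list[str]:
        out = []
        if not np.all(np.isfinite(self.count)) or np.any(self.count < 0):
            out.append("PopulationStructure: counts must be finite and >= 0")
        if np.any(self.newborns < 0) or not np.all(np.isfinite(self.newborns)):
            out.append("PopulationStructure: newborns must be finite and >= 0")
        if np.any(self.total_mortality < 0) or np.any(self.total_mortality > 1):
            out.append("PopulationStructure: total_mortality must lie in [0, 1]")
        if not np.allclose(self.total_mortality[AGE_MAX], 1.0):
            out.append("PopulationStructure: total_mortality at age 95 must equal 1 (terminal age)")
        return out


@dataclass
class DiseaseEpidemiology:
    """Age/sex epidemiology of one modeled non-communicable disease.

    ``incidence`` and ``excess_mortality`` are annual probabilities;
    ``prevalence`` is the baseline proportion diseased; ``excess_mortality``
    is the mortality of the diseased minus that of the disease-free.
    ``acute_fatal_fraction`` is the share of incident cases dying
    immediately at onset and may be non-zero only when ``acute`` is set
    (coronary heart disease and stroke in the motivating application).
    """

    disease_id: str
    incidence: np.ndarray
    prevalence: np.ndarray
    excess_mortality: np.ndarray
    acute_fatal_fraction: np.ndarray
    acute: bool = False

    def __post_init__(self) -> None:
        for name in ("incidence", "prevalence", "excess_mortality", "acute_fatal_fraction"):
            setattr(self, name, _as_age_sex(getattr(self, name), name))

    def violations(self) -> list[str]:
        out = []
        for name in ("incidence", "prevalence", "excess_mortality", "acute_fatal_fraction"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
                out.append(f"DiseaseEpidemiology[{self.disease_id}]: {name} must lie in [0, 1]")
        if not self.acute and np.any(self.acute_fatal_fraction > 0):
            out.append(
                f"DiseaseEpidemiology[{self.disease_id}]: acute_fatal_fraction > 0 "
                "on a disease not flagged acute"
            )
        return out


class RuleKind(str, enum.Enum):
    AT_LEAST = "at_least"
    AT_MOST = "at_most"
    WITHIN_BAND = "within_band"
    EXACTLY_ZERO = "exactly_zero"


@dataclass(frozen=True)
class GuidelineComponent:
    """One food-group recommendation, e.g. fruit >= 200 g/d or processed meat 0 g/d."""

    food_group: str
    rule_kind: RuleKind
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        kind = RuleKind(self.rule_kind)
        object.__setattr__(self, "rule_kind", kind)
        for b in (self.lower, self.upper):
            if b is not None and b < 0:
                raise ValueError("guideline bounds must be >= 0")
        if kind is RuleKind.AT_LEAST and self.lower is None:
            raise ValueError("at_least rule needs a lower bound")
        if kind is RuleKind.AT_MOST and self.upper is None:
            raise ValueError("at_most rule needs an upper bound")
        if kind is RuleKind.WITHIN_BAND:
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError("within_band rule needs lower < upper")


@dataclass(frozen=True)
class ExposureCategory:
    label: str
    intake: float  # representative intake, g/day
    adherent: bool


@dataclass
class ExposureModel:
    """Categorical exposure distribution for one food group.

    ``prevalence[age, sex, category]`` gives the probability of being in
    each consumption category; per stratum the categories sum to one.
    """

    food_group: str
    categories: list[ExposureCategory]
    prevalence: np.ndarray

    def __post_init__(self) -> None:
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        k = len(self.categories)
        if self.prevalence.shape != (N_AGES, N_SEXES, k):
            raise ValueError(
                f"prevalence must have shape ({N_AGES}, {N_SEXES}, {k}), got {self.prevalence.shape}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def adherent_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.categories) if c.adherent]

    def violations(self, rule: GuidelineComponent | None = None) -> list[str]:
        out = []
        sums = self.prevalence.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = np.argwhere(np.abs(sums - 1.0) > 1e-9)
            a, s = bad[0]
            out.append(
                f"ExposureModel[{self.food_group}]: category prevalences sum to "
                f"{sums[a, s]:.6f} != 1 at age {a}, sex {SEXES[s]}"
            )
        if np.any(self.prevalence < 0):
            out.append(f"ExposureModel[{self.food_group}]: negative category prevalence")
        if not self.adherent_indices:
            out.append(f"ExposureModel[{self.food_group}]: no adherent category")
        if rule is not None:
            from .exposure import classify_intake  # local import avoids a cycle

            for i, c in enumerate(self.categories):
                if classify_intake(c.intake, rule) != c.adherent:
                    out.append(
                        f"ExposureModel[{self.food_group}]: category '{c.label}' adherence "
                        f"flag inconsistent with rule at intake {c.intake} g/d"
                    )
        return out


@dataclass
class RelativeRiskTable:
    """Relative risks of one food group on one disease, by category and age band.

    ``rr``, ``ci_low``, ``ci_high`` have shape ``(n_categories, n_bands,
    n_sexes)``; ``bands`` is a list of inclusive ``(age_low, age_high)``
    tuples.  The reference category has RR 1 with a degenerate CI.
    """

    food_group: str
    disease_id: str
    category_labels: list[str]
    bands: list[tuple[int, int]]
    rr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reference_category: str

    def __post_init__(self) -> None:
        shape = (len(self.category_labels), len(self.bands), N_SEXES)
        for name in ("rr", "ci_low", "ci_high"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)

    def violations(self) -> list[str]:
        out = []
        name = f"RelativeRiskTable[{self.food_group}/{self.disease_id}]"
        if np.any(self.rr <= 0) or np.any(self.ci_low <= 0) or np.any(self.ci_high <= 0):
            out.append(f"{name}: relative risks and CI bounds must be > 0")
        if np.any(self.ci_low > self.rr + 1e-12) or np.any(self.ci_high < self.rr - 1e-12):
            out.append(f"{name}: CI must bracket the point estimate (ci_low <= rr <= ci_high)")
        if self.reference_category not in self.category_labels:
            out.append(f"{name}: unknown reference category '{self.reference_category}'")
        else:
            iref = self.category_labels.index(self.reference_category)
            ref_ok = (
                np.allclose(self.rr[iref], 1.0)
                and np.allclose(self.ci_low[iref], 1.0)
                and np.allclose(self.ci_high[iref], 1.0)
            )
            if not ref_ok:
                out.append(f"{name}: reference category must have RR 1 with degenerate CI")
        lows = [b[0] for b in self.bands]
        for (l1, h1), (l2, h2) in zip(self.bands, self.bands[1:]):
            if l2 <= h1:
                out.append(f"{name}: overlapping or unsorted age bands {((l1, h1), (l2, h2))}")
        if sorted(lows) != lows:
            out.append(f"{name}: age bands must be sorted")
        return out


class SimulationConfig(BaseModel):
    """Run configuration for the life-table simulation."""

    start_year: int = 2020
    horizon_years: int = Field(default=30, ge=1)
    report_years: list[int] = Field(default_factory=lambda: [2030, 2040, 2050])
    le_ages: list[int] = Field(default_factory=lambda: [0, 50, 70])
    adult_min_age: int = 19
    mc_reps: int = Field(default=100, ge=2)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        last = self.start_year + self.horizon_years
        for y in self.report_years:
            if not self.start_year <= y <= last:
                raise ValueError(f"report year {y} outside {self.start_year}..{last}")
        for a in self.le_ages:
            if not 0 <= a <= AGE_MAX:
                raise ValueError(f"life-expectancy age {a} outside 0..{AGE_MAX}")
        return self


@dataclass
class InputBundle:
    """All validated inputs for one assessment run."""

    population: PopulationStructure
    diseases: dict[str, DiseaseEpidemiology]
    exposures: dict[str, ExposureModel]
    rr_tables: dict[tuple[str, str], RelativeRiskTable]
    guidelines: dict[str, GuidelineComponent] = field(default_factory=dict)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.diseases)


def validate_bundle(bundle: InputBundle) -> list[str]:
    """Check every domain invariant; return the list of violations (empty = valid).

    Side-effect free and deterministic; violations are returned, never raised.
    """
    out: list[str] = []
    out += bundle.population.violations()
    for dis in bundle.diseases.values():
        out += dis.violations()
    for group, exp in bundle.exposures.items():
        out += exp.violations(bundle.guidelines.get(group))
    for (group, disease_id), table in bundle.rr_tables.items():
        out += table.violations()
        if group not in bundle.exposures:
            out.append(f"RelativeRiskTable[{group}/{disease_id}]: no exposure model for '{group}'")
        else:
            labels = [c.label for c in bundle.exposures[group].categories]
            if table.category_labels != labels:
                out.append(
                    f"RelativeRiskTable[{group}/{disease_id}]: categories do not match "
                    f"the exposure model for '{group}'"
                )
        if disease_id not in bundle.diseases:
            out.append(f"RelativeRiskTable[{group}/{disease_id}]: unknown disease '{disease_id}'")
    return out
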