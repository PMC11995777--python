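"""Guideline adherence, categorical exposure models and scenario construction.

The reference ("business-as-usual") scenario keeps the observed age- and
sex-specific distribution over consumption categories constant over the
simulation; the counterfactual moves the whole population onto the
guideline-adherent category from the start year onward.  Category
definitions (labels, representative intakes, adherence flags) are shared
between the two scenarios so that the only difference is the prevalence
vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    AGE_MAX,
    N_AGES,
    N_SEXES,
    SEXES,
    ExposureCategory,
    ExposureModel,
    GuidelineComponent,
    RuleKind,
)

__all__ = [
    "classify_intake",
    "adherence_prevalence",
    "build_exposure_model",
    "build_scenarios",
    "ScenarioPair",
]

logger = logging.getLogger(__name__)


def classify_intake(intake: float, rule: GuidelineComponent) -> bool:
    """Return whether an intake (g/day) meets a guideline component."""
    if intake < 0:
        raise ValueError(f"intake must be >= 0, got {intake}")
    kind = rule.rule_kind
    if kind is RuleKind.AT_LEAST:
        return intake >= rule.lower
    if kind is RuleKind.AT_MOST:
        return intake <= rule.upper
    if kind is RuleKind.WITHIN_BAND:
        return rule.lower <= intake <= rule.upper
    return intake == 0  # exactly_zero


def adherence_prevalence(intakes, rule: GuidelineComponent) -> float:
    """Fraction of a consumption sample meeting the guideline component."""
    intakes = np.asarray(intakes, dtype=float)
    if intakes.size == 0:
        raise ValueError("adherence_prevalence needs a non-empty sample")
    return float(np.mean([classify_intake(x, rule) for x in intakes.ravel()]))


def _adherent_mask(intakes: np.ndarray, rule: GuidelineComponent) -> np.ndarray:
    if np.any(intakes < 0):
        raise ValueError("intakes must be >= 0")
    kind = rule.rule_kind
    if kind is RuleKind.AT_LEAST:
        return intakes >= rule.lower
    if kind is RuleKind.AT_MOST:
        return intakes <= rule.upper
    if kind is RuleKind.WITHIN_BAND:
        return (intakes >= rule.lower) & (intakes <= rule.upper)
    return intakes == 0


def build_exposure_model(
    intakes: pd.DataFrame,
    rule: GuidelineComponent,
    n_categories: int = 4,
    adult_min_age: int = 19,
) -> ExposureModel:
    """Build a categorical exposure model from individual intake observations.

    Parameters
    ----------
    intakes
        DataFrame with columns ``age`` (years), ``sex`` (female/male) and
        ``intake`` (g/day); one row per observed person.
    rule
        The guideline component defining adherence for this food group.
    n_categories
        Total number of categories: one adherent category plus
        ``n_categories - 1`` quantile bins of the non-adherent intakes.

    Category boundaries and representative intakes (within-category
    medians) are computed from the pooled sample; per-stratum prevalences
    come from that stratum's observations.  A single-year age/sex stratum
    with no observations borrows prevalences from a widening pooled-sex
    age window (logged); ages below the youngest observed adult age reuse
    that age's prevalences.
    """
    if n_categories < 2:
        raise ValueError("need at least an adherent and one non-adherent category")
    missing = {"age", "sex", "intake"} - set(intakes.columns)
    if missing:
        raise ValueError(f"intakes frame missing columns {sorted(missing)}")

    values = intakes["intake"].to_numpy(float)
    adherent = _adherent_mask(values, rule)
    non_adh = values[~adherent]

    categories: list[ExposureCategory] = []
    adh_intake = float(np.median(values[adherent])) if adherent.any() else _rule_target(rule)
    categories.append(ExposureCategory("adherent", adh_intake, True))

    n_bins = n_categories - 1
    if non_adh.size:
        qs = np.quantile(non_adh, np.linspace(0, 1, n_bins + 1))
        # collapse duplicate edges from ties; keep bins well defined
        edges = np.unique(qs)
        if len(edges) < 2:
            edges = np.array([edges[0], edges[0]])
        bin_of = np.clip(np.searchsorted(edges, non_adh, side="right") - 1, 0, len(edges) - 2)
    else:
        edges = np.array([0.0, 0.0])
        bin_of = np.array([], dtype=int)
    for b in range(n_bins):
        members = non_adh[bin_of == b] if b < len(edges) - 1 else np.array([])
        if members.size:
            rep = float(np.median(members))
        else:
            rep = _nonadherent_target(rule)  # empty bin: keep the flag consistent
        categories.append(ExposureCategory(f"non_adherent_{b + 1}", rep, False))

    def assign(vals: np.ndarray) -> np.ndarray:
        """Category index per intake value under the pooled definitions."""
        out = np.zeros(len(vals), dtype=int)
        mask = ~_adherent_mask(vals, rule)
        if mask.any() and non_adh.size:
            b = np.clip(np.searchsorted(edges, vals[mask], side="right") - 1, 0, len(edges) - 2)
            out[mask] = 1 + np.clip(b, 0, n_bins - 1)
        elif mask.any():
            out[mask] = 1
        return out

    ages_obs = intakes["age"].to_numpy(int)
    sex_obs = intakes["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy(int)
    cat_obs = assign(values)

    prevalence = np.zeros((N_AGES, N_SEXES, n_categories))
    min_obs_age = int(ages_obs.min())
    for s in range(N_SEXES):
        for age in range(N_AGES):
            lookup_age = max(age, min_obs_age) if age < adult_min_age else age
            sel = (ages_obs == lookup_age) & (sex_obs == s)
            if not sel.any():
                # widen the window symmetrically, pooling both sexes
                for width in range(1, N_AGES):
                    sel = np.abs(ages_obs - lookup_age) <= width
                    if sel.any():
                        logger.info(
                            "exposure %s: no observations at age %d sex %s; pooled ages %d±%d",
                            rule.food_group, age, SEXES[s], lookup_age, width,
                        )
                        break
            counts = np.bincount(cat_obs[sel], minlength=n_categories)
            prevalence[age, s] = counts / counts.sum()

    return ExposureModel(food_group=rule.food_group, categories=categories, prevalence=prevalence)


def _nonadherent_target(rule: GuidelineComponent) -> float:
    """A representative non-adherent intake for a category with no members."""
    if rule.rule_kind is RuleKind.EXACTLY_ZERO:
        return 1.0
    if rule.rule_kind is RuleKind.AT_LEAST:
        return float(rule.lower) / 2.0 if rule.lower > 0 else 0.0
    return float(rule.upper) + 1.0  # at_most / within_band


def _rule_target(rule: GuidelineComponent) -> float:
    """A representative adherent intake when no adherent observation exists."""
    if rule.rule_kind is RuleKind.EXACTLY_ZERO:
        return 0.0
    if rule.rule_kind is RuleKind.AT_LEAST:
        return float(rule.lower)
    if rule.rule_kind is RuleKind.AT_MOST:
        return float(rule.upper)
    return float(0.5 * (rule.lower + rule.upper))


@dataclass
class ScenarioPair:
    """Reference (observed) and counterfactual (fully adherent) exposures.

    Both scenarios hold prevalences constant over time (no net drift), so
    the transition probabilities between categories are degenerate.
    """

    reference: ExposureModel
    counterfactual: ExposureModel
    transition_rule: str = "constant-prevalence"


def build_scenarios(exposure: ExposureModel) -> ScenarioPair:
    """Build the reference/counterfactual scenario pair for one food group.

    The counterfactual puts the whole population on the adherent category
    (probability 1 for every age and sex) from the start year onward; if
    several categories are flagged adherent the mass goes to the first.
    Category definitions are shared with the reference.
    """
    adherent = exposure.adherent_indices
    if not adherent:
        raise ValueError(f"exposure model for '{exposure.food_group}' has no adherent category")
    cf_prev = np.zeros_like(exposure.prevalence)
    cf_prev[:, :, adherent[0]] = 1.0
    counterfactual = ExposureModel(
        food_group=exposure.food_group,
        categories=list(exposure.categories),
        prevalence=cf_prev,
    )
    return ScenarioPair(reference=exposure, counterfactual=counterfactual)
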