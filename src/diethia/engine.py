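"""Deterministic multi-state life-table core.

Every birth cohort × sex × exposure category is advanced through annual
cycles over the simulation horizon.  Three kinds of health state are
tracked — free of all modeled non-communicable diseases (NCDs), having any
combination of them, and dead — with the full joint disease-state space
(``2^D`` alive states for ``D`` diseases) so that competing risks and
multimorbidity are bookkept exactly.

Annual cycle, in order (documented so the stochastic agent oracle can use
the identical sequence):

1. *Incidence.* For each alive joint state ``S`` and each disease
   ``d ∉ S``, a fraction ``i_d`` (the exposure-category-calibrated
   incidence) transitions to ``S ∪ {d}``.  Diseases are applied
   independently (product expansion), so simultaneous multi-incidence is
   possible.  Of newly incident cases of an acute disease, the acutely
   fatal fraction dies immediately.
2. *Mortality.* Each resulting alive state ``S`` dies with probability
   ``q(S) = min(1, m_other + Σ_{d∈S} μ_d)``: other-cause mortality plus
   the additive excess mortalities of the diseases present.

3. *Aging and churn.* Survivors age one year; newborn cohorts enter
   disease-free at age 0.  Risk-factor churn then restores the scenario's
   category distribution among the living at every age and sex
   (constant-prevalence transition rule, independent of disease state) —
   without it, selective mortality would let the living population's
   category mix drift away from the prevalences the scenario holds fixed.

Remission is not modeled; the dead state is absorbing; mass is conserved
exactly.  Age 95 is terminal — the mortality step kills everyone at that
age.  There is no migration: cohorts enter only at birth (newborn inflow)
or as the initial population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import (
    AGE_MAX,
    N_AGES,
    N_SEXES,
    SEXES,
    DiseaseEpidemiology,
    ExposureModel,
    InputBundle,
    PopulationStructure,
    SimulationConfig,
)
from .exposure import build_scenarios
from .risk import calibrate_incidence, expand_rr_by_age

__all__ = [
    "TransitionRates",
    "AggregatedResults",
    "CohortLifeTable",
    "other_cause_mortality",
    "mortality_of_state",
    "advance_cohort_year",
    "initialize_cohorts",
    "build_transition_rates",
    "simulate",
    "run_scenario_pair",
    "state_labels",
]

logger = logging.getLogger(__name__)


def other_cause_mortality(total_mortality, diseases) -> np.ndarray:
    """Mortality of the disease-free population.

    Prevalence-weighted excess mortality of each modeled disease is
    subtracted from total mortality: ``m_other = m − Σ_d π_d · μ_d``,
    floored at 0 (floored cells are logged).  ``diseases`` is an iterable
    of ``(prevalence, excess_mortality)`` pairs broadcastable against
    ``total_mortality``.
    """
    m = np.asarray(total_mortality, dtype=float)
    out = m.copy()
    for prev, excess in diseases:
        out = out - np.asarray(prev, float) * np.asarray(excess, float)
    n_neg = int(np.sum(out < 0))
    if n_neg:
        logger.warning("other-cause mortality negative in %d cells; floored at 0", n_neg)
        out = np.maximum(out, 0.0)
    return out


@dataclass
class TransitionRates:
    """All annual transition probabilities for one scenario run.

    ``incidence`` is the calibrated per-category incidence with shape
    ``(D, age, sex, category)``; ``excess_mortality`` and
    ``acute_fatal_fraction`` are ``(D, age, sex)``;
    ``other_mortality`` is ``(age, sex)``.
    """

    disease_ids: list[str]
    incidence: np.ndarray
    excess_mortality: np.ndarray
    acute_fatal_fraction: np.ndarray
    other_mortality: np.ndarray

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)


def mortality_of_state(state, rates: TransitionRates, age: int, sex: int) -> float:
    """Annual death probability of a joint disease state.

    ``state`` is an iterable of disease ids (empty = NCD-free).  The
    NCD-free state dies at the other-cause mortality; a diseased state
    adds the excess mortality of each disease present, capped at 1.
    """
    q = rates.other_mortality[age, sex]
    for disease_id in state:
        if disease_id not in rates.disease_ids:
            raise ValueError(f"unknown disease '{disease_id}' in state")
        d = rates.disease_ids.index(disease_id)
        q += rates.excess_mortality[d, age, sex]
    return float(min(q, 1.0))


def advance_cohort_year(
    occupancy: np.ndarray,
    incidence: np.ndarray,
    excess_mortality: np.ndarray,
    acute_fatal_fraction: np.ndarray,
    other_mortality: np.ndarray,
    terminal: np.ndarray | bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance occupancy through one annual cycle.

    ``occupancy`` has shape ``(..., 2^D + 1)``: the ``2^D`` alive joint
    states indexed by disease bitmask (state 0 = disease-free) followed by
    the absorbing dead state.  The rate arrays have a leading disease axis
    (``incidence``, ``excess_mortality``, ``acute_fatal_fraction``:
    shape ``(D, ...)``) or none (``other_mortality``) and must broadcast
    against the leading axes of ``occupancy``.  ``terminal`` marks strata
    whose mortality is forced to 1 (the terminal age).

    Returns ``(next_occupancy, incident, deaths)`` where ``incident`` has
    shape ``(D, ...)`` counting new cases per disease (acute deaths
    included) and ``deaths`` the total deaths of the cycle.
    """
    occ = np.asarray(occupancy, dtype=float)
    squeeze = occ.ndim == 1
    if squeeze:  # single-cohort convenience form
        occ = occ[None, :]
    if np.any(occ < 0):
        raise ValueError("occupancy must be non-negative")
    incidence = np.asarray(incidence, dtype=float)
    n_dis = incidence.shape[0]
    n_alive = 1 << n_dis
    if occ.shape[-1] != n_alive + 1:
        raise ValueError(f"occupancy last axis must be {n_alive + 1} (2^D alive states + dead)")
    occ = occ.copy()
    lead = occ.shape[:-1]
    incident = np.zeros((n_dis,) + lead)
    deaths = np.zeros(lead)

    # 1. incidence, one disease at a time (equivalent to the product
    #    expansion over simultaneous incidences), acute deaths immediate
    for d in range(n_dis):
        bit = 1 << d
        i_d = np.broadcast_to(incidence[d], lead)
        f_d = np.broadcast_to(acute_fatal_fraction[d], lead)
        for s in range(n_alive):
            if s & bit:
                continue
            moving = occ[..., s] * i_d
            incident[d] += moving
            acute_deaths = moving * f_d
            occ[..., s] = occ[..., s] - moving
            occ[..., s | bit] = occ[..., s | bit] + moving - acute_deaths
            occ[..., n_alive] = occ[..., n_alive] + acute_deaths
            deaths += acute_deaths

    # 2. state-dependent mortality
    m_other = np.broadcast_to(other_mortality, lead)
    term = np.broadcast_to(terminal, lead)
    for s in range(n_alive):
        q = m_other.copy()
        for d in range(n_dis):
            if s & (1 << d):
                q = q + np.broadcast_to(excess_mortality[d], lead)
        q = np.where(term, 1.0, np.minimum(q, 1.0))
        dying = occ[..., s] * q
        occ[..., s] = occ[..., s] - dying
        occ[..., n_alive] = occ[..., n_alive] + dying
        deaths += dying

    if squeeze:
        return occ[0], incident[:, 0], deaths[0]
    return occ, incident, deaths


def initialize_cohorts(
    population: PopulationStructure,
    diseases: dict[str, DiseaseEpidemiology],
    exposure: ExposureModel,
) -> np.ndarray:
    """Initial joint-state occupancies ``(age, sex, category, state)``.

    Each age/sex/category cell holds ``count × category prevalence``
    persons; joint disease states are the product of the marginal disease
    prevalences (independence across diseases, as no co-morbidity
    correlations are available).
    """
    disease_list = list(diseases.values())
    n_dis = len(disease_list)
    n_alive = 1 << n_dis
    k = exposure.n_categories
    occ = np.zeros((N_AGES, N_SEXES, k, n_alive + 1))
    cell = population.count[:, :, None] * exposure.prevalence  # (age, sex, cat)
    for s in range(n_alive):
        prob = np.ones((N_AGES, N_SEXES))
        for d, dis in enumerate(disease_list):
            prob *= dis.prevalence if s & (1 << d) else 1.0 - dis.prevalence
        occ[..., s] = cell * prob[:, :, None]
    return occ


def build_transition_rates(
    bundle: InputBundle,
    food_group: str,
    reference_exposure: ExposureModel,
    adult_min_age: int = 19,
    rr_draws: dict[str, np.ndarray] | None = None,
) -> TransitionRates:
    """Assemble calibrated transition probabilities for one food group.

    Incidence of each disease is calibrated so the *reference* exposure
    distribution reproduces the baseline incidence; diseases without an
    RR table for the food group get RR 1 everywhere (their incidence is
    category-independent).  ``rr_draws`` optionally substitutes redrawn
    RR arrays (keyed by disease id, in the table's band shape) for the
    uncertainty analysis.
    """
    disease_ids = bundle.disease_ids
    k = reference_exposure.n_categories
    n_dis = len(disease_ids)
    incidence = np.zeros((n_dis, N_AGES, N_SEXES, k))
    excess = np.zeros((n_dis, N_AGES, N_SEXES))
    acute = np.zeros((n_dis, N_AGES, N_SEXES))
    for d, disease_id in enumerate(disease_ids):
        dis = bundle.diseases[disease_id]
        excess[d] = dis.excess_mortality
        acute[d] = dis.acute_fatal_fraction
        table = bundle.rr_tables.get((food_group, disease_id))
        if table is None:
            rr_age = np.ones((N_AGES, N_SEXES, k))
        else:
            draw = None if rr_draws is None else rr_draws.get(disease_id)
            rr_age = expand_rr_by_age(table, adult_min_age=adult_min_age, rr=draw)
        incidence[d] = calibrate_incidence(dis.incidence, reference_exposure.prevalence, rr_age)
    other = other_cause_mortality(
        bundle.population.total_mortality,
        [(bundle.diseases[i].prevalence, bundle.diseases[i].excess_mortality) for i in disease_ids],
    )
    return TransitionRates(
        disease_ids=disease_ids,
        incidence=incidence,
        excess_mortality=excess,
        acute_fatal_fraction=acute,
        other_mortality=other,
    )


@dataclass
class AggregatedResults:
    """Aggregated life-table output of one scenario run.

    Snapshot arrays (``alive``, ``disease_free``, ``prevalent``,
    ``cohort_size``, ``cohort_init``) are recorded at the start of each
    calendar year ``years[y]``; flow arrays (``incident``, ``deaths``,
    ``disease_free_exits``) count events during that year.  Shapes are
    ``(n_years, age, sex)``, with a leading disease axis for
    ``prevalent`` and ``incident``.  ``cohort_size`` includes the
    cohort's accumulated dead, so ``cohort_size == cohort_init`` is the
    conservation identity (no migration).
    """

    disease_ids: list[str]
    years: np.ndarray
    alive: np.ndarray
    disease_free: np.ndarray
    prevalent: np.ndarray
    incident: np.ndarray
    deaths: np.ndarray
    disease_free_exits: np.ndarray
    cohort_size: np.ndarray
    cohort_init: np.ndarray
    occupancy_history: list[np.ndarray] | None = None
    category_labels: list[str] | None = None

    def year_index(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year))
        if idx >= len(self.years) or self.years[idx] != year:
            raise ValueError(f"year {year} not simulated (have {self.years[0]}..{self.years[-1]})")
        return idx


@dataclass
class CohortLifeTable:
    """Joint-state occupancy trajectory of one birth cohort.

    ``occupancy[year, state]`` covers the ``2^D`` alive joint states
    (bitmask order; state 0 = disease-free) plus the absorbing dead state
    in the last column.
    """

    birth_year: int
    sex: str
    exposure_category: str
    years: np.ndarray
    state_names: list[str]
    occupancy: np.ndarray


def state_labels(disease_ids: list[str]) -> list[str]:
    """Human-readable names of the joint states in bitmask order, then dead."""
    labels = []
    for s in range(1 << len(disease_ids)):
        present = [disease_ids[d] for d in range(len(disease_ids)) if s & (1 << d)]
        labels.append("+".join(present) if present else "disease_free")
    labels.append("dead")
    return labels


def simulate(
    scenario: ExposureModel,
    bundle: InputBundle,
    config: SimulationConfig,
    rates: TransitionRates,
    record_occupancy: bool = False,
) -> AggregatedResults:
    """Run the multi-state life table for one scenario.

    ``scenario`` supplies the exposure-category distribution used to
    initialize cohorts alive in the start year and to assign newborn
    cohorts (who enter disease-free at age 0 each year, at the stated
    newborn counts, without migration).  ``rates`` must be calibrated on
    the *reference* exposure (see :func:`build_transition_rates`), so a
    counterfactual run differs only in how the population is distributed
    across categories.

    One annual cycle is run for every calendar year from ``start_year``
    through ``start_year + horizon_years`` inclusive, so that flow
    quantities (deaths, incident cases) are available *in* the final
    report year.
    """
    if config.horizon_years > AGE_MAX:
        raise ValueError("horizon exceeding the age grid is not supported")
    n_dis = rates.n_diseases
    n_alive = 1 << n_dis
    n_years = config.horizon_years + 1
    years = config.start_year + np.arange(n_years)

    occ = initialize_cohorts(bundle.population, bundle.diseases, scenario)
    init_size = occ.sum(axis=-1)  # (age, sex, cat): entering size of each cohort slice

    alive = np.zeros((n_years, N_AGES, N_SEXES))
    disease_free = np.zeros((n_years, N_AGES, N_SEXES))
    prevalent = np.zeros((n_dis, n_years, N_AGES, N_SEXES))
    incident = np.zeros((n_dis, n_years, N_AGES, N_SEXES))
    deaths = np.zeros((n_years, N_AGES, N_SEXES))
    dfree_exits = np.zeros((n_years, N_AGES, N_SEXES))
    cohort_size = np.zeros((n_years, N_AGES, N_SEXES))
    cohort_init = np.zeros((n_years, N_AGES, N_SEXES))
    history: list[np.ndarray] | None = [] if record_occupancy else None

    terminal = np.zeros((N_AGES, 1, 1), dtype=bool)
    terminal[AGE_MAX] = True
    inc = rates.incidence.transpose(0, 1, 2, 3)  # (D, age, sex, cat)
    exc = rates.excess_mortality[:, :, :, None]
    acu = rates.acute_fatal_fraction[:, :, :, None]
    oth = rates.other_mortality[:, :, None]

    for y in range(n_years):
        # start-of-year snapshot
        alive[y] = occ[..., :n_alive].sum(axis=(-1, -2))
        disease_free[y] = occ[..., 0].sum(axis=-1)
        for d in range(n_dis):
            has_d = [s for s in range(n_alive) if s & (1 << d)]
            prevalent[d, y] = occ[..., has_d].sum(axis=(-1, -2))
        cohort_size[y] = occ.sum(axis=(-1, -2))
        cohort_init[y] = init_size.sum(axis=-1)
        if history is not None:
            history.append(occ.copy())

        dfree_before = occ[..., 0].copy()
        occ_next, inc_y, dth_y = advance_cohort_year(occ, inc, exc, acu, oth, terminal)
        incident[:, y] = inc_y.sum(axis=-1)
        deaths[y] = dth_y.sum(axis=-1)
        # state 0 only loses mass within a cycle (no remission), so the
        # drop is exactly the count exiting the disease-free state
        dfree_exits[y] = (dfree_before - occ_next[..., 0]).sum(axis=-1)

        # aging: every cohort (its dead included) shifts one year of age;
        # the terminal cohort (now fully dead) leaves the grid
        occ = np.zeros_like(occ_next)
        occ[1:] = occ_next[:-1]
        new_init = np.zeros_like(init_size)
        new_init[1:] = init_size[:-1]
        newborn_cells = bundle.population.newborns[:, None] * scenario.prevalence[0]  # (sex, cat)
        occ[0, :, :, 0] = newborn_cells
        new_init[0] = newborn_cells
        init_size = new_init

        # constant-prevalence transition rule: risk-factor churn restores the
        # scenario's category distribution among the living at every age/sex
        # (independent of disease state); the dead stay where they died
        state_tot = occ[..., :n_alive].sum(axis=2)  # (age, sex, state)
        occ[..., :n_alive] = scenario.prevalence[:, :, :, None] * state_tot[:, :, None, :]

    return AggregatedResults(
        disease_ids=rates.disease_ids,
        years=years,
        alive=alive,
        disease_free=disease_free,
        prevalent=prevalent,
        incident=incident,
        deaths=deaths,
        disease_free_exits=dfree_exits,
        cohort_size=cohort_size,
        cohort_init=cohort_init,
        occupancy_history=history,
        category_labels=[c.label for c in scenario.categories],
    )


def cohort_life_table(
    results: AggregatedResults,
    birth_year: int,
    sex: str,
    category: str,
    start_year: int,
) -> CohortLifeTable:
    """Extract one birth cohort's joint-state trajectory from a recorded run."""
    if results.occupancy_history is None:
        raise ValueError("simulate(..., record_occupancy=True) is required")
    s = SEXES.index(sex)
    k = results.category_labels.index(category)
    years, rows = [], []
    for y, occ in enumerate(results.occupancy_history):
        age = start_year + y - birth_year
        if 0 <= age <= AGE_MAX:
            years.append(start_year + y)
            rows.append(occ[age, s, k, :])
    return CohortLifeTable(
        birth_year=birth_year,
        sex=sex,
        exposure_category=category,
        years=np.array(years),
        state_names=state_labels(results.disease_ids),
        occupancy=np.array(rows),
    )


def run_scenario_pair(
    bundle: InputBundle,
    food_group: str,
    config: SimulationConfig,
    rr_draws: dict[str, np.ndarray] | None = None,
    record_occupancy: bool = False,
) -> tuple[AggregatedResults, AggregatedResults]:
    """Simulate the reference and counterfactual scenarios for one food group."""
    pair = build_scenarios(bundle.exposures[food_group])
    rates = build_transition_rates(
        bundle,
        food_group,
        reference_exposure=pair.reference,
        adult_min_age=config.adult_min_age,
        rr_draws=rr_draws,
    )
    ref = simulate(pair.reference, bundle, config, rates, record_occupancy)
    cf = simulate(pair.counterfactual, bundle, config, rates, record_occupancy)
    return ref, cf
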