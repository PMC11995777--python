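"""Outcome measures and Monte Carlo uncertainty analysis.

Outcomes compare a reference run against a counterfactual run of the same
bundle: preventable disease cases per 100,000 (and percent), and gains in
period total and disease-free life expectancy.  Uncertainty intervals are
empirical 2.5th/97.5th percentiles over replicates in which every relative
risk is redrawn from its 95% confidence interval.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .data import AGE_MAX, N_AGES, SEXES, InputBundle, SimulationConfig
from .engine import AggregatedResults, run_scenario_pair
from .risk import draw_rr_table

__all__ = [
    "PreventableCases",
    "preventable_cases",
    "life_expectancy",
    "disease_free_life_expectancy",
    "gains",
    "UncertaintyResult",
    "OutcomeReport",
    "run_uncertainty",
    "ui_percentiles",
]

logger = logging.getLogger(__name__)


class PreventableCases(NamedTuple):
    cases_per_100k: float
    percent: float
    cumulative_incident_per_100k: float


def preventable_cases(
    ref: AggregatedResults,
    cf: AggregatedResults,
    disease_id: str,
    sex: str,
    year: int,
) -> PreventableCases:
    """Preventable cases of one disease, per 100,000 of one sex, in one year.

    ``cases_per_100k`` is the difference in prevalent cases (reference −
    counterfactual), summed over ages and rescaled per 100,000 persons of
    that sex alive in the *reference* scenario that year; ``percent`` is
    the relative difference (NaN when the reference has no cases).
    Negative values indicate a disease increase — typically the
    larger-population effect on diseases unrelated to the exposure.
    ``cumulative_incident_per_100k`` is a secondary reading: the
    difference in incident cases accumulated from the start year through
    ``year``, on the same denominator.
    """
    d = ref.disease_ids.index(disease_id)
    s = SEXES.index(sex)
    y = ref.year_index(year)
    denom = ref.alive[y, :, s].sum()
    if denom == 0:  # nobody of this sex alive: all rates undefined
        return PreventableCases(float("nan"), float("nan"), float("nan"))
    prev_ref = ref.prevalent[d, y, :, s].sum()
    prev_cf = cf.prevalent[d, y, :, s].sum()
    diff = prev_ref - prev_cf
    cum_diff = ref.incident[d, : y + 1, :, s].sum() - cf.incident[d, : y + 1, :, s].sum()
    percent = 100.0 * diff / prev_ref if prev_ref > 0 else float("nan")
    return PreventableCases(
        cases_per_100k=1e5 * diff / denom,
        percent=percent,
        cumulative_incident_per_100k=1e5 * cum_diff / denom,
    )


def _period_le(q: np.ndarray, at_age: int) -> float:
    """Period life expectancy from annual death probabilities ``q[age]``.

    Standard single-year life table with a half-year person-years credit
    in the year of death; the terminal age (95) has ``q = 1`` and
    contributes half a year.
    """
    if not 0 <= at_age <= AGE_MAX:
        raise ValueError(f"age {at_age} outside the 0..{AGE_MAX} grid")
    q = np.clip(np.asarray(q, dtype=float), 0.0, 1.0)
    lx = 1.0
    total = 0.0
    for age in range(at_age, AGE_MAX + 1):
        qa = 1.0 if age == AGE_MAX else q[age]
        dx = lx * qa
        total += lx - 0.5 * dx  # survivors a full year, decedents half
        lx -= dx
    return total


def _mortality_profile(results: AggregatedResults, sex: str, year: int) -> np.ndarray:
    """Cross-sectional annual death probability by age in one calendar year."""
    s = SEXES.index(sex)
    y = results.year_index(year)
    alive = results.alive[y, :, s]
    deaths = results.deaths[y, :, s]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(alive > 0, deaths / np.maximum(alive, 1e-300), 1.0)
    return np.clip(q, 0.0, 1.0)


def life_expectancy(results: AggregatedResults, sex: str, at_age: int, year: int) -> float:
    """Period life expectancy at ``at_age`` from mortality observed in ``year``."""
    return _period_le(_mortality_profile(results, sex, year), at_age)


def disease_free_life_expectancy(
    results: AggregatedResults, sex: str, at_age: int, year: int
) -> float:
    """Expected years free of every modeled NCD, from cross-sectional exit rates.

    The same period life-table machinery is applied to *exit* from the
    all-disease-free state, where exit is the first disease onset or
    death, whichever comes first (an acutely fatal onset counts once).
    """
    s = SEXES.index(sex)
    y = results.year_index(year)
    dfree = results.disease_free[y, :, s]
    exits = results.disease_free_exits[y, :, s]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(dfree > 0, exits / np.maximum(dfree, 1e-300), 1.0)
    return _period_le(np.clip(q, 0.0, 1.0), at_age)


_METRICS: dict[str, Callable[[AggregatedResults, str, int, int], float]] = {
    "le": life_expectancy,
    "dfle": disease_free_life_expectancy,
}


def gains(
    ref: AggregatedResults,
    cf: AggregatedResults,
    metric: str,
    sex: str,
    at_age: int,
    year: int,
) -> float:
    """Counterfactual-minus-reference gain in a life-expectancy metric (years).

    ``metric`` is ``"le"`` (total) or ``"dfle"`` (disease-free).
    """
    fn = _METRICS[metric]
    return fn(cf, sex, at_age, year) - fn(ref, sex, at_age, year)


def ui_percentiles(replicates) -> tuple[float, float]:
    """95% uncertainty interval: 2.5th/97.5th percentiles, linear interpolation."""
    arr = np.asarray(replicates, dtype=float)
    lo, hi = np.percentile(arr, [2.5, 97.5], method="linear")
    return float(lo), float(hi)


@dataclass
class UncertaintyResult:
    """A point estimate with its Monte Carlo replicates and 95% UI."""

    point: float
    replicates: np.ndarray
    ui_low: float = field(init=False)
    ui_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, dtype=float)
        self.ui_low, self.ui_high = ui_percentiles(self.replicates)


@dataclass
class OutcomeReport:
    """All outcome measures for one food group, with uncertainty intervals.

    ``cases[(disease, sex, year)]`` and ``percent[(disease, sex, year)]``
    hold preventable prevalent cases per 100,000 and the percent
    reduction; ``le_gain[(sex, age)]`` and ``dfle_gain[(sex, age)]`` the
    life-expectancy gains (years) in the final simulated year.
    """

    food_group: str
    cases: dict[tuple[str, str, int], UncertaintyResult]
    percent: dict[tuple[str, str, int], UncertaintyResult]
    le_gain: dict[tuple[str, int], UncertaintyResult]
    dfle_gain: dict[tuple[str, int], UncertaintyResult]

    def cases_frame(self) -> pd.DataFrame:
        rows = []
        for (disease, sex, year), res in self.cases.items():
            pct = self.percent[(disease, sex, year)]
            rows.append(
                {
                    "food_group": self.food_group,
                    "disease": disease,
                    "sex": sex,
                    "year": year,
                    "cases_per_100k": res.point,
                    "cases_ui_low": res.ui_low,
                    "cases_ui_high": res.ui_high,
                    "percent": pct.point,
                    "percent_ui_low": pct.ui_low,
                    "percent_ui_high": pct.ui_high,
                }
            )
        return pd.DataFrame(rows)

    def gains_frame(self) -> pd.DataFrame:
        rows = []
        for (sex, age), res in self.le_gain.items():
            dfle = self.dfle_gain[(sex, age)]
            rows.append(
                {
                    "food_group": self.food_group,
                    "sex": sex,
                    "age": age,
                    "le_gain": res.point,
                    "le_ui_low": res.ui_low,
                    "le_ui_high": res.ui_high,
                    "dfle_gain": dfle.point,
                    "dfle_ui_low": dfle.ui_low,
                    "dfle_ui_high": dfle.ui_high,
                }
            )
        return pd.DataFrame(rows)


def _replicate_rng(master_seed: int, replicate: int, food_group: str, disease_id: str):
    """Deterministic substream per (replicate, food group, disease).

    Streams are keyed by a CRC of the food-group/disease name, so adding
    or removing a disease never perturbs the draws of the others.
    """
    key = zlib.crc32(f"{food_group}:{disease_id}".encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed, replicate, key]))


def _all_outcomes(
    ref: AggregatedResults,
    cf: AggregatedResults,
    bundle: InputBundle,
    config: SimulationConfig,
) -> dict:
    final_year = config.start_year + config.horizon_years
    out: dict = {"cases": {}, "percent": {}, "le": {}, "dfle": {}}
    for disease_id in bundle.disease_ids:
        for sex in SEXES:
            for year in config.report_years:
                pc = preventable_cases(ref, cf, disease_id, sex, year)
                out["cases"][(disease_id, sex, year)] = pc.cases_per_100k
                out["percent"][(disease_id, sex, year)] = pc.percent
    for sex in SEXES:
        for age in config.le_ages:
            out["le"][(sex, age)] = gains(ref, cf, "le", sex, age, final_year)
            out["dfle"][(sex, age)] = gains(ref, cf, "dfle", sex, age, final_year)
    return out


def run_uncertainty(
    bundle: InputBundle,
    food_group: str,
    config: SimulationConfig,
) -> OutcomeReport:
    """Full assessment of one food group with Monte Carlo uncertainty.

    The point estimate uses the central RRs.  Each of ``config.mc_reps``
    replicates redraws every RR table from its 95% CI (one substream per
    replicate × disease, derived from ``config.rng_seed``), reruns both
    scenarios and recomputes every outcome; 95% UIs are the empirical
    2.5th/97.5th percentiles over replicates.  Fully reproducible given
    the seed.  A failing replicate aborts with its index and seed.
    """
    ref, cf = run_scenario_pair(bundle, food_group, config)
    point = _all_outcomes(ref, cf, bundle, config)

    reps: list[dict] = []
    tables = {d: t for (g, d), t in bundle.rr_tables.items() if g == food_group}
    for r in range(config.mc_reps):
        try:
            draws = {
                disease_id: draw_rr_table(table, _replicate_rng(config.rng_seed, r, food_group, disease_id))
                for disease_id, table in sorted(tables.items())
            }
            ref_r, cf_r = run_scenario_pair(bundle, food_group, config, rr_draws=draws)
            reps.append(_all_outcomes(ref_r, cf_r, bundle, config))
            logger.info("replicate %d/%d done (seed %d)", r + 1, config.mc_reps, config.rng_seed)
        except Exception as exc:  # noqa: BLE001 - replicate context is essential
            raise RuntimeError(
                f"uncertainty replicate {r} failed (master seed {config.rng_seed}): {exc}"
            ) from exc

    def collect(kind: str) -> dict:
        return {
            key: UncertaintyResult(point=point[kind][key], replicates=[rep[kind][key] for rep in reps])
            for key in point[kind]
        }

    return OutcomeReport(
        food_group=food_group,
        cases=collect("cases"),
        percent=collect("percent"),
        le_gain=collect("le"),
        dfle_gain=collect("dfle"),
    )
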