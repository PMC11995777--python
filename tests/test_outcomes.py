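"""Outcome measures: preventable cases, (disease-free) life expectancy, UIs."""

import numpy as np
import pytest

from diethia.data import N_AGES, N_SEXES, SimulationConfig
from diethia.engine import AggregatedResults, run_scenario_pair
from diethia.outcomes import (
    UncertaintyResult,
    _period_le,
    disease_free_life_expectancy,
    gains,
    life_expectancy,
    preventable_cases,
    run_uncertainty,
    ui_percentiles,
)
from diethia.synthetic import DiseaseCurve, SyntheticSpec, make_bundle


def _fake_results(alive_total, prevalent_total, disease_id="d"):
    """Minimal one-age results object for outcome arithmetic tests."""
    n_years = 1
    alive = np.zeros((n_years, N_AGES, N_SEXES))
    prevalent = np.zeros((1, n_years, N_AGES, N_SEXES))
    alive[0, 50, :] = alive_total
    prevalent[0, 0, 50, :] = prevalent_total
    zero = np.zeros((n_years, N_AGES, N_SEXES))
    return AggregatedResults(
        disease_ids=[disease_id],
        years=np.array([2050]),
        alive=alive,
        disease_free=zero.copy(),
        prevalent=prevalent,
        incident=np.zeros((1, n_years, N_AGES, N_SEXES)),
        deaths=zero.copy(),
        disease_free_exits=zero.copy(),
        cohort_size=zero.copy(),
        cohort_init=zero.copy(),
    )


class TestPreventableCases:
    def test_published_scale_example(self):
        """Per-100k arithmetic on the scale of reported coronary-disease results."""
        ref = _fake_results(100_000, 4643.0)
        cf = _fake_results(100_000, 3784.0)
        pc = preventable_cases(ref, cf, "d", "female", 2050)
        assert pc.cases_per_100k == pytest.approx(859.0)
        assert pc.percent == pytest.approx(18.5, abs=0.05)

    def test_identical_scenarios_zero(self):
        ref = _fake_results(100_000, 4643.0)
        pc = preventable_cases(ref, ref, "d", "female", 2050)
        assert pc.cases_per_100k == 0.0 and pc.percent == 0.0

    def test_sign_convention_for_disease_increase(self):
        ref = _fake_results(100_000, 100.0)
        cf = _fake_results(100_000, 110.0)
        pc = preventable_cases(ref, cf, "d", "male", 2050)
        assert pc.cases_per_100k < 0 and pc.percent < 0

    def test_zero_reference_prevalence_reports_missing_percent(self):
        ref = _fake_results(100_000, 0.0)
        cf = _fake_results(100_000, 0.0)
        assert np.isnan(preventable_cases(ref, cf, "d", "female", 2050).percent)

    def test_percent_invariant_to_population_rescaling(self, default_bundle, default_config):
        bundle, _ = default_bundle
        ref, cf = run_scenario_pair(bundle, "processed_meat", default_config)
        scaled = SyntheticSpec(rng_seed=0, total_population=2_000_000.0)
        bundle2, _ = make_bundle(scaled)
        ref2, cf2 = run_scenario_pair(bundle2, "processed_meat", default_config)
        a = preventable_cases(ref, cf, "t2d", "female", 2050)
        b = preventable_cases(ref2, cf2, "t2d", "female", 2050)
        assert a.percent == pytest.approx(b.percent, rel=1e-9)
        assert a.cases_per_100k == pytest.approx(b.cases_per_100k, rel=1e-9)


class TestPeriodLifeExpectancy:
    def test_certain_death_gives_half_year(self):
        assert _period_le(np.ones(N_AGES), 0) == pytest.approx(0.5)
        assert _period_le(np.ones(N_AGES), 95) == pytest.approx(0.5)

    def test_no_mortality_survives_to_terminal_age(self):
        assert _period_le(np.zeros(N_AGES), 0) == pytest.approx(95.5)

    def test_two_age_hand_table(self):
        """q = (0.5, 1) from age 94: L94 = 0.75, L95 = 0.25, LE = 1.0."""
        q = np.zeros(N_AGES)
        q[94] = 0.5
        q[95] = 1.0
        assert _period_le(q, 94) == pytest.approx(1.0)


class TestDisuseFreeLifeExpectancy:
    def test_geometric_closed_form_constant_incidence(self):
        """Zero mortality, constant incidence i: DFLE follows the geometric series."""
        i = 0.05
        spec = SyntheticSpec(
            rng_seed=0,
            gompertz_alpha=0.0,  # no mortality below the terminal age
            # logistic midpoint far below the age grid => incidence = i at all ages
            diseases={"d": DiseaseCurve(i, -1000, 1, 0, 70, 10, 0.0, 0.0)},
            rr_specs={"d": [(1.0, 1.0, 1.0), (1.0, 1.0, 1.0)]},
        )
        bundle, _ = make_bundle(spec)
        config = SimulationConfig(rng_seed=0, horizon_years=5, report_years=[2025])
        ref, _ = run_scenario_pair(bundle, "processed_meat", config)
        expected = sum((1 - i) ** a * (1 - i / 2) for a in range(95)) + 0.5 * (1 - i) ** 95
        got = disease_free_life_expectancy(ref, "female", 0, 2025)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_zero_incidence_dfle_equals_le(self, disease_free_bundle, default_config):
        ref, _ = run_scenario_pair(disease_free_bundle, "processed_meat", default_config)
        for age in (0, 50, 70):
            le = life_expectancy(ref, "male", age, 2050)
            dfle = disease_free_life_expectancy(ref, "male", age, 2050)
            assert dfle == pytest.approx(le, abs=1e-12)

    def test_dfle_never_exceeds_le(self, default_bundle, default_config):
        bundle, _ = default_bundle
        for res in run_scenario_pair(bundle, "processed_meat", default_config):
            for sex in ("female", "male"):
                for age in (0, 50, 70):
                    for year in (2030, 2040, 2050):
                        le = life_expectancy(res, sex, age, year)
                        dfle = disease_free_life_expectancy(res, sex, age, year)
                        assert dfle <= le + 1e-12


class TestGains:
    def test_identical_scenarios_gain_zero(self, default_bundle, default_config):
        bundle, _ = default_bundle
        ref, _ = run_scenario_pair(bundle, "processed_meat", default_config)
        assert gains(ref, ref, "le", "female", 50, 2050) == 0.0

    def test_antisymmetric_under_scenario_swap(self, default_bundle, default_config):
        bundle, _ = default_bundle
        ref, cf = run_scenario_pair(bundle, "processed_meat", default_config)
        for metric in ("le", "dfle"):
            g = gains(ref, cf, metric, "male", 50, 2050)
            assert gains(cf, ref, metric, "male", 50, 2050) == pytest.approx(-g)
        pc = preventable_cases(ref, cf, "t2d", "male", 2050)
        swapped = preventable_cases(cf, ref, "t2d", "male", 2050)
        # antisymmetry of the case difference (denominators differ by scenario)
        ref_alive = ref.alive[ref.year_index(2050), :, 1].sum()
        cf_alive = cf.alive[cf.year_index(2050), :, 1].sum()
        assert swapped.cases_per_100k * cf_alive == pytest.approx(-pc.cases_per_100k * ref_alive)

    def test_harmful_removal_gains_nonnegative(self, default_bundle, default_config):
        bundle, _ = default_bundle
        ref, cf = run_scenario_pair(bundle, "processed_meat", default_config)
        for metric in ("le", "dfle"):
            for sex in ("female", "male"):
                for age in (0, 50, 70):
                    assert gains(ref, cf, metric, sex, age, 2050) >= 0.0


class TestUncertainty:
    def test_percentile_rule_hand_computation(self):
        lo, hi = ui_percentiles(np.arange(1, 101))
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_ui_invariant_under_permutation(self):
        reps = np.random.default_rng(0).normal(size=100)
        assert ui_percentiles(reps) == ui_percentiles(np.sort(reps))

    def test_uncertainty_result_orders_bounds(self):
        res = UncertaintyResult(point=0.0, replicates=[3.0, -1.0, 2.0])
        assert res.ui_low <= res.ui_high

    def test_degenerate_cis_collapse_ui(self, worked_example):
        bundle, config, _ = worked_example
        table = bundle.rr_tables[("toy_group", "disease")]
        saved = (table.ci_low.copy(), table.ci_high.copy())
        table.ci_low[:], table.ci_high[:] = table.rr, table.rr
        try:
            report = run_uncertainty(bundle, "toy_group", config.model_copy(update={"mc_reps": 5}))
        finally:
            table.ci_low[:], table.ci_high[:] = saved
        for res in list(report.cases.values()) + list(report.le_gain.values()):
            if np.isnan(res.point):  # e.g. no males in this one-cohort fixture
                assert np.all(np.isnan(res.replicates))
                continue
            assert np.all(res.replicates == res.point)
            assert res.ui_low == res.ui_high == res.point

    def test_same_seed_reproduces_uis_bitwise(self, worked_example):
        bundle, config, _ = worked_example
        cfg = config.model_copy(update={"mc_reps": 5, "rng_seed": 77})
        r1 = run_uncertainty(bundle, "toy_group", cfg)
        r2 = run_uncertainty(bundle, "toy_group", cfg)
        for key in r1.cases:
            assert np.array_equal(
                r1.cases[key].replicates, r2.cases[key].replicates, equal_nan=True
            )
            assert np.array_equal(
                [r1.cases[key].ui_low, r1.cases[key].ui_high],
                [r2.cases[key].ui_low, r2.cases[key].ui_high],
                equal_nan=True,
            )

    def test_report_frames_well_formed(self, worked_example):
        bundle, config, _ = worked_example
        report = run_uncertainty(bundle, "toy_group", config.model_copy(update={"mc_reps": 3}))
        cases = report.cases_frame()
        gains_df = report.gains_frame()
        assert {"cases_per_100k", "percent", "cases_ui_low"} <= set(cases.columns)
        assert np.all(gains_df["le_ui_low"] <= gains_df["le_ui_high"])
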