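"""Multi-state life-table engine: transitions, conservation, cohort dynamics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from diethia.data import AGE_MAX, N_AGES, N_SEXES, SimulationConfig
from diethia.engine import (
    advance_cohort_year,
    build_transition_rates,
    cohort_life_table,
    initialize_cohorts,
    mortality_of_state,
    other_cause_mortality,
    run_scenario_pair,
    simulate,
    state_labels,
)
from diethia.exposure import build_scenarios


class TestOtherCauseMortality:
    def test_prevalence_weighted_subtraction(self):
        assert other_cause_mortality(0.01, [(0.1, 0.02)]) == pytest.approx(0.008)

    def test_no_diseases_is_total(self):
        assert other_cause_mortality(0.01, []) == 0.01

    def test_floor_at_zero_logged(self, caplog):
        with caplog.at_level("WARNING", logger="diethia.engine"):
            out = other_cause_mortality(0.001, [(0.5, 0.01)])
        assert out == 0.0
        assert "floored" in caplog.text


def _toy_rates(n_dis=2, other=0.0):
    from diethia.engine import TransitionRates

    shape = (n_dis, N_AGES, N_SEXES)
    return TransitionRates(
        disease_ids=[f"d{i}" for i in range(1, n_dis + 1)],
        incidence=np.zeros(shape + (1,)),
        excess_mortality=np.zeros(shape),
        acute_fatal_fraction=np.zeros(shape),
        other_mortality=np.full((N_AGES, N_SEXES), other),
    )


class TestMortalityOfState:
    def test_empty_state_is_other_cause(self):
        rates = _toy_rates(other=0.008)
        assert mortality_of_state([], rates, 50, 0) == pytest.approx(0.008)

    def test_excess_adds(self):
        rates = _toy_rates(other=0.008)
        rates.excess_mortality[0, 50, 0] = 0.02
        assert mortality_of_state(["d1"], rates, 50, 0) == pytest.approx(0.028)

    def test_capped_at_one(self):
        rates = _toy_rates(other=0.2)
        rates.excess_mortality[0, 50, 0] = 0.02
        rates.excess_mortality[1, 50, 0] = 0.9
        assert mortality_of_state(["d1", "d2"], rates, 50, 0) == 1.0

    def test_unknown_disease_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            mortality_of_state(["nope"], _toy_rates(), 50, 0)


class TestAdvanceCohortYear:
    def _advance(self, occ, i=0.0, mu=0.0, f=0.0, other=0.0, terminal=False):
        d = np.array([[i]]), np.array([[mu]]), np.array([[f]]), np.array(other)
        return advance_cohort_year(np.asarray(occ, float), *d, terminal)

    def test_all_rates_zero_is_identity(self):
        occ, inc, deaths = self._advance([0.7, 0.2, 0.1])
        np.testing.assert_array_equal(occ, [0.7, 0.2, 0.1])
        assert inc.sum() == 0 and deaths.sum() == 0

    def test_single_incidence_step(self):
        occ, inc, _ = self._advance([1.0, 0.0, 0.0], i=0.1)
        np.testing.assert_allclose(occ, [0.9, 0.1, 0.0])
        assert inc.sum() == pytest.approx(0.1)

    def test_acute_fraction_dies_immediately(self):
        occ, inc, deaths = self._advance([1.0, 0.0, 0.0], i=0.1, f=0.2)
        np.testing.assert_allclose(occ, [0.9, 0.08, 0.02])
        assert inc.sum() == pytest.approx(0.1)  # incident count includes acute deaths
        assert deaths.sum() == pytest.approx(0.02)

    def test_negative_occupancy_rejected(self):
        with pytest.raises(ValueError):
            self._advance([-0.1, 0.0, 0.0])

    def test_terminal_kills_everyone(self):
        occ, _, deaths = self._advance([0.5, 0.3, 0.2], terminal=True)
        np.testing.assert_allclose(occ, [0.0, 0.0, 1.0])
        assert deaths.sum() == pytest.approx(0.8)

    @given(
        free=st.floats(0, 100),
        dis=st.floats(0, 100),
        i=st.floats(0, 1),
        mu=st.floats(0, 1),
        f=st.floats(0, 1),
        other=st.floats(0, 1),
    )
    def test_mass_conserved_dead_absorbing(self, free, dis, i, mu, f, other):
        start = np.array([free, dis, 1.0])
        occ, _, deaths = self._advance(start, i=i, mu=mu, f=f, other=other)
        assert occ.sum() == pytest.approx(start.sum(), rel=1e-12)
        assert np.all(occ >= -1e-12)
        assert occ[-1] >= 1.0 - 1e-12  # dead never shrinks
        assert occ[0] <= free + 1e-12  # no remission back to disease-free


class TestInitializeCohorts:
    def test_zero_prevalence_all_disease_free(self, disease_free_bundle):
        b = disease_free_bundle
        exp = b.exposures["processed_meat"]
        occ = initialize_cohorts(b.population, b.diseases, exp)
        assert occ[..., 1:].sum() == 0.0
        assert occ.sum() == pytest.approx(b.population.count.sum())

    def test_single_disease_split(self, worked_example):
        bundle, _, _ = worked_example
        occ = initialize_cohorts(
            bundle.population, bundle.diseases, bundle.exposures["toy_group"]
        )
        cell = occ[93, 0, :, :]  # (category, state)
        np.testing.assert_allclose(cell[:, 0], [180.0, 720.0])
        np.testing.assert_allclose(cell[:, 1], [20.0, 80.0])

    def test_two_disease_independence_product(self, two_disease_bundle):
        b = two_disease_bundle
        occ = initialize_cohorts(
            b.population, b.diseases, b.exposures["processed_meat"]
        )
        age, sex = 80, 0
        p1 = b.diseases["chd"].prevalence[age, sex]
        p2 = b.diseases["t2d"].prevalence[age, sex]
        cell_pop = occ[age, sex].sum()
        both = occ[age, sex, :, 3].sum()  # bitmask 0b11: both diseases
        assert both / cell_pop == pytest.approx(p1 * p2, rel=1e-12)


class TestSimulate:
    def test_worked_example_matches_hand_table(self, worked_example):
        bundle, config, expected = worked_example
        ref, _ = run_scenario_pair(bundle, "toy_group", config, record_occupancy=True)
        for year, cats in expected["reference"].items():
            occ = ref.occupancy_history[ref.year_index(year)]
            age = 93 + (year - 2020)
            for k, label in enumerate(["adherent", "non_adherent_1"]):
                np.testing.assert_allclose(occ[age, 0, k, :], cats[label], atol=1e-12)

    def test_year_one_incidence_drop_equals_pif(self, worked_example):
        bundle, config, expected = worked_example
        ref, cf = run_scenario_pair(bundle, "toy_group", config)
        assert ref.incident[0, 0].sum() == pytest.approx(expected["reference_incident_2020"])
        pif = 1 - cf.incident[0, 0].sum() / ref.incident[0, 0].sum()
        assert pif == pytest.approx(expected["pif"], abs=1e-12)

    def test_conservation_every_cohort_year(self, default_bundle, default_config):
        bundle, _ = default_bundle
        ref, cf = run_scenario_pair(bundle, "processed_meat", default_config)
        for res in (ref, cf):
            rel = np.abs(res.cohort_size - res.cohort_init) / np.maximum(res.cohort_init, 1e-300)
            assert np.nanmax(rel[res.cohort_init > 0]) < 1e-9

    def test_dead_nondecreasing_no_remission(self, default_bundle, default_config):
        bundle, _ = default_bundle
        config = default_config.model_copy(update={"horizon_years": 10, "report_years": [2025]})
        ref, _ = run_scenario_pair(bundle, "processed_meat", config, record_occupancy=True)
        n_alive = 1 << len(ref.disease_ids)
        for y in range(1, len(ref.occupancy_history)):
            prev_occ = ref.occupancy_history[y - 1]
            occ = ref.occupancy_history[y]
            # cohorts shift one age per year: compare at ages 1..95 vs 0..94
            assert np.all(occ[1:, :, :, n_alive] >= prev_occ[:-1, :, :, n_alive] - 1e-9)

    def test_harmful_removal_monotone(self, default_bundle, default_config):
        """All RR >= 1: full adherence lowers associated disease burden and deaths."""
        bundle, _ = default_bundle
        ref, cf = run_scenario_pair(bundle, "processed_meat", default_config)
        for d, disease_id in enumerate(ref.disease_ids):
            if disease_id == "lung_cancer":
                continue
            assert np.all(cf.prevalent[d].sum(axis=(1, 2)) <= ref.prevalent[d].sum(axis=(1, 2)) + 1e-9)
        assert np.all(cf.alive.sum(axis=(1, 2)) >= ref.alive.sum(axis=(1, 2)) - 1e-9)

    def test_bystander_disease_grows_with_larger_population(self, default_bundle, default_config):
        """An RR-1 disease accrues more cases in the longer-lived counterfactual."""
        bundle, _ = default_bundle
        ref, cf = run_scenario_pair(bundle, "processed_meat", default_config)
        d = ref.disease_ids.index("lung_cancer")
        y = ref.year_index(2050)
        assert cf.prevalent[d, y].sum() > ref.prevalent[d, y].sum()

    def test_horizon_beyond_age_grid_rejected(self, default_bundle):
        bundle, _ = default_bundle
        config = SimulationConfig(horizon_years=120, report_years=[2050])
        pair = build_scenarios(bundle.exposures["processed_meat"])
        rates = build_transition_rates(bundle, "processed_meat", pair.reference)
        with pytest.raises(ValueError, match="age grid"):
            simulate(pair.reference, bundle, config, rates)


class TestCohortLifeTable:
    def test_extracted_cohort_conserves_mass(self, worked_example):
        """Across categories (risk-factor churn moves the living between them),
        a birth cohort's total occupancy is constant and its dead pool grows."""
        bundle, config, _ = worked_example
        ref, _ = run_scenario_pair(bundle, "toy_group", config, record_occupancy=True)
        tables = [
            cohort_life_table(ref, birth_year=2020 - 93, sex="female",
                              category=c, start_year=2020)
            for c in ("adherent", "non_adherent_1")
        ]
        combined = sum(t.occupancy for t in tables)
        totals = combined.sum(axis=1)
        np.testing.assert_allclose(totals, totals[0], rtol=1e-12)
        for t in tables:
            assert np.all(np.diff(t.occupancy[:, -1]) >= -1e-12)  # dead stay put

    def test_state_labels(self):
        labels = state_labels(["a", "b"])
        assert labels == ["disease_free", "a", "b", "a+b", "dead"]
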