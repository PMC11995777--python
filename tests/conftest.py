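import hypothesis
import pytest

from diethia.data import SimulationConfig
from diethia.synthetic import DiseaseCurve, SyntheticSpec, make_bundle, make_worked_example

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic bundle: processed-meat-like exposure, three diseases."""
    bundle, ground_truth = make_bundle(SyntheticSpec(rng_seed=0))
    return bundle, ground_truth


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(rng_seed=0)


@pytest.fixture(scope="session")
def worked_example():
    """Tiny fixed bundle (one cohort, one disease, two categories) + hand table."""
    return make_worked_example()


@pytest.fixture(scope="session")
def null_bundle():
    """Synthetic bundle whose exposure has RR 1 on every disease."""
    spec = SyntheticSpec(
        rng_seed=0,
        rr_specs={
            "chd": [(1.0, 1.0, 1.0), (1.0, 1.0, 1.0)],
            "t2d": [(1.0, 1.0, 1.0), (1.0, 1.0, 1.0)],
            "lung_cancer": [(1.0, 1.0, 1.0), (1.0, 1.0, 1.0)],
        },
    )
    bundle, _ = make_bundle(spec)
    return bundle


@pytest.fixture(scope="session")
def disease_free_bundle():
    """One all-zero disease: the engine degenerates to a classic life table."""
    spec = SyntheticSpec(
        rng_seed=0,
        diseases={"null_disease": DiseaseCurve(0, 70, 10, 0, 70, 10, 0.0, 0.0)},
        rr_specs={"null_disease": [(1.0, 1.0, 1.0), (1.0, 1.0, 1.0)]},
    )
    bundle, _ = make_bundle(spec)
    return bundle


@pytest.fixture(scope="session")
def two_disease_bundle():
    """Reduced bundle (two diseases) for the heavier uncertainty runs."""
    spec = SyntheticSpec(
        rng_seed=0,
        diseases={
            "chd": DiseaseCurve(0.03, 80, 8, 0.18, 82, 8, 0.003, 0.045, acute_fatal=0.2),
            "t2d": DiseaseCurve(0.02, 75, 10, 0.25, 75, 8, 0.002, 0.03),
        },
        rr_specs={
            "chd": [(1.18, 1.04, 1.33), (1.12, 1.01, 1.24)],
            "t2d": [(1.30, 1.18, 1.44), (1.18, 1.10, 1.27)],
        },
    )
    bundle, _ = make_bundle(spec)
    return bundle
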