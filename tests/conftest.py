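import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from navitro import Curve4PL, SyntheticSpec, demo_registry


@pytest.fixture(scope="session")
def registry():
    return demo_registry()


@pytest.fixture
def decline_truth():
    """A clean cytotoxicity curve: full decline, EC50 at 1 µM."""
    return Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0, hill=1.0,
                    visual_check_flag="passed")


@pytest.fixture
def basic_spec(decline_truth):
    return SyntheticSpec(
        seed=7,
        true_curves={("tolbutamide", "viability"): decline_truth},
        n_plates=2, noise_cv=0.05,
    )
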