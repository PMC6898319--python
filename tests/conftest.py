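import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("suite")

from periq import (  # noqa: E402
    CutoffAnchor,
    CutoffSurface,
    ImageQualityStudy,
    PipelineConfig,
    make_reference,
)
from periq.synthetic import generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def reference():
    return make_reference("builtin", seed=0)


@pytest.fixture(scope="session")
def surface():
    return CutoffSurface()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def high_cutoff_surface():
    """Cutoff surface so permissive the neural filter is nearly transparent."""
    anchors = [
        CutoffAnchor(x, y, 500.0) for x in (-50.0, 0.0, 50.0) for y in (-50.0, 0.0, 50.0)
    ]
    return CutoffSurface(anchors)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort({"PNS": 1, "RPM": 1}, seed=11)


@pytest.fixture(scope="session")
def small_results(small_cohort):
    study = ImageQualityStudy(small_cohort, PipelineConfig(seed=11))
    return study.fit()
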