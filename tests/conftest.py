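import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# detector modules log expected truncation warnings on running/jumping traces
logging.getLogger("firewatch").setLevel(logging.ERROR)


@pytest.fixture()
def default_pipeline_config():
    from firewatch import PipelineConfig

    return PipelineConfig()


@pytest.fixture(scope="session")
def fall_forward_run():
    """One canonical forward-fall trace with ground truth (seed fixed)."""
    from firewatch import ScenarioSpec, generate

    frame, truth = generate(ScenarioSpec(label="fall_forward", seed=11))
    return frame, truth
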