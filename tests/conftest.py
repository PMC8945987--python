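import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_segmentation_warnings():
    # Seed-outside-foreground warnings are expected on some random fields
    # and asserted explicitly where they matter.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="seed .* lies outside")
        yield
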