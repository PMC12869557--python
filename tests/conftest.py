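import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_run():
    """One shared transient phantom solve over a 24 h horizon."""
    import organoflux as of

    cfg = of.phantom_config(output_times=np.arange(0.0, 86401.0, 1200.0))
    return of.solve_phantom(cfg)
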