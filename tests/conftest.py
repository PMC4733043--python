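import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "orgcount",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("orgcount")


@pytest.fixture
def fig1_rates():
    """The four-process parameter set used for the convergence examples:
    de novo 2.0, fission 0.9, decay 1.0, fusion 0.02."""
    from orgcount import ModelRates

    return ModelRates(k_de_novo=2.0, k_fission=0.9, gamma=1.0, k_fusion=0.02)


@pytest.fixture
def divergent_rates():
    """Fission exceeding decay with no fusion: no limiting distribution."""
    from orgcount import ModelRates

    return ModelRates(k_de_novo=2.0, k_fission=1.1, gamma=1.0, k_fusion=0.0)
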