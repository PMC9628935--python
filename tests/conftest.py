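import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from markerscan import synthetic_data as sd  # noqa: E402


@pytest.fixture(scope="session")
def default_panel():
    """Full-scale default panel (21 strains, 17 coding loci + 16S-like),
    seed 1."""
    panel, truth = sd.generate_panel(sd.default_config(seed=1))
    return panel, truth


@pytest.fixture(scope="session")
def small_panel():
    """Scaled-down panel for fast tests (same species design, ~30% locus
    lengths; planted windows that no longer fit are dropped)."""
    panel, truth = sd.generate_panel(sd.default_config(seed=7, scale=0.3))
    return panel, truth
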