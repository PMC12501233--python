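import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitodyn import load_presets

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def presets():
    """All ten packaged scenarios, with the documented OVCAR3-SS fill rule."""
    return load_presets(fill_missing="plus_serum")


@pytest.fixture(scope="session")
def panel(presets):
    """Default-settings panel run over all ten presets (shared; read-only)."""
    from mitodyn import run_panel

    return run_panel(presets)


def rel_error(a, b):
    """Scaled max-norm discrepancy between two trajectories on a common grid:
    max_t ||a-b||_inf normalized by the reference's overall magnitude."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.max(np.abs(a - b)) / np.max(np.abs(b)))
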