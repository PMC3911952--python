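import pytest

from ureteroflow.cfd2d import build_domain, mesh_domain, solve_simple
from ureteroflow.geometry import StentSpec
from ureteroflow.synthetic import SynthConfig, synth_ureter_profile


@pytest.fixture(scope="session")
def profile():
    """Deterministic tapering pig-ureter profile (min 2.2 mm at i=12)."""
    return synth_ureter_profile(SynthConfig(seed=0, length_sd_mm=0.0))


@pytest.fixture(scope="session")
def stent():
    return StentSpec()


@pytest.fixture(scope="session")
def coarse_flow():
    """Shared side-hole solve on a coarse grid (0.1 mm, v_h = 0.01 m/s)."""
    mesh = mesh_domain(build_domain(), 0.1)
    return solve_simple(mesh, v_h_m_s=0.01)
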