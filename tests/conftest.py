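import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from uavtraits import SceneConfig, extract_stage_traits, generate_field_scene

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_scene():
    """2x2 plots, all four stages — cheap construction oracle."""
    return generate_field_scene(SceneConfig(n_plot_rows=2, n_plot_cols=2), seed=7)


@pytest.fixture(scope="session")
def big_scene():
    """56 plots, final stage only — for plot-height recovery statistics."""
    cfg = SceneConfig(n_plot_rows=8, n_plot_cols=7, cell_size=2.0, stages=(("S4", 84),))
    return generate_field_scene(cfg, seed=11)


@pytest.fixture(scope="session")
def big_scene_traits(big_scene):
    s = big_scene
    df = extract_stage_traits(s.dsm["S4"], s.dem, s.bands["S4"], s.plots)
    truth = s.truth[s.truth.stage == "S4"].set_index("plot_id")
    return df.set_index("plot_id").join(truth)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
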