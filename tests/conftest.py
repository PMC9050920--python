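import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim_config():
    """Factory for quick desk-size simulations (20 cells, sub-second)."""
    from astrogamma.simulator import SimConfig
    from astrogamma.topology import TopologyConfig

    def make(T_total=600.0, T_discard=100.0, n_cells=20, seed=0, **kw):
        top = kw.pop("topology", TopologyConfig(
            n_cells=n_cells, neighborhood=6,
            g_syn=kw.get("g_syn", 0.01), g_syn_P=kw.get("g_syn_P", 0.7),
            seed=seed))
        return SimConfig(T_total=T_total, T_discard=T_discard,
                         n_cells=n_cells, seed=seed, topology=top, **kw)

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
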