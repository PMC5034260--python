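import numpy as np
import pytest

import tdlusim


@pytest.fixture(scope="session")
def tiny_domain():
    """One acinus on a small grid: fast unit-test geometry."""
    return tdlusim.build_tdlu(
        n_acini=1, lumen_radius=2, acinus_spacing=8, grid_size=16,
        jitter=0, epithelial_band=None,
    )


@pytest.fixture(scope="session")
def small_domain():
    """Nine acini, ~250 epithelial nodes: cheap simulation geometry."""
    return tdlusim.build_tdlu(
        n_acini=9, lumen_radius=2, acinus_spacing=12, grid_size=52,
        epithelial_band=None,
    )


@pytest.fixture(scope="session")
def baseline_domain():
    """The default full-size TDLU (~530 epithelial nodes)."""
    return tdlusim.build_tdlu(n_acini=12, lumen_radius=3, acinus_spacing=13, grid_size=80)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
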