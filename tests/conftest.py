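import numpy as np
import pytest

from tradescape import LandmarkConfiguration, fit_surface, gpa, pca_morphospace
from tradescape.synthetic import SyntheticConfig, gen_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    return gen_study(SyntheticConfig(n_tips=40, seed=11))


@pytest.fixture(scope="session")
def small_surfaces(small_study):
    """TPS surfaces fitted to the small study's two functional grids."""
    grid = small_study.grid
    f1 = fit_surface(grid, small_study.f1_values, "tps", 3)
    f2 = fit_surface(grid, small_study.f2_values, "tps", 2)
    return f1, f2


@pytest.fixture()
def random_configs():
    """Ten noisy 35-landmark configurations around a common base shape."""
    rng = np.random.default_rng(7)
    base = rng.normal(size=(35, 3))
    return [
        LandmarkConfiguration(base + rng.normal(0, 0.05, size=(35, 3)), species_id=f"s{i}")
        for i in range(10)
    ]


@pytest.fixture()
def small_morphospace(random_configs):
    return pca_morphospace(gpa(random_configs))
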