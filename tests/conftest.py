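import numpy as np
import pytest
from hypothesis import settings

from epishear import GridSpec, Kymograph, make_condition_preset

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_grid():
    return GridSpec()


@pytest.fixture(scope="session")
def small_grid():
    """A tiny grid for fast I/O round-trip tests."""
    return GridSpec(n_cols=3, n_rows=4, field_width=60.0, plank_height=80.0,
                    t_start=-0.25, t_end=0.5)


@pytest.fixture(scope="session")
def shear_preset():
    return make_condition_preset("+Shear")


@pytest.fixture(scope="session")
def noiseless_shear():
    return make_condition_preset("+Shear", noise_sd=0.0)


def make_kymograph(times, positions, values, **kw):
    return Kymograph(component=kw.pop("component", "y"),
                     times=np.asarray(times, dtype=float),
                     y_positions=np.asarray(positions, dtype=float),
                     values=np.asarray(values, dtype=float), **kw)


@pytest.fixture(scope="session")
def kymo_factory():
    return make_kymograph
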