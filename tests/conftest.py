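import numpy as np
import pytest

from lutphysio.io_formats import SessionBundle, TimeSeries
from lutphysio.synthetic import SimParams, simulate_cmg, simulate_session


@pytest.fixture
def small_params() -> SimParams:
    """A short cystometry/photometry session: 3 voids + 2 NVCs in 30 min."""
    return SimParams(duration_s=1800.0, n_voids=3, n_nvcs=2, seed=7)


@pytest.fixture
def small_session(small_params):
    return simulate_session(small_params)


@pytest.fixture
def small_cmg(small_params):
    return simulate_cmg(small_params)


@pytest.fixture
def tiny_bundle() -> SessionBundle:
    rng = np.random.default_rng(0)
    fs = 100.0
    n = 500
    return SessionBundle(
        animal_id="m007",
        pressure=TimeSeries("pressure", 0.0, fs, 5 + rng.random(n), "cmH2O"),
        emg=TimeSeries("emg", 0.0, fs, rng.standard_normal(n) * 0.05, "mV"),
        metadata={"infusion_rate_ul_min": "25"},
    )
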