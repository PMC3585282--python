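import pytest

from ecisfit import simulate as sim
from ecisfit.model import ElectrodeGeometry, MonolayerParams


@pytest.fixture(scope="session")
def geometry():
    return ElectrodeGeometry()


@pytest.fixture(scope="session")
def clean_model():
    """Electrode model without the high-frequency lead artifact."""
    return sim.ElectrodeModel(series_inductance=0.0)


@pytest.fixture(scope="session")
def doubling_freqs():
    return sim.DEFAULT_FREQUENCIES_HZ


@pytest.fixture(scope="session")
def baseline():
    return MonolayerParams(alpha=6.0, rb=4.0, cm=1.8)


@pytest.fixture(scope="session")
def clean_reference(clean_model, geometry):
    return sim.generate_reference(clean_model, noise_sd=0.0, seed=0, geometry=geometry)
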