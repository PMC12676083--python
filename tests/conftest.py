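import numpy as np
import pytest

from phyllostat import GenotypePreset, get_preset
from phyllostat.synth import RosetteParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def col0_preset():
    return get_preset("col0")


@pytest.fixture
def plt_preset():
    return get_preset("plt_triple")


@pytest.fixture
def noiseless_preset():
    """A pure golden-angle spiral: no initiation noise, no torsion, no episodes."""
    return GenotypePreset(
        name="noiseless",
        delta_i_sd=0.0,
        decussate_rate=0.0,
        m_motif_rate=0.0,
        torsion_mean_deg=0.0,
        torsion_sd_deg=0.0,
        rosette=RosetteParams(amplitude=0.0, noise_sd=0.0),
    )
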