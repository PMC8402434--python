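import numpy as np
import pytest

import phenospec as ps


@pytest.fixture(scope="session")
def visnir_archetypes():
    return ps.make_archetypes("visnir", n_bands=128, effect_size=0.08)


@pytest.fixture(scope="session")
def small_table(visnir_archetypes):
    """Moderate synthetic table for model-level tests (reused, read-only)."""
    return ps.simulate_spectra(visnir_archetypes, (90, 48, 36), ps.NoiseConfig(seed=11))


@pytest.fixture(scope="session")
def cal_val(small_table):
    return ps.split_cal_val(small_table, seed=5)


@pytest.fixture(scope="session")
def spri_encoding():
    return ps.encode_groups_spri(("BH", "AR", "AS"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
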