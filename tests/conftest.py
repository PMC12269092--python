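import numpy as np
import pytest

from lakephotochem import synthio
from lakephotochem.photochem import PhotoConstants


@pytest.fixture(scope="session")
def constants():
    return PhotoConstants()


@pytest.fixture(scope="session")
def solar_field():
    return synthio.gen_solar_spectrum()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def drainage_spec():
    """A representative drainage lake with a planted positive DOC trend."""
    return synthio.LakeSpec(
        lake_id="LTEST",
        hydro_class="headwater_drainage",
        till_class="thin",
        tau_years=0.5,
        doc_baseline=4.0,
        doc_trend=0.057,
        color_per_doc=1.0 / 0.095,
        suva_trend=-0.02,
        phi_true=0.022,
        fe_um=1.9,
    )
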