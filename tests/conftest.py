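import numpy as np
import pytest

from fieldfx.io_roi import ROIPatch
from fieldfx.phantom import PhantomConfig, render_case


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_case():
    """One rendered paired case at calibration scale, shared across tests."""
    cfg = PhantomConfig(image_size=512, tumor_radius=32, field_range=80.0,
                        field_amplitude=1.0, rng_seed=7)
    return render_case(cfg, patient_id="P000", with_specimen=True)


@pytest.fixture(scope="session")
def phantom_roi(phantom_case):
    from fieldfx.io_roi import extract_roi

    x, y = phantom_case.roi_coords["mammo"]["B"]
    return extract_roi(phantom_case.mammogram, x, y, bit_depth=12,
                       patient_id="P000", modality="mammo", region="B")


@pytest.fixture
def constant_roi():
    return ROIPatch(pixels=np.full((128, 128), 7, dtype=np.int64), bit_depth=12)


@pytest.fixture
def random_roi(rng):
    return ROIPatch(pixels=rng.integers(0, 4096, (128, 128)), bit_depth=12)
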