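import numpy as np
import pytest

from spadtrack import Calibration, PixelGrid, PsfModel


@pytest.fixture
def grid8():
    return PixelGrid(8, 8, 100.0)


@pytest.fixture
def psf_narrow():
    return PsfModel(5.0)


@pytest.fixture
def psf_typical():
    # NA 1.45, 665 nm emission -> sigma ~ 96 nm
    return PsfModel.from_optics(1.45, 665.0)


@pytest.fixture
def flat_cal(grid8, psf_typical):
    return Calibration(
        dc=np.full(grid8.shape, 1e-3),
        mask=np.ones(grid8.shape, dtype=bool),
        h=2.0,
        psf=psf_typical,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
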