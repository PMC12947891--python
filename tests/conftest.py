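import numpy as np
import pytest
from hypothesis import settings

from tfpop import AcquisitionGeometry, PsfModel

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def psf():
    return PsfModel(w0=0.25, wz=0.75)


@pytest.fixture
def geometry_small():
    """A small raster geometry with the study's pixel and timing constants."""
    return AcquisitionGeometry(
        pixel_size=0.03195,
        dwell=2.06e-6,
        line_time=5e-3,
        frame_time=128 * 5e-3,
        n_rows=128,
        n_cols=128,
    )


@pytest.fixture
def geometry_case1():
    from tfpop.synthetic import case_geometry

    return case_geometry("case-1")


@pytest.fixture
def geometry_case2():
    from tfpop.synthetic import case_geometry

    return case_geometry("case-2")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
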