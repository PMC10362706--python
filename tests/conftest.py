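"""Shared fixtures: phantom series and frames at unit-test resolution.

Unit tests run the face phantom at 2 mm grid resolution to stay fast; the
acceptance tests use 1 mm (their stated problem size).
"""

import numpy as np
import pytest

from facevol.pipeline import RunConfig
from facevol.sagittal_frame import build_frame
from facevol.synthetic import (CbctPhantomSpec, GaussianBump, PhantomSpec,
                               ToothBlob, make_cbct_series, make_face_series)

UNIT_RES = 2.0


@pytest.fixture(scope="session")
def face_series():
    """Static phantom series (no deformation, no noise)."""
    return make_face_series(PhantomSpec(resolution=UNIT_RES, seed=11))


@pytest.fixture(scope="session")
def bump_series():
    """Series with one analytic Gaussian bump on T1 and T2."""
    bumps = (GaussianBump(center=(74.0, -50.0), amplitude=2.0, sigma=6.0),)
    return make_face_series(PhantomSpec(resolution=UNIT_RES, seed=11,
                                        bumps=bumps))


@pytest.fixture(scope="session")
def frame(face_series):
    return build_frame(face_series.lasers["horizontal-complete"],
                       face_series.lasers["vertical"])


@pytest.fixture(scope="session")
def t0(face_series):
    return face_series.scans["T0"]


@pytest.fixture(scope="session")
def cbct_series():
    return make_cbct_series(CbctPhantomSpec(seed=5))


@pytest.fixture(scope="session")
def small_cbct_series():
    spec = CbctPhantomSpec(shape=(48, 48, 48), spacing=(0.5, 0.5, 0.5),
                           blobs=(ToothBlob(center=(12.0, 12.0, 12.0),
                                            radius=5.0),),
                           seed=2)
    return make_cbct_series(spec)


@pytest.fixture()
def run_config():
    return RunConfig()
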