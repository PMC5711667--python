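import numpy as np
import pytest

from ptinrline import (
    STUDY_PROFILES,
    load_study_frame,
    load_study_samples,
    records_to_frame,
)


@pytest.fixture(scope="session")
def study_records():
    return load_study_samples()


@pytest.fixture(scope="session")
def study_df(study_records):
    # via the record layer so the fixture exercises the reader too
    return records_to_frame(study_records)


@pytest.fixture(scope="session")
def bundled_df():
    return load_study_frame()


@pytest.fixture(scope="session")
def profiles():
    return STUDY_PROFILES


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
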