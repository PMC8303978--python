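import numpy as np
import pytest

from gaitndd.io import GaitRecord
from gaitndd.simulate import default_phenotype, generate_record


@pytest.fixture(scope="session")
def hc_record() -> GaitRecord:
    """One healthy-control record, 300 s at the database's 300 Hz."""
    return generate_record(default_phenotype("HC"), duration_s=300.0, fs=300.0)


@pytest.fixture(scope="session")
def als_record() -> GaitRecord:
    return generate_record(default_phenotype("ALS"), duration_s=300.0, fs=300.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_record(lf, rf, group="HC", fs=100.0, subject_id="toy") -> GaitRecord:
    return GaitRecord(
        subject_id=subject_id, group=group, fs=fs,
        lf=np.asarray(lf, dtype=float), rf=np.asarray(rf, dtype=float),
    )
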