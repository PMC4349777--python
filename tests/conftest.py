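import numpy as np
import pytest

from nephrospan.kidney_classify import AlbuminuriaCategory, EgfrCategory
from nephrospan.person import Sex
from nephrospan.persontime import DEFAULT_SCHEME, StratumCounts
from nephrospan.synthetic_cohort import HazardSpec

LOW_KEY = (Sex.MALE, EgfrCategory.GE60, AlbuminuriaCategory.NORMAL)


@pytest.fixture
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture
def low_key():
    return LOW_KEY


def counts_from_rates(rates, py_per_band=10_000.0, stratum="x", sex=Sex.MALE):
    """StratumCounts whose observed rates equal ``rates`` exactly."""
    rates = np.asarray(rates, dtype=float)
    py = np.full(rates.shape, py_per_band)
    return StratumCounts(
        stratum=stratum, sex=sex, deaths=rates * py, person_years=py
    )


def spec_for(rates, key=LOW_KEY):
    return HazardSpec({key: np.asarray(rates, dtype=float)})


@pytest.fixture
def rng():
    return np.random.default_rng(20140033)
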