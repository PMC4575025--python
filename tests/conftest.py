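from datetime import date, timedelta

import numpy as np
import pytest

from vctgrowth import (
    CohortConfig,
    DEFAULT_MALIGNANT_MODEL,
    DEFAULT_WINDOW,
    NoduleSeries,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def window():
    return DEFAULT_WINDOW


@pytest.fixture(scope="session")
def malignant_model():
    return DEFAULT_MALIGNANT_MODEL


@pytest.fixture(scope="session")
def stable_cohort_89():
    """Default-condition stable cohort: 89 nodules, a = 0.057, fixed seed."""
    return simulate_cohort(CohortConfig(seed=20150917))


def make_series(volumes, days=None, nodule_id="n1", calcified=False):
    """Helper building a NoduleSeries from volumes and day offsets."""
    volumes = np.asarray(volumes, dtype=float)
    if days is None:
        days = np.arange(len(volumes)) * 100.0
    d0 = date(2010, 1, 1)
    return NoduleSeries(
        nodule_id=nodule_id,
        patient_id="p1",
        dates=[d0 + timedelta(days=int(d)) for d in days],
        volumes=volumes,
        calcified=calcified,
    )
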