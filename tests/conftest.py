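import numpy as np
import pandas as pd
import pytest

from lagfuse import CohortConfig, generate_patient
from lagfuse.curation import PatientSeries, curate, fit_transform


@pytest.fixture(scope="session")
def tiny_cfg() -> CohortConfig:
    """Short record (8 days, last 2 for testing) keeping every structural
    feature of the full protocol: gaps, sparse events, offset channels."""
    return CohortConfig(n_patients=2, days_total=8, days_test=2, seed=7)


@pytest.fixture(scope="session")
def tiny_raw(tiny_cfg):
    return generate_patient(tiny_cfg, 0)


@pytest.fixture(scope="session")
def tiny_transformed(tiny_raw):
    ps = curate(tiny_raw)
    ts, scaler = fit_transform(ps)
    return ps, ts, scaler


def make_transformed_series(values_by_channel: dict, split_index: int) -> PatientSeries:
    """Hand-built series already on the transformed (differenced) scale."""
    n = len(next(iter(values_by_channel.values())))
    grid = pd.date_range("2021-01-04 00:05", periods=n, freq="5min")
    return PatientSeries(
        patient_id="T000",
        grid=grid,
        channels={k: np.asarray(v, float) for k, v in values_by_channel.items()},
        split_index=split_index,
        transformed=True,
    )
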