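import numpy as np
import pytest
from hypothesis import settings

import metabotype as mt

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def main_cohort():
    """Default-config synthetic main cohort (n=882), with ground truth."""
    return mt.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def main_fit(main_cohort):
    """Sex-stratified k-means model fitted on the main cohort."""
    cohort, _ = main_cohort
    return mt.fit_sex_stratified(cohort, algorithm="kmeans", seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A quicker n=200 cohort for unit-level checks."""
    cfg = mt.SyntheticConfig(n=200)
    return mt.generate_cohort(cfg, seed=7)


@pytest.fixture()
def make_record():
    """Factory for complete, valid patient records."""

    def _make(
        pid="p1",
        sex="male",
        glucose=(5.0, 8.0, 9.0, 7.0),
        insulin=(10.0, 60.0, 80.0, 40.0),
        uric_acid=400.0,
        age=30.0,
        bmi=35.0,
        **kwargs,
    ):
        grid = mt.OGTT_GRID
        return mt.PatientRecord(
            patient_id=pid,
            sex=sex,
            age=age,
            bmi=bmi,
            ogtt_glucose=dict(zip(grid, glucose)),
            ogtt_insulin=dict(zip(grid, insulin)),
            uric_acid=uric_acid,
            **kwargs,
        )

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
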