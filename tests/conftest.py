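"""Shared fixtures: hand-built toy records and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from silvarisk import Cohort, PatientRecord, default_config, generate_cohort


def make_record(**overrides) -> PatientRecord:
    """A valid low-risk baseline record, overridable field by field."""
    base = dict(
        patient_id="P001",
        age=46.0,
        figo_stage=1,
        silva="A",
        tumor_size=1.5,
        dsi_fraction=0.2,
        lvsi="none",
        ln_site="none",
        margin_positive=False,
        parametrial_positive=False,
        pni=False,
        adjuvant=False,
        rfs_time=60.0,
        rfs_event=False,
        os_time=60.0,
        os_event=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def toy_cohort() -> Cohort:
    """Five hand-built records, two of them high-risk."""
    return Cohort(
        records=(
            make_record(patient_id="P1"),
            make_record(patient_id="P2", silva="C", lvsi="substantial",
                        tumor_size=4.0, dsi_fraction=0.9,
                        rfs_time=20.0, rfs_event=True, os_time=30.0, os_event=True),
            make_record(patient_id="P3", silva="B", lvsi="mild", dsi_fraction=0.5),
            make_record(patient_id="P4", ln_site="pelvic", silva="C"),
            make_record(patient_id="P5", margin_positive=True, silva="B"),
        ),
        label="toy",
    )


@pytest.fixture(scope="session")
def synthetic_cohort_500() -> Cohort:
    return generate_cohort(default_config().replace(n=500, seed=11))


@pytest.fixture(scope="session")
def synthetic_cohort_2000() -> Cohort:
    return generate_cohort(default_config().replace(n=2000, seed=11))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
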