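import numpy as np
import pytest

from daoh90 import (GeneratorConfig, generate_cohort, batch_compute,
                    cohort_to_frames)


@pytest.fixture(scope="session")
def default_cohort():
    """A 2000-patient synthetic cohort under the default (strong-coupling)
    generator settings, shared across the suite."""
    return generate_cohort(GeneratorConfig(n_patients=2000, seed=20240901))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    """(patients_df, daoh_table) for the default cohort, standard variant."""
    pat, _, _ = cohort_to_frames(default_cohort)
    table = batch_compute(default_cohort.patients, default_cohort.episodes)
    return pat, table


def random_patient_case(rng, max_horizon=90):
    """One randomized DAOH scenario: overlapping/abutting episodes, optional
    in- or out-of-hospital death, random horizon.  Shared by the oracle
    equivalence tests and the acceptance suite."""
    from daoh90 import HospitalEpisode, PatientRecord

    idx = int(rng.integers(0, 50))
    horizon = int(rng.integers(1, max_horizon + 1))
    n_ep = int(rng.integers(1, 6))
    episodes = []
    for _ in range(n_ep):
        a = idx + int(rng.integers(-10, horizon + 10))
        d = a + int(rng.integers(0, 40))
        episodes.append(HospitalEpisode("X", a, d))
    death = None
    if rng.random() < 0.4:
        death = idx + int(rng.integers(0, horizon + 20))
    patient = PatientRecord(patient_id="X", index_day=idx, death_day=death)
    variant = "death_zero" if rng.random() < 0.5 else "standard"
    return patient, episodes, horizon, variant
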