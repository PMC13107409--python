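import numpy as np
import pytest

from alstrials.trial_data import (
    Observation,
    PatientCourse,
    TrialDataset,
    VisitSchedule,
)


def make_patient(pid, arm, times, scores, death=None, dropout=None):
    """Patient with observed scores where ``scores`` is not None."""
    obs = [
        Observation(pid, float(t), None if s is None else float(s), s is not None)
        for t, s in zip(times, scores)
    ]
    baseline = float(scores[0])
    return PatientCourse(
        patient_id=pid,
        arm=arm,
        baseline_score=baseline,
        observations=obs,
        death_time=death,
        dropout_time=dropout,
    )


def make_dataset(patients, times):
    return TrialDataset(schedule=VisitSchedule(tuple(float(t) for t in times)), patients=patients)


@pytest.fixture
def two_patient_dataset():
    times = (0, 4, 8)
    pats = [
        make_patient("A", "placebo", times, [40, 38, 36]),
        make_patient("B", "active", times, [42, 41, 40]),
    ]
    return make_dataset(pats, times)


@pytest.fixture(scope="session")
def master_dataset():
    """One fixed Ceftriaxone-like synthetic master dataset (the permutation
    engine's substrate)."""
    from alstrials.generator import ceftriaxone_like_config, simulate_trial

    return simulate_trial(ceftriaxone_like_config(seed=42))


@pytest.fixture(scope="session")
def clean_master_dataset():
    """A complete (no-attrition, no intermittent missingness) null dataset."""
    from dataclasses import replace

    from alstrials.generator import AttritionModel, ceftriaxone_like_config, simulate_trial

    cfg = ceftriaxone_like_config(seed=7)
    cfg = replace(
        cfg,
        n=402,
        attrition=AttritionModel(0.0, 0.8, 0.0, 0.0),
    )
    return simulate_trial(cfg)
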