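import numpy as np
import pytest

from thermadiff import GeneratorConfig, InjurySpec, PatientRecord, PatientStream
from thermadiff.stream_io import LOCATIONS, MINUTES_PER_DAY


def build_stream(
    patient_id="P01",
    days=3,
    minutes_per_day=10,
    left=90.0,
    right=90.0,
    worn_left=True,
    worn_right=True,
    start_minute=0,
):
    """Hand-built stream: the same reading at every location of a foot.

    ``left``/``right`` may be scalars or callables ``(day, minute) -> temp``.
    """
    day_idx, minute_idx, temps, worn = [], [], [], []
    for d in range(days):
        for m in range(start_minute, start_minute + minutes_per_day):
            day_idx.append(d)
            minute_idx.append(m)
            lv = left(d, m) if callable(left) else left
            rv = right(d, m) if callable(right) else right
            temps.append([[lv] * 6, [rv] * 6])
            worn.append([worn_left, worn_right])
    n = len(day_idx)
    return PatientStream(
        patient_id=patient_id,
        day=np.asarray(day_idx, dtype=np.int64),
        minute=np.asarray(minute_idx, dtype=np.int64),
        temps=np.asarray(temps, dtype=np.float64).reshape(n, 2, 6),
        worn=np.asarray(worn, dtype=bool).reshape(n, 2),
    )


def make_patient(patient_id="S01", cohort="study", injury=None, **kw):
    if cohort == "study" and injury is None:
        injury = InjurySpec(
            injury_type="ulcer",
            foot="right",
            locations=("mts5",),
            onset_day=90,
            diagnosis_day=100,
            peak_offset=5.0,
            ramp_days=0,
        )
    defaults = dict(age=65, sex="male", diagnoses=frozenset({"neuropathy"}))
    defaults.update(kw)
    return PatientRecord(
        patient_id=patient_id, cohort=cohort, injury=injury, **defaults
    )


@pytest.fixture
def noiseless_config():
    """All stochastic temperature terms shared between feet; differential is 0."""
    return GeneratorConfig(
        n_study=0,
        n_control=1,
        days=20,
        wear_minutes_per_day_mean=120,
        wear_minutes_per_day_sd=10,
        bilateral_noise_sd=0.0,
        patient_noise_cv=0.0,
        seed=11,
    )


@pytest.fixture
def small_config():
    return GeneratorConfig(
        n_study=1,
        n_control=2,
        days=110,
        wear_minutes_per_day_mean=150,
        wear_minutes_per_day_sd=15,
        bilateral_noise_sd=0.5,
        patient_noise_cv=0.0,
        seed=5,
    )
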