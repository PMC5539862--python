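import numpy as np
import pytest

from stagewalk.synthetic import Cohort, CohortConfig, Patient, RawRecording, generate_cohort


def make_recording(
    timestamps, fx=None, fy=None, fz=None, patient_id="P001", stage="middle"
):
    """Build a RawRecording from callables (or constants) per axis."""
    t = np.asarray(timestamps, dtype=float)

    def ev(f, default):
        if f is None:
            return np.full_like(t, default)
        if callable(f):
            return np.asarray(f(t), dtype=float)
        return np.full_like(t, float(f))

    return RawRecording(patient_id, stage, t, ev(fx, 0.0), ev(fy, 0.0), ev(fz, 0.0))


def small_cohort_config(stage_effect=None, seed=0, durations=(60.0, 120.0), noise_sd=0.5):
    """A seconds-scale cohort: 3/4/3 patients, 2-3 recordings each."""
    return CohortConfig(
        n_patients={"early": 3, "middle": 4, "late": 3},
        recordings_per_patient={
            "early": (3, 3, 2),
            "middle": (3, 2, 2, 2),
            "late": (3, 2, 2),
        },
        duration_range=durations,
        stage_effect=stage_effect or {"x": 1.2, "y": 1.0, "z": 0.15},
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config(seed=11))


@pytest.fixture(scope="session")
def separated_cohort():
    """Cohort with stage effects far above the noise floor on x and y."""
    return generate_cohort(
        small_cohort_config(stage_effect={"x": 12.0, "y": 10.0, "z": 0.2}, seed=7)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (the printed study composition)."""
    return generate_cohort(seed=1)
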