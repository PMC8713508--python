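import numpy as np
import pandas as pd
import pytest

from sidkit.catalog import SIGN_IDS
from sidkit.core_cohort import Cohort, OBSERVATION_COLUMNS, Patient


def make_decedent(pid: str, death_h: float, age: float = 80.0) -> Patient:
    return Patient(pid, age=age, sex="f", diagnosis="respiratory",
                   obs_start_h=0.0, terminal_h=death_h, died=True)


def obs_frame(rows: list[dict]) -> pd.DataFrame:
    """Rows of {patient_id, time_h, <sign>: 0/1/nan..., sbp, hr, ...}."""
    frame = pd.DataFrame(rows)
    return frame.reindex(columns=list(OBSERVATION_COLUMNS))


def cohort_with_onsets(
    onsets: dict[str, dict[str, float]],
    death_h: dict[str, float],
    step_h: float = 12.0,
    sbp: float = 100.0,
    hr: float = 80.0,
) -> Cohort:
    """Hand-laid decedent cohort: `onsets[pid][sign] = onset hour`; flags
    persist from onset to death; flat vitals (SI = hr/sbp throughout)."""
    patients = [make_decedent(pid, t) for pid, t in death_h.items()]
    rows = []
    for pid, t_death in death_h.items():
        extra = list(onsets.get(pid, {}).values())  # observe each onset instant
        times = np.unique(np.concatenate(
            [np.arange(0.0, t_death, step_h), [t_death], extra]
        ))
        for t in times:
            row = {"patient_id": pid, "time_h": t, "sbp": sbp, "hr": hr}
            for s in SIGN_IDS:
                onset = onsets.get(pid, {}).get(s)
                row[s] = 0.0 if onset is None else float(t >= onset)
            rows.append(row)
    return Cohort(patients, obs_frame(rows))


def random_cohort(rng: np.random.Generator, n: int) -> Cohort:
    """Random decedent cohort with random persistent sign onsets and noisy
    vitals (so shock-index events also occur), for oracle comparisons."""
    patients = []
    rows = []
    for i in range(n):
        pid = f"r{i:03d}"
        death = float(rng.integers(4, 20)) * 12.0
        patients.append(make_decedent(pid, death))
        times = np.arange(0.0, death + 1.0, 12.0)
        onsets = {}
        for s in SIGN_IDS:
            if rng.random() < 0.45:
                onsets[s] = float(rng.choice(times))
        for t in times:
            row = {
                "patient_id": pid,
                "time_h": t,
                "sbp": float(rng.uniform(75.0, 135.0)),
                "hr": float(rng.uniform(55.0, 140.0)),
            }
            for s in SIGN_IDS:
                row[s] = float(t >= onsets[s]) if s in onsets else 0.0
            rows.append(row)
    return Cohort(patients, obs_frame(rows))


@pytest.fixture
def toy4() -> Cohort:
    """Four decedents (death at 120 h) with hand-laid onsets."""
    return cohort_with_onsets(
        onsets={
            "a": {"radial_pulselessness": 110.0},
            "b": {"radial_pulselessness": 30.0},
            "c": {},
            "d": {"mandibular_respiration": 60.0},
        },
        death_h={"a": 120.0, "b": 120.0, "c": 120.0, "d": 120.0},
    )
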