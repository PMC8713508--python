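"""Cohort domain model: patients, 12-hourly observations, CSV I/O, first events.

Time is measured in hours (non-negative reals) from a per-cohort origin;
"days" in reports are hours / 24.  Sign flags are ternary: present (1),
absent (0) or missing (empty cell / NaN); a missing flag is skipped, never
treated as absent.  A sign's event is its FIRST explicitly positive
observation; later disappearance is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import SIGN_IDS

__all__ = [
    "SchemaError",
    "CohortValidationError",
    "UndefinedResultError",
    "CENSOR_REASONS",
    "VITAL_COLUMNS",
    "Observation",
    "Patient",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "first_event_time",
    "apply_discontinuation",
]


class SchemaError(ValueError):
    """An input table is missing a required column or carries unknown labels."""


class CohortValidationError(ValueError):
    """A cohort invariant is violated (named patient in the message)."""


class UndefinedResultError(ValueError):
    """A statistic is undefined on this input (e.g. no exhibitor of a sign)."""


CENSOR_REASONS: tuple[str, ...] = (
    "ate_gt_half_2d",
    "60_days_elapsed",
    "discharged",
    "ventilator",
    "artificial_nutrition",
    "cancer_diagnosed",
)

VITAL_COLUMNS: tuple[str, ...] = ("sbp", "dbp", "hr", "temp", "rr", "spo2")

PATIENT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "diagnosis",
    "charlson",
    "obs_start_h",
    "terminal_h",
    "terminal_status",
    "censor_reason",
)

OBSERVATION_COLUMNS: tuple[str, ...] = ("patient_id", "time_h") + SIGN_IDS + VITAL_COLUMNS


@dataclass(frozen=True)
class Observation:
    """One bedside assessment: ternary sign flags plus optional vitals."""

    patient_id: str
    time_h: float
    signs: Mapping[str, bool | None] = field(default_factory=dict)
    sbp: float | None = None
    dbp: float | None = None
    hr: float | None = None
    temp: float | None = None
    rr: float | None = None
    spo2: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.signs) - set(SIGN_IDS)
        if unknown:
            raise SchemaError(f"unknown sign label(s): {sorted(unknown)}")
        if self.sbp is not None and not self.sbp > 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: SBP must be > 0, got {self.sbp}"
            )
        if self.hr is not None and self.hr < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: HR must be >= 0, got {self.hr}"
            )
        if self.spo2 is not None and not 0 <= self.spo2 <= 100:
            raise CohortValidationError(
                f"patient {self.patient_id}: SpO2 must be in [0, 100], got {self.spo2}"
            )


@dataclass(frozen=True)
class Patient:
    """One subject with exactly one terminal status (death or censoring)."""

    patient_id: str
    age: float
    sex: str
    diagnosis: str
    obs_start_h: float
    terminal_h: float
    died: bool
    censor_reason: str | None = None
    charlson: float | None = None

    def __post_init__(self) -> None:
        if self.terminal_h < self.obs_start_h:
            raise CohortValidationError(
                f"patient {self.patient_id}: terminal time {self.terminal_h} "
                f"precedes observation start {self.obs_start_h}"
            )
        if self.died and self.censor_reason is not None:
            raise CohortValidationError(
                f"patient {self.patient_id}: decedent cannot carry a censor reason"
            )
        if not self.died:
            if self.censor_reason not in CENSOR_REASONS:
                raise CohortValidationError(
                    f"patient {self.patient_id}: censor_reason must be one of "
                    f"{CENSOR_REASONS}, got {self.censor_reason!r}"
                )


class Cohort:
    """Patients plus their time-ordered observations.

    Observations are held in a single :class:`pandas.DataFrame` with one row
    per (patient, time) and the sign flags encoded as ``1.0`` / ``0.0`` /
    ``NaN``; :class:`Observation` objects are materialised on demand.
    """

    def __init__(self, patients: Iterable[Patient], observations: pd.DataFrame | None):
        self.patients: dict[str, Patient] = {}
        for p in patients:
            if p.patient_id in self.patients:
                raise CohortValidationError(f"duplicate patient id {p.patient_id}")
            self.patients[p.patient_id] = p
        if observations is None:
            observations = pd.DataFrame(columns=OBSERVATION_COLUMNS)
        missing = set(OBSERVATION_COLUMNS) - set(observations.columns)
        if missing:
            raise SchemaError(f"observation table missing column(s): {sorted(missing)}")
        obs = observations.loc[:, list(OBSERVATION_COLUMNS)].copy()
        obs["patient_id"] = obs["patient_id"].astype(str)
        for c in OBSERVATION_COLUMNS[1:]:
            obs[c] = pd.to_numeric(obs[c], errors="coerce").astype(float)
        obs = obs.sort_values(["patient_id", "time_h"], kind="stable").reset_index(drop=True)
        self.obs: pd.DataFrame = obs
        self._validate()

    @classmethod
    def from_records(
        cls, patients: Iterable[Patient], observations: Iterable[Observation]
    ) -> "Cohort":
        rows = []
        for o in observations:
            row: dict[str, object] = {"patient_id": o.patient_id, "time_h": o.time_h}
            for s in SIGN_IDS:
                v = o.signs.get(s)
                row[s] = np.nan if v is None else float(v)
            for c in VITAL_COLUMNS:
                v = getattr(o, c)
                row[c] = np.nan if v is None else float(v)
            rows.append(row)
        frame = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
        return cls(patients, frame)

    def _validate(self) -> None:
        obs = self.obs
        unknown = set(obs["patient_id"]) - set(self.patients)
        if unknown:
            raise CohortValidationError(f"observations for unknown patient(s): {sorted(unknown)}")
        sign_vals = obs[list(SIGN_IDS)].to_numpy(float)
        bad = ~(np.isnan(sign_vals) | (sign_vals == 0.0) | (sign_vals == 1.0))
        if bad.any():
            raise SchemaError("sign flags must be 0, 1 or empty")
        for pid, g in obs.groupby("patient_id", sort=False):
            t = g["time_h"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise CohortValidationError(f"patient {pid}: timestamps not strictly ascending")
            p = self.patients[pid]
            if t[0] < p.obs_start_h:
                raise CohortValidationError(f"patient {pid}: observation before start")
            if t[-1] > p.terminal_h:
                raise CohortValidationError(f"patient {pid}: observation after terminal time")
        sbp = obs["sbp"].to_numpy(float)
        if np.any(sbp[~np.isnan(sbp)] <= 0):
            raise CohortValidationError("SBP must be > 0 where present")
        hr = obs["hr"].to_numpy(float)
        if np.any(hr[~np.isnan(hr)] < 0):
            raise CohortValidationError("HR must be >= 0 where present")
        spo2 = obs["spo2"].to_numpy(float)
        ok = np.isnan(spo2) | ((spo2 >= 0) & (spo2 <= 100))
        if not ok.all():
            raise CohortValidationError("SpO2 must be in [0, 100] where present")

    # -- accessors ---------------------------------------------------------

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients)

    @property
    def decedent_ids(self) -> list[str]:
        return [pid for pid, p in self.patients.items() if p.died]

    def patient_observations(self, patient_id: str) -> pd.DataFrame:
        if patient_id not in self.patients:
            raise KeyError(f"unknown patient {patient_id}")
        return self.obs[self.obs["patient_id"] == patient_id]

    def iter_observations(self, patient_id: str) -> Iterator[Observation]:
        for _, r in self.patient_observations(patient_id).iterrows():
            signs = {
                s: (None if math.isnan(r[s]) else bool(r[s])) for s in SIGN_IDS
            }
            vit = {
                c: (None if math.isnan(r[c]) else float(r[c])) for c in VITAL_COLUMNS
            }
            yield Observation(str(r["patient_id"]), float(r["time_h"]), signs, **vit)

    def decedents_only(self) -> "Cohort":
        keep = set(self.decedent_ids)
        return Cohort(
            [p for p in self.patients.values() if p.patient_id in keep],
            self.obs[self.obs["patient_id"].isin(keep)],
        )

    def __len__(self) -> int:
        return len(self.patients)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.patients != other.patients:
            return False
        a, b = self.obs, other.obs
        if len(a) != len(b):
            return False
        if len(a) == 0:
            return True
        eq = (a.to_numpy(object) == b.to_numpy(object))
        both_nan = a.isna().to_numpy() & b.isna().to_numpy()
        return bool((eq | both_nan).all())

    def __repr__(self) -> str:
        return f"Cohort(n_patients={len(self.patients)}, n_observations={len(self.obs)})"


# -- CSV I/O ---------------------------------------------------------------


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table missing column(s): {missing}")


def read_cohort(patient_path, observation_path) -> Cohort:
    """Load a cohort from the two-CSV layout (see the data dictionary)."""
    pt = pd.read_csv(patient_path, dtype={"patient_id": str}, float_precision="round_trip")
    _require_columns(pt, PATIENT_COLUMNS, "patient")
    patients = []
    for _, r in pt.iterrows():
        died = str(r["terminal_status"]).strip().lower() == "died"
        reason = r["censor_reason"]
        reason = None if pd.isna(reason) or str(reason) == "" else str(reason)
        charlson = None if pd.isna(r["charlson"]) else float(r["charlson"])
        patients.append(
            Patient(
                patient_id=str(r["patient_id"]),
                age=float(r["age"]),
                sex=str(r["sex"]),
                diagnosis=str(r["diagnosis"]),
                obs_start_h=float(r["obs_start_h"]),
                terminal_h=float(r["terminal_h"]),
                died=died,
                censor_reason=reason,
                charlson=charlson,
            )
        )
    ob = pd.read_csv(observation_path, dtype={"patient_id": str}, float_precision="round_trip")
    if len(ob) == 0 and list(ob.columns) == []:  # fully empty file
        ob = pd.DataFrame(columns=OBSERVATION_COLUMNS)
    _require_columns(ob, OBSERVATION_COLUMNS, "observation")
    return Cohort(patients, ob)


def write_cohort(cohort: Cohort, patient_path, observation_path) -> None:
    """Write the two-CSV layout; missing values become empty cells."""
    rows = []
    for p in cohort.patients.values():
        rows.append(
            {
                "patient_id": p.patient_id,
                "age": p.age,
                "sex": p.sex,
                "diagnosis": p.diagnosis,
                "charlson": "" if p.charlson is None else p.charlson,
                "obs_start_h": p.obs_start_h,
                "terminal_h": p.terminal_h,
                "terminal_status": "died" if p.died else "censored",
                "censor_reason": "" if p.censor_reason is None else p.censor_reason,
            }
        )
    pd.DataFrame(rows, columns=list(PATIENT_COLUMNS)).to_csv(patient_path, index=False)
    obs = cohort.obs.copy()
    for s in SIGN_IDS:  # flags as bare 0/1, not 0.0/1.0
        obs[s] = obs[s].map(lambda v: "" if math.isnan(v) else str(int(v)))
    obs.to_csv(observation_path, index=False)


# -- first events ----------------------------------------------------------


def first_event_time(cohort: Cohort, patient_id: str, sign: str) -> float | None:
    """Earliest timestamp at which `sign` is explicitly present, else None."""
    if sign not in SIGN_IDS:
        raise KeyError(f"unknown sign {sign!r}")
    g = cohort.patient_observations(patient_id)
    pos = g.loc[g[sign] == 1.0, "time_h"]
    if pos.empty:
        return None
    return float(pos.iloc[0])


def first_event_times(cohort: Cohort, sign: str) -> dict[str, float]:
    """First event time per patient for one sign (patients without event omitted)."""
    if sign not in SIGN_IDS:
        raise KeyError(f"unknown sign {sign!r}")
    sub = cohort.obs.loc[cohort.obs[sign] == 1.0, ["patient_id", "time_h"]]
    if sub.empty:
        return {}
    return sub.groupby("patient_id", sort=False)["time_h"].min().astype(float).to_dict()


# -- discontinuation -------------------------------------------------------


def apply_discontinuation(
    patient: Patient,
    observations: pd.DataFrame,
    ate_more_than_half: Sequence[bool],
    max_days: float = 60.0,
) -> tuple[Patient, pd.DataFrame]:
    """Censor a record at the first triggered discontinuation rule.

    ``ate_more_than_half[d]`` covers observation day ``d`` (0-based,
    24-hour days from ``obs_start_h``).  The meal rule triggers at the end
    of the second consecutive qualifying day — the earliest instant at
    which "two or more days" is decidable.  Death stands if it precedes
    every trigger.  The terminal time never moves later.
    """
    triggers: list[tuple[float, str]] = []
    for d in range(1, len(ate_more_than_half)):
        if ate_more_than_half[d - 1] and ate_more_than_half[d]:
            triggers.append((patient.obs_start_h + 24.0 * (d + 1), "ate_gt_half_2d"))
            break
    limit = patient.obs_start_h + 24.0 * max_days
    if patient.terminal_h > limit:
        triggers.append((limit, "60_days_elapsed"))
    triggers = [(t, r) for t, r in triggers if t < patient.terminal_h]
    if not triggers:
        return patient, observations
    t_c, reason = min(triggers)
    truncated = replace(
        patient, terminal_h=t_c, died=False, censor_reason=reason
    )
    kept = observations[observations["time_h"] <= t_c]
    return truncated, kept
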