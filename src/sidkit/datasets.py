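"""Packaged reference data: the per-sign count table over the 50 decedents
and a deterministic cohort reconstruction consistent with it."""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .catalog import SIGN_IDS
from .core_cohort import Cohort, OBSERVATION_COLUMNS, Patient


def load_table3_counts() -> dict:
    """The printed per-sign counts: n within 72 h of death and the
    mortality numerators/denominators at 72 h and 24 h, over 50 decedents."""
    text = resources.files("sidkit.data").joinpath("table3_counts.json").read_text()
    return json.loads(text)


def cohort_from_table3_counts(counts: dict | None = None) -> Cohort:
    """Deterministic decedent cohort whose per-sign counts reproduce the
    reference table exactly.

    Each of the ``n_decedents`` patients is observed 12-hourly over 10 days
    and dies at hour 240.  For each sign, exhibitors are assigned onset
    leads of 12 h (death within 24 h of onset), 48 h (within 72 h but not
    24 h) or 96 h (beyond 72 h) so that the mortality numerators and the
    prevalence count match the table; flags persist from onset to death.
    Sign assignments are independent across signs, which is immaterial for
    per-sign statistics.
    """
    if counts is None:
        counts = load_table3_counts()
    n = counts["n_decedents"]
    death_h = 240.0
    times = np.arange(0.0, death_h + 1.0, 12.0)
    patients = [
        Patient(f"d{i:03d}", age=85.8, sex="f", diagnosis="respiratory",
                obs_start_h=0.0, terminal_h=death_h, died=True)
        for i in range(n)
    ]
    frames = []
    for i, p in enumerate(patients):
        frame = pd.DataFrame({"patient_id": p.patient_id, "time_h": times})
        for sid in SIGN_IDS:
            row = counts["signs"][sid]
            if row["mortality_72h"] is None:
                frame[sid] = 0.0
                continue
            num72, den = row["mortality_72h"]
            num24 = row["mortality_24h"][0]
            if i < num24:
                lead = 12.0
            elif i < num72:
                lead = 48.0
            elif i < den:
                lead = 96.0
            else:
                lead = None
            col = np.zeros(times.size)
            if lead is not None:
                col[times >= death_h - lead] = 1.0
            frame[sid] = col
        # flat vitals; SI stays at 0.8, so no shock-index event interferes
        frame["sbp"] = 100.0
        frame["hr"] = 80.0
        frames.append(frame)
    obs = pd.concat(frames, ignore_index=True).reindex(columns=list(OBSERVATION_COLUMNS))
    return Cohort(patients, obs)
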