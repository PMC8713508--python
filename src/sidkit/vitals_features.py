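"""Shock index, the SI > 1.0 predictor event, and backward-binned vitals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_cohort import Cohort, VITAL_COLUMNS

__all__ = [
    "shock_index",
    "si_series",
    "si_event_time",
    "TrajectorySummary",
    "binned_trajectory",
    "trajectory_frame",
]

TRAJECTORY_VITALS: tuple[str, ...] = VITAL_COLUMNS + ("si",)


def shock_index(hr: float, sbp: float) -> float:
    """Heart rate divided by systolic blood pressure.

    Scale-consistent: shock_index(k*hr, k*sbp) == shock_index(hr, sbp).
    """
    if sbp <= 0:
        raise ValueError(f"SBP must be > 0 to compute the shock index, got {sbp}")
    if hr < 0:
        raise ValueError(f"HR must be >= 0, got {hr}")
    return hr / sbp


def si_series(observations: pd.DataFrame) -> pd.Series:
    """Per-row shock index; NaN where HR or SBP is missing (SBP > 0 enforced)."""
    hr = observations["hr"].to_numpy(float)
    sbp = observations["sbp"].to_numpy(float)
    out = np.full(len(observations), np.nan)
    ok = ~np.isnan(hr) & ~np.isnan(sbp)
    out[ok] = hr[ok] / sbp[ok]
    return pd.Series(out, index=observations.index, name="si")


def si_event_time(
    cohort: Cohort, patient_id: str, threshold: float = 1.0
) -> float | None:
    """Earliest timestamp with shock index strictly above `threshold`.

    Rows lacking HR or SBP are skipped.  The inequality is strict.
    """
    g = cohort.patient_observations(patient_id)
    si = si_series(g)
    hit = g.loc[si.to_numpy() > threshold, "time_h"]
    if hit.empty:
        return None
    return float(hit.iloc[0])


def si_event_times(cohort: Cohort, threshold: float = 1.0) -> dict[str, float]:
    """First SI-above-threshold time per patient (patients without event omitted)."""
    obs = cohort.obs
    si = si_series(obs).to_numpy()
    sub = obs.loc[si > threshold, ["patient_id", "time_h"]]
    if sub.empty:
        return {}
    return sub.groupby("patient_id", sort=False)["time_h"].min().astype(float).to_dict()


@dataclass(frozen=True)
class TrajectorySummary:
    """Per-bin summary of one vital, binned backward from death.

    Bin ``b`` covers ``(12*b, 12*(b+1)]`` hours before death (half-open);
    an observation exactly at death falls in bin 0.  Bins with ``n == 0``
    have NaN mean/sd and are flagged empty.
    """

    vital: str
    bin_hours: float
    bin_start_h: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    @property
    def empty_bins(self) -> np.ndarray:
        return self.n == 0


def binned_trajectory(
    cohort: Cohort,
    vital: str,
    bin_hours: float = 12.0,
    span_hours: float = 168.0,
    stat: str = "mean",
) -> TrajectorySummary:
    """Backward-binned location/spread of one vital over decedents.

    `stat` selects the per-bin location estimate: "mean" (default) or
    "median"; the spread is always the standard deviation.
    """
    if vital not in TRAJECTORY_VITALS:
        raise KeyError(f"unknown vital {vital!r}; expected one of {TRAJECTORY_VITALS}")
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    n_bins = int(np.ceil(span_hours / bin_hours))
    death_by_pid = {
        pid: p.terminal_h for pid, p in cohort.patients.items() if p.died
    }
    obs = cohort.obs[cohort.obs["patient_id"].isin(death_by_pid)]
    values = si_series(obs) if vital == "si" else obs[vital]
    death = obs["patient_id"].map(death_by_pid).to_numpy(float)
    offset = death - obs["time_h"].to_numpy(float)
    vals = values.to_numpy(float)
    keep = ~np.isnan(vals) & (offset >= 0) & (offset <= span_hours)
    offset, vals = offset[keep], vals[keep]
    # (12b, 12(b+1)] half-open backward bins; offset 0 goes to bin 0
    idx = np.ceil(offset / bin_hours).astype(int) - 1
    idx[idx < 0] = 0
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        v = vals[idx == b]
        n[b] = v.size
        if v.size:
            mean[b] = np.mean(v) if stat == "mean" else np.median(v)
            sd[b] = np.std(v, ddof=0)
    return TrajectorySummary(
        vital=vital,
        bin_hours=bin_hours,
        bin_start_h=np.arange(n_bins) * bin_hours,
        mean=mean,
        sd=sd,
        n=n,
    )


def trajectory_frame(summaries: list[TrajectorySummary]) -> pd.DataFrame:
    """Flatten summaries to the export layout."""
    rows = []
    for s in summaries:
        for b in range(len(s.n)):
            rows.append(
                {
                    "vital": s.vital,
                    "bin_start_h_before_death": s.bin_start_h[b],
                    "mean": s.mean[b],
                    "sd": s.sd[b],
                    "n": s.n[b],
                }
            )
    return pd.DataFrame(rows, columns=["vital", "bin_start_h_before_death", "mean", "sd", "n"])
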