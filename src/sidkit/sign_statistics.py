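"""Per-sign cohort statistics: prevalence near death, mortality after onset,
and the backward Kaplan-Meier onset estimate with a Brookmeyer-Crowley CI.

All statistics are computed over decedents.  Horizon comparisons are
inclusive ("within 72 hours" means <= 72 h).  Prevalence counts a sign as
present within the window if ANY observation inside the window is positive
(signs persist after onset, so a sign with early onset still counts), while
mortality-after-onset is anchored to the FIRST appearance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .catalog import PREDICTOR_IDS, SI_PREDICTOR, SIGN_IDS, Horizon
from .core_cohort import Cohort, UndefinedResultError, first_event_times
from .vitals_features import si_event_times, si_series

__all__ = [
    "KmEstimate",
    "SignSummary",
    "predictor_event_times",
    "prevalence_within_window",
    "mortality_after_onset",
    "km_curve",
    "km_backward_onset",
    "summarize_signs",
    "summary_frame",
]


def predictor_event_times(cohort: Cohort, predictor: str) -> dict[str, float]:
    """First-event time per patient for any of the 12 predictors."""
    if predictor == SI_PREDICTOR:
        return si_event_times(cohort)
    return first_event_times(cohort, predictor)


def _death_times(cohort: Cohort) -> dict[str, float]:
    deaths = {pid: p.terminal_h for pid, p in cohort.patients.items() if p.died}
    if not deaths:
        raise UndefinedResultError("cohort contains no decedent")
    return deaths


def prevalence_within_window(
    cohort: Cohort, predictor: str, window_h: float = 72.0
) -> tuple[int, float]:
    """Decedents with the predictor positive at some observation within
    `window_h` hours of death, as (count, proportion of all decedents)."""
    if predictor not in PREDICTOR_IDS:
        raise KeyError(f"unknown predictor {predictor!r}")
    deaths = _death_times(cohort)
    obs = cohort.obs[cohort.obs["patient_id"].isin(deaths)]
    if predictor == SI_PREDICTOR:
        positive = si_series(obs).to_numpy() > 1.0
    else:
        positive = obs[predictor].to_numpy(float) == 1.0
    offset = obs["patient_id"].map(deaths).to_numpy(float) - obs["time_h"].to_numpy(float)
    hit = positive & (offset >= 0) & (offset <= window_h)
    count = obs.loc[hit, "patient_id"].nunique()
    return int(count), count / len(deaths)


def mortality_after_onset(
    cohort: Cohort, predictor: str, horizon: Horizon
) -> tuple[int, int, float]:
    """Of decedents ever exhibiting the predictor, how many died within the
    horizon of its first appearance: (numerator, denominator, proportion)."""
    if predictor not in PREDICTOR_IDS:
        raise KeyError(f"unknown predictor {predictor!r}")
    deaths = _death_times(cohort)
    events = predictor_event_times(cohort, predictor)
    exhibitors = {pid: t for pid, t in events.items() if pid in deaths}
    if not exhibitors:
        raise UndefinedResultError(
            f"no decedent exhibits {predictor!r}; mortality after onset is undefined"
        )
    den = len(exhibitors)
    num = sum(1 for pid, t in exhibitors.items() if deaths[pid] - t <= horizon.hours)
    return num, den, num / den


# -- Kaplan-Meier ----------------------------------------------------------


@dataclass(frozen=True)
class KmEstimate:
    """Kaplan-Meier median (days before death) with a 95% CI.

    The CI follows the Brookmeyer-Crowley construction on the log(-log)
    (exponential Greenwood) scale.  Bounds are inf when the corresponding
    band never crosses 0.5.
    """

    median_days: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int


def km_curve(
    durations: np.ndarray, events: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Product-limit estimate with exponential-Greenwood confidence bands.

    Returns (event_times, survival, lower_band, upper_band), evaluated at
    the distinct uncensored event times.
    """
    d = np.asarray(durations, float)
    e = np.asarray(events, bool)
    if d.size == 0 or not e.any():
        raise UndefinedResultError("Kaplan-Meier estimate needs at least one event")
    times = np.unique(d[e])
    n_at = np.array([(d >= t).sum() for t in times], float)
    d_at = np.array([((d == t) & e).sum() for t in times], float)
    surv = np.cumprod(1.0 - d_at / n_at)
    z = norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        # Greenwood cumulative variance term; undefined once S hits 0 or at S == 1
        cum = np.cumsum(d_at / (n_at * (n_at - d_at)))
        v = cum / np.log(surv) ** 2
        c = np.log(-np.log(surv))
        lower = np.exp(-np.exp(c + z * np.sqrt(v)))
        upper = np.exp(-np.exp(c - z * np.sqrt(v)))
    lower = np.where(surv <= 0.0, 0.0, lower)
    upper = np.where(surv <= 0.0, 0.0, upper)
    lower = np.where(surv >= 1.0, 1.0, lower)
    upper = np.where(surv >= 1.0, 1.0, upper)
    return times, surv, lower, upper


def _first_crossing(times: np.ndarray, values: np.ndarray, q: float = 0.5) -> float:
    # epsilon guards against cumprod round-off at exact ties (e.g. S == 0.5
    # with an even, uncensored sample)
    idx = np.flatnonzero(values <= q + 1e-12)
    return float(times[idx[0]]) if idx.size else float("inf")


def km_backward_onset(
    cohort: Cohort,
    predictor: str,
    include_nonexhibitors: bool = False,
    alpha: float = 0.05,
) -> KmEstimate:
    """Median days between first appearance and death, estimated by
    Kaplan-Meier on the backward times u = (T_death - t_event) / 24.

    By default only exhibitors enter (all uncensored); with
    `include_nonexhibitors`, non-exhibiting decedents enter censored at
    their full backward observation span.
    """
    deaths = _death_times(cohort)
    events = predictor_event_times(cohort, predictor)
    durations, flags = [], []
    for pid, t_death in deaths.items():
        if pid in events:
            durations.append((t_death - events[pid]) / 24.0)
            flags.append(True)
        elif include_nonexhibitors:
            durations.append((t_death - cohort.patients[pid].obs_start_h) / 24.0)
            flags.append(False)
    if not any(flags):
        raise UndefinedResultError(
            f"no decedent exhibits {predictor!r}; onset estimate is undefined"
        )
    dur = np.asarray(durations, float)
    ev = np.asarray(flags, bool)
    times, surv, lower, upper = km_curve(dur, ev, alpha=alpha)
    return KmEstimate(
        median_days=_first_crossing(times, surv),
        ci_low=_first_crossing(times, lower),
        ci_high=_first_crossing(times, upper),
        n=int(dur.size),
        n_events=int(ev.sum()),
    )


# -- Table-3-shaped summary ------------------------------------------------


@dataclass(frozen=True)
class SignSummary:
    predictor: str
    n_within_72h: int
    prevalence_within_72h: float
    mortality_72h: tuple[int, int, float] | None
    mortality_24h: tuple[int, int, float] | None
    km: KmEstimate | None


def summarize_signs(cohort: Cohort, include_si: bool = False) -> list[SignSummary]:
    """Prevalence / onset / mortality rows for each catalog sign.

    Signs with zero exhibitors (e.g. apnea in the source cohort) get None
    for onset and mortality rather than zero proportions.
    """
    from .catalog import HORIZON_24H, HORIZON_72H

    predictors = PREDICTOR_IDS if include_si else SIGN_IDS
    out = []
    for p in predictors:
        n72, prev = prevalence_within_window(cohort, p, 72.0)
        try:
            m72 = mortality_after_onset(cohort, p, HORIZON_72H)
            m24 = mortality_after_onset(cohort, p, HORIZON_24H)
            km = km_backward_onset(cohort, p)
        except UndefinedResultError:
            m72 = m24 = km = None
        out.append(SignSummary(p, n72, prev, m72, m24, km))
    return out


def summary_frame(summaries: list[SignSummary]) -> pd.DataFrame:
    """Flatten summaries to the export CSV layout."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "sign": s.predictor,
                "km_median_days": np.nan if s.km is None else s.km.median_days,
                "ci_low": np.nan if s.km is None else s.km.ci_low,
                "ci_high": np.nan if s.km is None else s.km.ci_high,
                "n_within72h": s.n_within_72h,
                "prevalence_pct": round(100.0 * s.prevalence_within_72h, 1),
                "mort72_num": np.nan if s.mortality_72h is None else s.mortality_72h[0],
                "mort72_den": np.nan if s.mortality_72h is None else s.mortality_72h[1],
                "mort72_pct": np.nan if s.mortality_72h is None else round(100.0 * s.mortality_72h[2], 1),
                "mort24_num": np.nan if s.mortality_24h is None else s.mortality_24h[0],
                "mort24_den": np.nan if s.mortality_24h is None else s.mortality_24h[1],
                "mort24_pct": np.nan if s.mortality_24h is None else round(100.0 * s.mortality_24h[2], 1),
            }
        )
    return pd.DataFrame(rows)
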