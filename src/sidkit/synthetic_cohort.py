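"""Seeded generator of dying-phase cohorts.

Each decedent gets an observation span drawn from a lognormal, 12-hourly
assessments up to and including the death instant, per-sign Bernoulli
occurrence with an onset lead drawn backward from death, persistent sign
flags after onset, and vitals that drift from a patient-level baseline over
the final hours so that the shock index typically crosses 1.0 near death.

Signs are marginally calibrated; they correlate only through the shared
death-time anchoring (no explicit sign-sign copula).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .catalog import SIGN_IDS
from .core_cohort import CENSOR_REASONS, Cohort, OBSERVATION_COLUMNS, Patient
from .datasets import load_table3_counts

__all__ = [
    "SignModel",
    "VitalModel",
    "GeneratorConfig",
    "generate",
    "default_config_from_table3",
    "calibration_report",
]


@dataclass(frozen=True)
class SignModel:
    """Marginal model of one sign: occurrence probability and onset lead
    (days before death) with the given median."""

    probability: float
    median_lead_days: float = 1.0
    family: str = "exponential"  # or "lognormal"
    lognormal_sigma: float = 0.6

    def validate(self, name: str) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"{name}.probability must be in [0, 1], got {self.probability}")
        if self.median_lead_days <= 0:
            raise ValueError(f"{name}.median_lead_days must be > 0, got {self.median_lead_days}")
        if self.family not in ("exponential", "lognormal"):
            raise ValueError(f"{name}.family must be 'exponential' or 'lognormal'")

    def sample_leads(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Onset leads in days; parameterised by the median."""
        if self.family == "exponential":
            scale = self.median_lead_days / math.log(2.0)
            return rng.exponential(scale, n)
        mu = math.log(self.median_lead_days)
        return rng.lognormal(mu, self.lognormal_sigma, n)


@dataclass(frozen=True)
class VitalModel:
    """Baseline + terminal linear drift + Gaussian noise for one vital."""

    baseline_mean: float
    baseline_sd: float
    terminal_shift: float  # signed change reached at the death instant
    noise_sd: float
    drift_window_h: float = 72.0
    clip_low: float = -np.inf
    clip_high: float = np.inf

    def validate(self, name: str) -> None:
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ValueError(f"{name}: standard deviations must be >= 0")
        if self.drift_window_h <= 0:
            raise ValueError(f"{name}.drift_window_h must be > 0")

    def values(
        self, offsets_h: np.ndarray, baseline: float, rng: np.random.Generator
    ) -> np.ndarray:
        frac = np.clip(1.0 - offsets_h / self.drift_window_h, 0.0, 1.0)
        v = baseline + self.terminal_shift * frac + rng.normal(0.0, self.noise_sd, offsets_h.size)
        return np.clip(v, self.clip_low, self.clip_high)


def _default_vitals() -> dict[str, VitalModel]:
    return {
        "sbp": VitalModel(118.0, 12.0, -35.0, 6.0, clip_low=40.0, clip_high=220.0),
        "dbp": VitalModel(68.0, 8.0, -18.0, 5.0, clip_low=20.0, clip_high=140.0),
        "hr": VitalModel(88.0, 10.0, +32.0, 5.0, clip_low=20.0, clip_high=190.0),
        "temp": VitalModel(36.7, 0.4, +0.6, 0.3, clip_low=33.0, clip_high=42.0),
        "rr": VitalModel(18.0, 3.0, +8.0, 2.5, clip_low=4.0, clip_high=60.0),
        "spo2": VitalModel(95.0, 2.0, -6.0, 2.0, clip_low=50.0, clip_high=100.0),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 50
    seed: int = 0
    signs: dict[str, SignModel] = field(default_factory=dict)
    obs_interval_h: float = 12.0
    jitter_h: float = 0.0
    span_mean_days: float = 14.1
    span_lognormal_sigma: float = 0.8
    span_min_days: float = 1.0
    vitals: dict[str, VitalModel] = field(default_factory=_default_vitals)
    survivor_fraction: float = 0.0
    survivor_sign_factor: float = 0.2
    censor_reason_mix: dict[str, float] = field(
        default_factory=lambda: {"ate_gt_half_2d": 0.5, "discharged": 0.3, "60_days_elapsed": 0.2}
    )
    missing_sign_prob: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.obs_interval_h <= 0:
            raise ValueError(f"obs_interval_h must be > 0, got {self.obs_interval_h}")
        if self.span_mean_days <= 0:
            raise ValueError(f"span_mean_days must be > 0, got {self.span_mean_days}")
        if self.span_min_days <= 0:
            raise ValueError(f"span_min_days must be > 0, got {self.span_min_days}")
        if not 0.0 <= self.survivor_fraction < 1.0:
            raise ValueError(f"survivor_fraction must be in [0, 1), got {self.survivor_fraction}")
        if not 0.0 <= self.missing_sign_prob < 1.0:
            raise ValueError(f"missing_sign_prob must be in [0, 1), got {self.missing_sign_prob}")
        unknown = set(self.signs) - set(SIGN_IDS)
        if unknown:
            raise ValueError(f"unknown sign id(s) in config: {sorted(unknown)}")
        for name, sm in self.signs.items():
            sm.validate(f"signs[{name}]")
        for name, vm in self.vitals.items():
            vm.validate(f"vitals[{name}]")
        for reason in self.censor_reason_mix:
            if reason not in CENSOR_REASONS:
                raise ValueError(f"unknown censor reason {reason!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def default_config_from_table3(n_patients: int = 50, seed: int = 0) -> GeneratorConfig:
    """Config whose per-sign occurrence probabilities and median onset
    leads match the packaged per-sign count table (occurrence 0 for the
    never-observed sign)."""
    counts = load_table3_counts()
    n = counts["n_decedents"]
    signs = {}
    for sid in SIGN_IDS:
        row = counts["signs"][sid]
        prob = row["n_within_72h"] / n
        median = row["median_onset_days"]
        signs[sid] = SignModel(
            probability=prob,
            median_lead_days=1.0 if median is None else float(median),
        )
    return GeneratorConfig(n_patients=n_patients, seed=seed, signs=signs)


def _obs_times(span_h: float, interval_h: float, jitter_h: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(0.0, span_h, interval_h)
    if jitter_h > 0:
        t = t + rng.uniform(-jitter_h, jitter_h, t.size)
        t = np.clip(t, 0.0, span_h)
    t = np.unique(np.append(t, span_h))  # always observe the terminal instant
    return t[(t >= 0.0) & (t <= span_h)]


def generate(config: GeneratorConfig) -> Cohort:
    """Draw a cohort from the configured generative model (deterministic in
    the config seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_survivors = int(round(n * config.survivor_fraction))
    reasons = list(config.censor_reason_mix) or ["discharged"]
    weights = np.array([config.censor_reason_mix.get(r, 1.0) for r in reasons], float)
    weights = weights / weights.sum()

    mu = math.log(config.span_mean_days) - config.span_lognormal_sigma**2 / 2.0
    patients: list[Patient] = []
    frames: list[pd.DataFrame] = []
    for i in range(n):
        pid = f"p{i:04d}"
        is_survivor = i >= n - n_survivors
        span_days = max(config.span_min_days, rng.lognormal(mu, config.span_lognormal_sigma))
        span_h = span_days * 24.0
        times = _obs_times(span_h, config.obs_interval_h, config.jitter_h, rng)
        offsets = span_h - times  # hours before the terminal instant
        frame = pd.DataFrame({"patient_id": pid, "time_h": times})
        sign_factor = config.survivor_sign_factor if is_survivor else 1.0
        for sid in SIGN_IDS:
            sm = config.signs.get(sid, SignModel(probability=0.0))
            col = np.zeros(times.size)
            if rng.random() < sm.probability * sign_factor:
                if is_survivor:
                    onset = rng.uniform(0.0, span_h)
                else:
                    lead_h = sm.sample_leads(1, rng)[0] * 24.0
                    onset = max(span_h - lead_h, 0.0)
                col[times >= onset] = 1.0
            if config.missing_sign_prob > 0:
                miss = rng.random(times.size) < config.missing_sign_prob
                col = np.where(miss, np.nan, col)
            frame[sid] = col
        for name, vm in config.vitals.items():
            baseline = rng.normal(vm.baseline_mean, vm.baseline_sd)
            drift_off = offsets if not is_survivor else np.full_like(offsets, np.inf)
            frame[name] = vm.values(drift_off, baseline, rng)
        frames.append(frame)
        if is_survivor:
            reason = str(rng.choice(reasons, p=weights))
            patients.append(
                Patient(pid, age=float(np.round(rng.normal(85.8, 8.2), 1)), sex=str(rng.choice(["f", "m"], p=[0.77, 0.23])),
                        diagnosis="respiratory", obs_start_h=0.0, terminal_h=span_h,
                        died=False, censor_reason=reason)
            )
        else:
            patients.append(
                Patient(pid, age=float(np.round(rng.normal(85.8, 8.2), 1)), sex=str(rng.choice(["f", "m"], p=[0.77, 0.23])),
                        diagnosis="respiratory", obs_start_h=0.0, terminal_h=span_h,
                        died=True)
            )
    if frames:
        obs = pd.concat(frames, ignore_index=True)
        obs = obs.reindex(columns=list(OBSERVATION_COLUMNS))
    else:
        obs = pd.DataFrame(columns=OBSERVATION_COLUMNS)
    return Cohort(patients, obs)


def calibration_report(
    cohort: Cohort,
    config: GeneratorConfig,
    prob_tol: float | None = None,
    onset_tol_days: float | None = None,
) -> pd.DataFrame:
    """Compare empirical per-sign occurrence and median onset lead against
    the configured targets.

    Default tolerances scale with the cohort size (binomial / order-statistic
    concentration); pass explicit values to pin them.
    """
    from .core_cohort import first_event_times

    deaths = {pid: p.terminal_h for pid, p in cohort.patients.items() if p.died}
    n = max(len(deaths), 1)
    rows = []
    for sid in SIGN_IDS:
        sm = config.signs.get(sid, SignModel(probability=0.0))
        events = {
            pid: t for pid, t in first_event_times(cohort, sid).items() if pid in deaths
        }
        emp_prob = len(events) / n
        p = sm.probability
        ptol = prob_tol if prob_tol is not None else max(0.02, 4.0 * math.sqrt(p * (1 - p) / n))
        leads = np.array([(deaths[pid] - t) / 24.0 for pid, t in events.items()])
        emp_median = float(np.median(leads)) if leads.size else np.nan
        otol = (
            onset_tol_days
            if onset_tol_days is not None
            else max(0.5, 3.0 * sm.median_lead_days / math.sqrt(max(leads.size, 1)))
        )
        onset_ok = True if p == 0.0 or not leads.size else abs(emp_median - sm.median_lead_days) <= otol
        rows.append(
            {
                "sign": sid,
                "target_probability": p,
                "empirical_probability": emp_prob,
                "probability_tol": ptol,
                "probability_ok": abs(emp_prob - p) <= ptol,
                "target_median_days": sm.median_lead_days,
                "empirical_median_days": emp_median,
                "onset_tol_days": otol,
                "onset_ok": onset_ok,
            }
        )
    return pd.DataFrame(rows)
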