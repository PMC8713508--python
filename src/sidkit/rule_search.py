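"""OR-rule prediction probability, exhaustive best-subset search, and k-fold CV.

The rule fires at the EARLIEST first-event time among the subset's member
predictors.  A decedent counts as a success when at least one member occurs
and death follows within the horizon of that earliest event; equivalently,
every occurring member must have occurred within the horizon of death.  The
probability denominator is all decedents (patients without any member event,
or whose earliest event lies beyond the horizon, are failures).

The search over subsets of size m is exhaustive across all C(12, m)
combinations; ties are broken toward the lexicographically smallest tuple of
catalog indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .catalog import PREDICTOR_IDS, PREDICTOR_INDEX, Horizon
from .core_cohort import Cohort, UndefinedResultError
from .sign_statistics import predictor_event_times

__all__ = [
    "RuleSubset",
    "EvaluationResult",
    "FoldResult",
    "CvResult",
    "event_lead_matrix",
    "rule_event_time",
    "prediction_probability",
    "best_subset",
    "best_subsets",
    "cv_probability",
    "model_table",
]

logger = logging.getLogger(__name__)


def _as_subset(subset) -> tuple[str, ...]:
    """Normalise to a catalog-ordered tuple of predictor ids; validate."""
    members = tuple(subset)
    if not members:
        raise ValueError("rule subset must be non-empty")
    unknown = [p for p in members if p not in PREDICTOR_INDEX]
    if unknown:
        raise KeyError(f"unknown predictor(s): {unknown}")
    if len(set(members)) != len(members):
        raise ValueError(f"duplicate predictors in subset: {members}")
    return tuple(sorted(members, key=PREDICTOR_INDEX.__getitem__))


RuleSubset = tuple  # alias for readability in signatures


@dataclass(frozen=True)
class EvaluationResult:
    """Raw (training) prediction probability of one subset at one horizon."""

    subset: tuple[str, ...]
    horizon: Horizon
    prob_raw: float
    outcomes: pd.DataFrame = field(repr=False)  # patient_id, rule_event_h, success


@dataclass(frozen=True)
class FoldResult:
    fold: int
    subset: tuple[str, ...]
    heldout_successes: int
    heldout_n: int
    heldout_ids: tuple[str, ...]


@dataclass(frozen=True)
class CvResult:
    m: int
    horizon: Horizon
    k: int
    seed: int
    prob_cv: float
    folds: tuple[FoldResult, ...]


def _decedent_cohort(cohort: Cohort) -> Cohort:
    n_censored = len(cohort) - len(cohort.decedent_ids)
    if n_censored:
        logger.warning(
            "excluding %d censored patient(s); rule statistics are over decedents",
            n_censored,
        )
        cohort = cohort.decedents_only()
    if len(cohort) == 0:
        raise UndefinedResultError("no decedents in cohort")
    return cohort


def event_lead_matrix(cohort: Cohort) -> pd.DataFrame:
    """Decedents x 12 predictors matrix of leads (hours before death) of the
    first event; NaN where the predictor never occurs.  Censored patients
    are excluded (with a warning)."""
    cohort = _decedent_cohort(cohort)
    pids = cohort.decedent_ids
    deaths = np.array([cohort.patients[pid].terminal_h for pid in pids])
    mat = np.full((len(pids), len(PREDICTOR_IDS)), np.nan)
    pos = {pid: i for i, pid in enumerate(pids)}
    for j, pred in enumerate(PREDICTOR_IDS):
        for pid, t in predictor_event_times(cohort, pred).items():
            i = pos[pid]
            mat[i, j] = deaths[i] - t
    return pd.DataFrame(mat, index=pids, columns=list(PREDICTOR_IDS))


def rule_event_time(cohort: Cohort, patient_id: str, subset) -> float | None:
    """Earliest first-event time among the subset members; None if none occurs."""
    if patient_id not in cohort.patients:
        raise KeyError(f"unknown patient {patient_id}")
    members = _as_subset(subset)
    times = [
        t
        for p in members
        if (t := predictor_event_times(cohort, p).get(patient_id)) is not None
    ]
    return min(times) if times else None


def _subset_successes(leads: np.ndarray, cols: tuple[int, ...], horizon_h: float) -> np.ndarray:
    """Vectorised success flags for one subset given the lead matrix."""
    sub = leads[:, cols]
    occurred = ~np.isnan(sub)
    # earliest event = largest lead; success iff some member occurs and no
    # occurring member leads by more than the horizon
    too_early = occurred & (sub > horizon_h)
    return occurred.any(axis=1) & ~too_early.any(axis=1)


def prediction_probability(
    cohort: Cohort, subset, horizon: Horizon, leads: pd.DataFrame | None = None
) -> EvaluationResult:
    """Proportion of decedents for whom the OR-rule fires within the horizon
    of death (inclusive boundary)."""
    members = _as_subset(subset)
    if leads is None:
        leads = event_lead_matrix(cohort)
    mat = leads.to_numpy(float)
    cols = tuple(PREDICTOR_INDEX[p] for p in members)
    success = _subset_successes(mat, cols, horizon.hours)
    sub = mat[:, cols]
    with np.errstate(invalid="ignore"):
        max_lead = np.nanmax(np.where(np.isnan(sub), -np.inf, sub), axis=1)
    deaths = np.array([cohort.patients[pid].terminal_h for pid in leads.index])
    rule_time = np.where(np.isinf(max_lead), np.nan, deaths - max_lead)
    outcomes = pd.DataFrame(
        {
            "patient_id": leads.index,
            "rule_event_h": rule_time,
            "success": success,
        }
    ).reset_index(drop=True)
    return EvaluationResult(members, horizon, float(success.mean()), outcomes)


def _search(mat: np.ndarray, m: int, horizon_h: float) -> tuple[tuple[int, ...], float, list[tuple[int, ...]]]:
    """Exhaustive search over all C(12, m) column subsets.

    Returns (argmax columns, best probability, all tied argmaxes).  The
    first combination in lexicographic order wins ties.
    """
    n = mat.shape[0]
    best_cols: tuple[int, ...] | None = None
    best_hits = -1
    ties: list[tuple[int, ...]] = []
    for cols in combinations(range(len(PREDICTOR_IDS)), m):
        hits = int(_subset_successes(mat, cols, horizon_h).sum())
        if hits > best_hits:
            best_hits, best_cols, ties = hits, cols, [cols]
        elif hits == best_hits:
            ties.append(cols)
    assert best_cols is not None
    return best_cols, best_hits / n, ties


def best_subset(
    cohort: Cohort, m: int, horizon: Horizon, leads: pd.DataFrame | None = None
) -> tuple[tuple[str, ...], EvaluationResult]:
    """Argmax of prediction_probability over all C(12, m) subsets."""
    if not 1 <= m <= len(PREDICTOR_IDS):
        raise ValueError(f"m must be in 1..{len(PREDICTOR_IDS)}, got {m}")
    if leads is None:
        leads = event_lead_matrix(cohort)
    cols, _, _ = _search(leads.to_numpy(float), m, horizon.hours)
    subset = tuple(PREDICTOR_IDS[j] for j in cols)
    return subset, prediction_probability(cohort, subset, horizon, leads=leads)


def best_subsets(
    cohort: Cohort, m: int, horizon: Horizon, leads: pd.DataFrame | None = None
) -> list[tuple[str, ...]]:
    """All tied optima, lexicographically ordered by catalog indices."""
    if not 1 <= m <= len(PREDICTOR_IDS):
        raise ValueError(f"m must be in 1..{len(PREDICTOR_IDS)}, got {m}")
    if leads is None:
        leads = event_lead_matrix(cohort)
    _, _, ties = _search(leads.to_numpy(float), m, horizon.hours)
    return [tuple(PREDICTOR_IDS[j] for j in cols) for cols in ties]


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def cv_probability(
    cohort: Cohort,
    m: int,
    horizon: Horizon,
    k: int = 10,
    seed: int = 0,
    refit_per_fold: bool = True,
    pooled: bool = True,
) -> CvResult:
    """k-fold cross-validated prediction probability.

    Decedents are split into k near-equal folds by a seeded random
    permutation.  For each fold the subset is re-searched on the other
    k - 1 folds (default) or the full-data best subset is re-scored
    (`refit_per_fold=False`); held-out successes are pooled over folds
    (micro-average, default) or fold-averaged (`pooled=False`).
    """
    leads = event_lead_matrix(cohort)
    mat = leads.to_numpy(float)
    n = mat.shape[0]
    if n < k:
        raise ValueError(f"cohort has {n} decedents, fewer than k={k} folds")
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, k, rng)
    full_cols, _, _ = _search(mat, m, horizon.hours)
    results = []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if refit_per_fold:
            cols, _, _ = _search(mat[train_mask], m, horizon.hours)
        else:
            cols = full_cols
        hits = int(_subset_successes(mat[test_idx], cols, horizon.hours).sum())
        results.append(
            FoldResult(
                fold=f,
                subset=tuple(PREDICTOR_IDS[j] for j in cols),
                heldout_successes=hits,
                heldout_n=int(test_idx.size),
                heldout_ids=tuple(leads.index[i] for i in test_idx),
            )
        )
    if pooled:
        prob = sum(r.heldout_successes for r in results) / n
    else:
        prob = float(np.mean([r.heldout_successes / r.heldout_n for r in results]))
    return CvResult(m=m, horizon=horizon, k=k, seed=seed, prob_cv=prob, folds=tuple(results))


def model_table(
    cohort: Cohort,
    horizon: Horizon,
    m_values=range(1, 13),
    k: int = 10,
    seed: int = 0,
    refit_per_fold: bool = True,
) -> pd.DataFrame:
    """One row per m: member indicators (catalog order), raw and CV accuracy."""
    leads = event_lead_matrix(cohort)
    dec = cohort.decedents_only()
    rows = []
    for m in m_values:
        subset, ev = best_subset(dec, m, horizon, leads=leads)
        cv = cv_probability(dec, m, horizon, k=k, seed=seed, refit_per_fold=refit_per_fold)
        row: dict[str, object] = {"horizon": horizon.label, "m": m}
        for p in PREDICTOR_IDS:
            row[p] = int(p in subset)
        row["prob_raw"] = ev.prob_raw
        row["prob_cv"] = cv.prob_cv
        row["prob_raw_pct"] = round(100.0 * ev.prob_raw, 1)
        row["prob_cv_pct"] = round(100.0 * cv.prob_cv, 1)
        row["seed"] = seed
        row["k"] = k
        rows.append(row)
    return pd.DataFrame(rows)
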