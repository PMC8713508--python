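"""Independent brute-force oracle for the OR-rule statistics.

Deliberately written against the public per-observation iteration only, in
plain Python, so it shares no code path with the vectorised implementation.
"""

from itertools import combinations

from sidkit.catalog import PREDICTOR_IDS, SI_PREDICTOR


def naive_event_times(cohort) -> dict[str, dict[str, float]]:
    """events[pid][predictor] = first positive time, by linear scan."""
    events: dict[str, dict[str, float]] = {}
    for pid in cohort.patient_ids:
        per: dict[str, float] = {}
        for obs in cohort.iter_observations(pid):
            for sign, flag in obs.signs.items():
                if flag is True and sign not in per:
                    per[sign] = obs.time_h
            if (
                SI_PREDICTOR not in per
                and obs.hr is not None
                and obs.sbp is not None
                and obs.hr / obs.sbp > 1.0
            ):
                per[SI_PREDICTOR] = obs.time_h
        events[pid] = per
    return events


def naive_prediction_prob(cohort, events, subset, horizon_h) -> float:
    successes = 0
    decedents = [pid for pid in cohort.patient_ids if cohort.patients[pid].died]
    for pid in decedents:
        times = [events[pid][p] for p in subset if p in events[pid]]
        if not times:
            continue
        rule_time = min(times)
        if cohort.patients[pid].terminal_h - rule_time <= horizon_h:
            successes += 1
    return successes / len(decedents)


def naive_best_subset(cohort, events, m, horizon_h):
    """First-in-lexicographic-order argmax over all C(12, m) subsets."""
    best, best_prob = None, -1.0
    for subset in combinations(PREDICTOR_IDS, m):
        prob = naive_prediction_prob(cohort, events, subset, horizon_h)
        if prob > best_prob:
            best, best_prob = subset, prob
    return best, best_prob
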