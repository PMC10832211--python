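"""The three evaluation protocols and RMSE summarisation.

* Visit-dropping imputation study: subjects with complete scheduled visits are
  refitted with every combination of dropped visits; the refit is scored
  against ALL of the subject's visit measurements (including the dropped
  ones), so an essential visit shows up as an RMSE increase over baseline.
* Single-point holdout comparison: one random non-birth measurement per
  subject is removed; each registered method predicts it from the rest.
  Holdout choices depend only on (cohort, seed), never on the method list.
* Last-value prediction: the curve is fitted to year 1 (or years 1-2) only
  and scored on the later, unseen years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (GrowthSeries, VisitSchedule, WELL_BABY_SCHEDULE,
                     assign_visits, has_complete_visits)
from .interpolate import get_interpolator
from .model import FitControl, MichaelisMentenModel, mm_value, rescue_start, rmse

log = logging.getLogger(__name__)

__all__ = [
    "RmseSummary",
    "ImputationResult",
    "PredictionResult",
    "summarize_rmse",
    "imputation_experiment",
    "holdout_experiment",
    "prediction_experiment",
    "c1_birth_correlation",
    "YEAR_WINDOWS",
]

#: Closed day-intervals for the fit/evaluation year windows.
YEAR_WINDOWS = {"Y1": (0, 365), "Y2": (366, 730), "Y3": (731, 1125)}


@dataclass(frozen=True)
class RmseSummary:
    """Distributional summary of per-subject RMSE values (kg or cm).

    Quantiles use linear interpolation between order statistics; sd uses the
    n-1 denominator.
    """

    mean: float
    sd: float
    median: float
    iqr: float
    p90: float
    min: float
    max: float
    n_subjects: int
    n_failures: int = 0

    def row(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "median": self.median,
                "iqr": self.iqr, "p90": self.p90, "min": self.min, "max": self.max,
                "n_subjects": self.n_subjects, "n_failures": self.n_failures}


def summarize_rmse(values: Sequence[float], n_failures: int = 0) -> RmseSummary:
    """Summarise a non-empty list of per-subject RMSEs."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty RMSE list")
    q25, q50, q75, q90 = np.percentile(v, [25, 50, 75, 90])
    return RmseSummary(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        median=float(q50),
        iqr=float(q75 - q25),
        p90=float(q90),
        min=float(v.min()),
        max=float(v.max()),
        n_subjects=int(v.size),
        n_failures=n_failures,
    )


@dataclass(frozen=True)
class ImputationResult:
    """Effect of dropping one combination of visits, averaged over subjects."""

    dropped_visits: tuple[int, ...]
    delta_rmse: float      # mean over subjects of (refit RMSE - baseline RMSE)
    n_failures: int        # refits that failed for this combination
    n_subjects: int        # subjects contributing to delta_rmse
    degenerate: bool = False  # fewer than 3 points would remain


def _fit_points(ages, values, measure, control, rescue):
    model = MichaelisMentenModel(values, ages, measure=measure)
    res = model.fit(control=control)
    if not res.converged and rescue:
        res = model.fit(start=rescue_start(measure), control=control)
    return res


def imputation_experiment(cohort: Iterable[GrowthSeries],
                          schedule: VisitSchedule = WELL_BABY_SCHEDULE,
                          subset: int = 12, max_drop: int = 5,
                          control: FitControl | None = None,
                          rescue_on_failure: bool = False) -> list[ImputationResult]:
    """Drop every combination of 1..max_drop visits and measure the RMSE cost.

    ``subset`` is 7 (year-1 visits) or 12 (all visits); only subjects with a
    measurement at every one of those visits enter.  Each subject's analysis
    set is its per-visit chosen measurement.  The refit after dropping is
    scored against all ``subset`` visit values; ``delta_rmse`` is the mean
    change versus the subject's own all-visit baseline.  The empty combination
    is included and is exactly zero.  Combinations leaving fewer than 3 points
    are reported as degenerate and not fitted.
    """
    if subset not in (7, 12):
        raise ValueError("subset must be 7 or 12")

    subjects = []  # (visit -> measurement, baseline_rmse, measure)
    for series in cohort:
        assignment = assign_visits(series, schedule)
        if not has_complete_visits(assignment, subset):
            continue
        visits = {v: assignment[v] for v in range(1, subset + 1)}
        ages = np.array([visits[v].age_days for v in sorted(visits)], dtype=float)
        values = np.array([visits[v].value for v in sorted(visits)], dtype=float)
        base = _fit_points(ages, values, series.measure, control, rescue_on_failure)
        if not base.converged:
            log.warning("baseline fit failed for %s (%s)", series.subject_id, base.status)
            continue
        subjects.append((visits, base.rmse, series.measure, ages, values))

    results = [ImputationResult((), 0.0, 0, len(subjects))]
    visit_ids = range(1, subset + 1)
    combos = [c for size in range(1, max_drop + 1) for c in combinations(visit_ids, size)]
    for combo in combos:
        if subset - len(combo) < 3:
            results.append(ImputationResult(combo, float("nan"), 0, 0, degenerate=True))
            continue
        deltas, failures = [], 0
        for visits, base_rmse, measure, all_ages, all_values in subjects:
            keep = [v for v in visits if v not in combo]
            ages = np.array([visits[v].age_days for v in keep], dtype=float)
            values = np.array([visits[v].value for v in keep], dtype=float)
            try:
                res = _fit_points(ages, values, measure, control, rescue_on_failure)
            except ValueError:  # < 3 distinct ages after dropping duplicates
                failures += 1
                continue
            if not res.converged:
                failures += 1
                continue
            full_rmse = rmse(all_values - mm_value(res.params, all_ages))
            deltas.append(full_rmse - base_rmse)
        results.append(ImputationResult(
            combo, float(np.mean(deltas)) if deltas else float("nan"),
            failures, len(deltas)))
    return results


def select_holdouts(cohort: Sequence[GrowthSeries], seed: int) -> dict[str, int]:
    """Choose one random non-birth measurement index per subject.

    Per-subject streams are spawned from the seed by subject position, so the
    choice for subject i never depends on the number of other subjects, the
    method list, or evaluation order.  Subjects with fewer than two non-birth
    measurements are skipped.
    """
    holdouts: dict[str, int] = {}
    for i, series in enumerate(cohort):
        candidates = [j for j, m in enumerate(series.measurements) if m.age_days > 1]
        if len(candidates) < 2:
            continue
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        holdouts[series.subject_id] = candidates[int(rng.integers(len(candidates)))]
    return holdouts


def holdout_experiment(cohort: Sequence[GrowthSeries], methods: Sequence[str | Callable],
                       seed: int = 1234, measure: str | None = None,
                       ) -> tuple[dict[str, RmseSummary], pd.DataFrame]:
    """Score interpolation methods on one random held-out point per subject.

    Returns per-method summaries of the per-subject absolute holdout errors
    (a one-point RMSE is the absolute error) and a per-subject detail table.
    Subjects on which any method errors (e.g. the growth fit diverges) are
    dropped from every method and counted as failures, keeping the comparison
    paired.
    """
    if not methods:
        raise ValueError("need at least one method")
    kind = measure or (cohort[0].measure if cohort else "weight")
    resolved: dict[str, Callable] = {}
    for m in methods:
        if callable(m):
            resolved[getattr(m, "__name__", str(m))] = m
        else:
            resolved[m] = get_interpolator(m, measure=kind)

    holdouts = select_holdouts(cohort, seed)
    per_method: dict[str, list[float]] = {name: [] for name in resolved}
    rows, n_failures = [], 0
    for series in cohort:
        if series.subject_id not in holdouts:
            continue
        j = holdouts[series.subject_id]
        held = series.measurements[j]
        ages = np.delete(series.ages, j)
        values = np.delete(series.values, j)
        preds = {}
        try:
            for name, func in resolved.items():
                preds[name] = func(ages, values, float(held.age_days))
        except (RuntimeError, ValueError) as exc:
            n_failures += 1
            log.warning("subject %s dropped from holdout: %s", series.subject_id, exc)
            continue
        for name, pred in preds.items():
            err = abs(pred - held.value)
            per_method[name].append(err)
            rows.append({"subject_id": series.subject_id, "method": name,
                         "holdout_age": held.age_days, "observed": held.value,
                         "predicted": pred, "abs_error": err})

    summaries = {name: summarize_rmse(errs, n_failures=n_failures)
                 for name, errs in per_method.items() if errs}
    return summaries, pd.DataFrame(rows)


@dataclass(frozen=True)
class PredictionResult:
    """Per-subject RMSE of one fit-window / evaluation-window pair."""

    subject_id: str
    fit_window: str    # "Y1", "Y1+Y2" or "Y1-3"
    eval_window: str   # "Y3", "Y2-3" or "Y1-3"
    rmse: float
    n_eval_points: int


def _window_mask(ages: np.ndarray, window: str) -> np.ndarray:
    parts = {"Y1": ("Y1",), "Y2": ("Y2",), "Y3": ("Y3",),
             "Y1+Y2": ("Y1", "Y2"), "Y1-2": ("Y1", "Y2"),
             "Y2-3": ("Y2", "Y3"), "Y1-3": ("Y1", "Y2", "Y3")}[window]
    mask = np.zeros(ages.shape, dtype=bool)
    for p in parts:
        lo, hi = YEAR_WINDOWS[p]
        mask |= (ages >= lo) & (ages <= hi)
    return mask


def _eligible(ages: np.ndarray) -> bool:
    counts = {w: int(_window_mask(ages, w).sum()) for w in ("Y1", "Y2", "Y3")}
    return counts["Y1"] >= 5 and counts["Y2"] >= 2 and counts["Y3"] >= 2


def prediction_experiment(cohort: Iterable[GrowthSeries], fit_window: str = "Y1+Y2",
                          control: FitControl | None = None,
                          rescue_on_failure: bool = False,
                          ) -> tuple[list[PredictionResult], int, int]:
    """Last-value prediction: fit early windows, score the later unseen ones.

    Eligibility requires >= 5 points in year 1 and >= 2 in each of years 2
    and 3.  ``fit_window`` "Y1" is scored on Y2-3, "Y1+Y2" on Y3, and the
    baseline "Y1-3" on Y1-3, Y3 and Y2-3 (one result row per pair).  Returns
    (results, n_fit_failures, n_ineligible); RMSE is evaluated at the
    subject's actual measurement ages in the evaluation window.
    """
    if fit_window not in ("Y1", "Y1+Y2", "Y1-3"):
        raise ValueError("fit_window must be one of 'Y1', 'Y1+Y2', 'Y1-3'")
    eval_windows = {"Y1": ["Y2-3"], "Y1+Y2": ["Y3"], "Y1-3": ["Y1-3", "Y3", "Y2-3"]}[fit_window]

    results, n_failures, n_ineligible = [], 0, 0
    for series in cohort:
        ages, values = series.ages, series.values
        if not _eligible(ages):
            n_ineligible += 1
            continue
        fit_mask = _window_mask(ages, fit_window)
        try:
            res = _fit_points(ages[fit_mask], values[fit_mask], series.measure,
                              control, rescue_on_failure)
        except ValueError:
            n_failures += 1
            continue
        if not res.converged:
            n_failures += 1
            continue
        for ew in eval_windows:
            em = _window_mask(ages, ew)
            err = values[em] - mm_value(res.params, ages[em])
            results.append(PredictionResult(series.subject_id, fit_window, ew,
                                            rmse(err), int(em.sum())))
    return results, n_failures, n_ineligible


def c1_birth_correlation(c1_values: Sequence[float], birth_values: Sequence[float]) -> float:
    """Spearman rank correlation between fitted c1 and recorded birth size."""
    c1 = np.asarray(c1_values, dtype=float)
    birth = np.asarray(birth_values, dtype=float)
    if c1.size != birth.size:
        raise ValueError("c1 and birth-size vectors must be paired")
    if c1.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(c1) == 0 or np.ptp(birth) == 0:
        raise ValueError("zero variance in c1 or birth size")
    rho = stats.spearmanr(c1, birth).statistic
    return float(rho)
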