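"""Longitudinal cohort data model, cleaning rules and the well-baby schedule.

Measurements are kept internally in kilograms (weight), centimetres (height)
and integer days since birth.  Cleaning implements the protocol rules: values
beyond 1,125 days are dropped; weights between birth and 19 days are dropped
(immediate post-natal weight loss) while the birth record itself (day 0 or 1)
is kept; subjects retaining fewer than five measurements are excluded.  An
automated implausibility screen (height decreases, robust-z outliers) stands
in for manual review and is advisory by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Measurement",
    "GrowthSeries",
    "VisitSchedule",
    "CleaningReport",
    "WELL_BABY_SCHEDULE",
    "lb_to_kg",
    "load_cohort",
    "write_cohort",
    "clean_series",
    "clean_cohort",
    "flag_implausible",
    "assign_visits",
    "has_complete_visits",
]

LB_TO_KG = 0.45359237  # exact, by definition of the avoirdupois pound

MEASURES = ("weight", "height")
UNITS = {"weight": "kg", "height": "cm"}


def lb_to_kg(weight_lb: float) -> float:
    """Convert pounds to kilograms (exact factor 0.45359237)."""
    if weight_lb < 0:
        raise ValueError("weight in pounds must be >= 0")
    return weight_lb * LB_TO_KG


@dataclass(frozen=True)
class Measurement:
    """One observation: age in whole days since birth and a positive size."""

    age_days: int
    value: float
    measure: str = "weight"

    def __post_init__(self):
        if self.age_days < 0:
            raise ValueError("age_days must be >= 0")
        if not self.value > 0:
            raise ValueError("value must be > 0")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure kind: {self.measure!r}")


@dataclass
class GrowthSeries:
    """One child's age-ordered measurement series for one measure kind."""

    subject_id: str
    sex: str
    measure: str
    measurements: list[Measurement]

    def __post_init__(self):
        if any(m.measure != self.measure for m in self.measurements):
            raise ValueError("all measurements must share the series' measure kind")
        self.measurements = sorted(self.measurements, key=lambda m: m.age_days)

    @classmethod
    def from_arrays(cls, subject_id, sex, measure, ages, values) -> "GrowthSeries":
        ms = [Measurement(int(a), float(v), measure) for a, v in zip(ages, values)]
        return cls(str(subject_id), sex, measure, ms)

    @property
    def ages(self) -> np.ndarray:
        return np.array([m.age_days for m in self.measurements], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([m.value for m in self.measurements], dtype=float)

    def __len__(self) -> int:
        return len(self.measurements)


@dataclass(frozen=True)
class VisitSchedule:
    """Ordered, non-overlapping well-baby visit day-windows.

    Each window is (visit_index, min_day, max_day), closed on both ends.
    """

    windows: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        prev_hi = -1
        for idx, lo, hi in self.windows:
            if lo > hi or lo <= prev_hi:
                raise ValueError("visit windows must be increasing and non-overlapping")
            prev_hi = hi

    def __iter__(self):
        return iter(self.windows)

    def __len__(self):
        return len(self.windows)

    def midpoint(self, visit_index: int) -> float:
        for idx, lo, hi in self.windows:
            if idx == visit_index:
                return (lo + hi) / 2
        raise KeyError(visit_index)


#: The 12 recommended well-baby visits, birth to ~36 months.  Visit 1 is
#: day 1 exactly; day-0 birth records are also accepted for visit 1.
WELL_BABY_SCHEDULE = VisitSchedule((
    (1, 1, 1),
    (2, 20, 44),
    (3, 46, 90),
    (4, 95, 148),
    (5, 158, 225),
    (6, 250, 298),
    (7, 310, 399),
    (8, 410, 490),
    (9, 500, 600),
    (10, 640, 800),
    (11, 842, 982),
    (12, 1024, 1125),
))


@dataclass
class CleaningReport:
    """Book-keeping of rows skipped at load time and values dropped per rule.

    For every subject, dropped + retained equals the input count.
    """

    n_rows_input: int = 0
    n_rows_skipped: int = 0
    dropped_age: dict = field(default_factory=dict)
    dropped_neonatal: dict = field(default_factory=dict)
    dropped_implausible: dict = field(default_factory=dict)
    retained: dict = field(default_factory=dict)
    excluded_subjects: list = field(default_factory=list)

    def dropped_total(self, subject_id: str) -> int:
        return (self.dropped_age.get(subject_id, 0)
                + self.dropped_neonatal.get(subject_id, 0)
                + self.dropped_implausible.get(subject_id, 0))


REQUIRED_COLUMNS = ("subject_id", "sex", "age_days", "value")


def load_cohort(path, measure: str | None = None,
                max_bad_fraction: float = 0.5) -> tuple[list[GrowthSeries], CleaningReport]:
    """Read a long-format CSV cohort into per-subject series.

    Expected columns: subject_id, sex, age_days, value, plus optional
    ``measure`` (weight|height; filtered when the ``measure`` argument is
    given) and optional ``unit`` (lb rows are converted to kg).  Rows with
    missing or unparseable required fields are skipped and counted; more than
    ``max_bad_fraction`` bad rows is an error.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    report = CleaningReport(n_rows_input=len(df))

    if measure is not None and "measure" in df.columns:
        df = df[df["measure"] == measure]
    kind = measure or (df["measure"].iloc[0] if "measure" in df.columns and len(df) else "weight")

    age = pd.to_numeric(df["age_days"], errors="coerce")
    val = pd.to_numeric(df["value"], errors="coerce")
    ok = age.notna() & val.notna() & df["subject_id"].notna() & (val > 0) & (age >= 0)
    n_bad = int((~ok).sum())
    report.n_rows_skipped = n_bad
    if len(df) and n_bad / len(df) > max_bad_fraction:
        raise ValueError(f"{n_bad}/{len(df)} rows unparseable (limit {max_bad_fraction:.0%})")
    if n_bad:
        log.warning("skipped %d unparseable rows in %s", n_bad, path)
    df = df[ok].copy()
    df["age_days"] = age[ok].astype(int)
    df["value"] = val[ok]
    if "unit" in df.columns:
        is_lb = df["unit"].astype(str).str.lower().isin(["lb", "lbs", "pound", "pounds"])
        df.loc[is_lb, "value"] = df.loc[is_lb, "value"] * LB_TO_KG

    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        sex = str(grp["sex"].iloc[0])
        out.append(GrowthSeries.from_arrays(sid, sex, kind, grp["age_days"], grp["value"]))
    return out, report


def write_cohort(seriess: Iterable[GrowthSeries], path) -> None:
    """Write series in the same long CSV dialect that load_cohort reads."""
    rows = [
        {"subject_id": s.subject_id, "sex": s.sex, "measure": s.measure,
         "age_days": m.age_days, "value": m.value, "unit": UNITS[s.measure]}
        for s in seriess for m in s.measurements
    ]
    pd.DataFrame(rows, columns=["subject_id", "sex", "measure", "age_days",
                                "value", "unit"]).to_csv(path, index=False, float_format="%.10g")


def clean_series(series: GrowthSeries, max_age: int = 1125, neonatal_low: int = 1,
                 neonatal_high: int = 19, min_obs: int = 5,
                 report: CleaningReport | None = None) -> GrowthSeries | None:
    """Apply the protocol cleaning rules to one series.

    Drops measurements beyond ``max_age`` days; for weight, drops measurements
    in the neonatal window [neonatal_low, neonatal_high] except the birth
    record itself (day <= 1).  Returns ``None`` (exclusion, not an error) when
    fewer than ``min_obs`` measurements remain.
    """
    kept, n_age, n_neo = [], 0, 0
    for m in series.measurements:
        if m.age_days > max_age:
            n_age += 1
        elif (series.measure == "weight" and m.age_days > 1
              and neonatal_low <= m.age_days <= neonatal_high):
            n_neo += 1
        else:
            kept.append(m)
    if report is not None:
        sid = series.subject_id
        report.dropped_age[sid] = report.dropped_age.get(sid, 0) + n_age
        report.dropped_neonatal[sid] = report.dropped_neonatal.get(sid, 0) + n_neo
        report.retained[sid] = len(kept)
    if len(kept) < min_obs:
        if report is not None:
            report.excluded_subjects.append(series.subject_id)
        return None
    return GrowthSeries(series.subject_id, series.sex, series.measure, kept)


def clean_cohort(seriess: Iterable[GrowthSeries], **kwargs) -> tuple[list[GrowthSeries], CleaningReport]:
    """clean_series over a cohort, collecting a shared CleaningReport."""
    report = CleaningReport()
    out = []
    for s in seriess:
        report.n_rows_input += len(s)
        cleaned = clean_series(s, report=report, **kwargs)
        if cleaned is not None:
            out.append(cleaned)
    return out, report


def flag_implausible(series: GrowthSeries, height_decrease_tol: float = 0.5,
                     robust_z_cut: float = 5.0) -> list[Measurement]:
    """Advisory implausibility screen; removal is the caller's choice.

    Flags (a) height values lower than any earlier height by more than
    ``height_decrease_tol`` cm, and (b) values whose robust z-score (median /
    MAD of residuals from a centred running median of window 3) exceeds
    ``robust_z_cut``.
    """
    flagged: dict[int, Measurement] = {}
    values = series.values
    n = len(series)

    if series.measure == "height":
        running_max = -np.inf
        for i, m in enumerate(series.measurements):
            if m.value < running_max - height_decrease_tol:
                flagged[i] = m
            running_max = max(running_max, m.value)

    if n >= 3:
        med = np.array([np.median(values[max(0, i - 1):min(n, i + 2)]) for i in range(n)])
        resid = values - med
        dev = np.abs(resid - np.median(resid))
        scale = 1.4826 * np.median(dev)
        if scale == 0:  # >=half the residuals identical; fall back to the sd
            scale = float(np.std(resid, ddof=1)) if n > 1 else 0.0
        if scale > 0:
            for i in np.nonzero(dev / scale > robust_z_cut)[0]:
                flagged[int(i)] = series.measurements[int(i)]

    return [flagged[i] for i in sorted(flagged)]


def assign_visits(series: GrowthSeries,
                  schedule: VisitSchedule = WELL_BABY_SCHEDULE) -> dict[int, Measurement]:
    """Map measurements onto scheduled visits.

    A measurement is a candidate for the (unique) window containing its age;
    day-0 records are accepted for visit 1 alongside day-1 records.  Within a
    window the measurement closest to the window midpoint wins, ties going to
    the earlier age.  Measurements in no window are left unassigned.
    """
    assignment: dict[int, Measurement] = {}
    for idx, lo, hi in schedule:
        eff_lo = 0 if idx == 1 and lo == 1 else lo  # birth records: day 0 or 1
        mid = (lo + hi) / 2
        best = None
        for m in series.measurements:
            if eff_lo <= m.age_days <= hi:
                key = (abs(m.age_days - mid), m.age_days)
                if best is None or key < best[0]:
                    best = (key, m)
        if best is not None:
            assignment[idx] = best[1]
    return assignment


def has_complete_visits(assignment: dict[int, Measurement], through_visit: int) -> bool:
    """True iff visits 1..through_visit (7 = year 1, 12 = full) all matched."""
    if through_visit not in (7, 12):
        raise ValueError("through_visit must be 7 or 12")
    return all(v in assignment for v in range(1, through_visit + 1))
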