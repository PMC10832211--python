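"""Single-point interpolators used by the holdout comparison.

Each interpolator is a callable ``(ages, values, age0) -> float`` predicting
the measurement at ``age0`` from the remaining points.  The registry holds
the in-package methods (the growth-curve fit itself, last observation carried
forward, ordinary least-squares line, local-quadratic LOESS, GCV smoothing
spline) and accepts externally registered methods (e.g. mixed-effects or
shape-invariant growth models) through the same interface.
"""

from __future__ import annotations

import logging
from typing import Callable, Protocol

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .model import FitControl, MichaelisMentenModel, rescue_start

log = logging.getLogger(__name__)

__all__ = [
    "Interpolator",
    "INTERPOLATORS",
    "register_interpolator",
    "get_interpolator",
    "interpolate_locf",
    "interpolate_linear",
    "interpolate_loess",
    "interpolate_spline",
    "make_mm_interpolator",
]


class Interpolator(Protocol):
    def __call__(self, ages: np.ndarray, values: np.ndarray, age0: float) -> float: ...


def interpolate_locf(ages, values, age0: float) -> float:
    """Last observation carried forward: latest value observed before age0."""
    ages = np.asarray(ages, dtype=float)
    before = np.nonzero(ages < age0)[0]
    if before.size == 0:
        raise ValueError("LOCF needs at least one observation before the target age")
    return float(np.asarray(values, dtype=float)[before[np.argmax(ages[before])]])


def interpolate_linear(ages, values, age0: float) -> float:
    """Ordinary least-squares line over all points, evaluated at age0."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size < 2:
        raise ValueError("linear interpolation needs >= 2 observations")
    if np.ptp(ages) == 0:
        raise ValueError("zero age variance")
    slope, intercept = np.polyfit(ages, values, 1)
    return float(intercept + slope * age0)


def interpolate_loess(ages, values, age0: float, span: float = 0.75) -> float:
    """Local quadratic regression with tricube weights (LOESS, degree 2).

    The ``span`` fraction of points nearest to ``age0`` enters a weighted
    quadratic fit.  Fewer than 4 points falls back to the least-squares line
    (logged).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size < 4:
        log.warning("LOESS fallback to linear: only %d points", ages.size)
        return interpolate_linear(ages, values, age0)
    k = max(4, int(np.ceil(span * ages.size)))
    dist = np.abs(ages - age0)
    idx = np.argsort(dist, kind="stable")[:k]
    d = dist[idx]
    dmax = d.max()
    if dmax == 0:
        return float(values[idx].mean())
    w = (1 - np.minimum(d / dmax, 1.0) ** 3) ** 3
    w[np.argmin(d)] = max(w[np.argmin(d)], 1e-6)  # keep nearest point in play
    coeffs = np.polyfit(ages[idx], values[idx], 2, w=np.sqrt(w))
    return float(np.polyval(coeffs, age0))


def interpolate_spline(ages, values, age0: float) -> float:
    """Cubic smoothing spline with GCV-chosen penalty, evaluated at age0.

    Duplicate ages are averaged (the spline needs strictly increasing knots);
    too few points falls back to the least-squares line (logged).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    ux, inv = np.unique(ages, return_inverse=True)
    uy = np.bincount(inv, weights=values) / np.bincount(inv)
    if ux.size < 5:
        log.warning("spline fallback to linear: only %d distinct ages", ux.size)
        return interpolate_linear(ages, values, age0)
    try:
        spl = make_smoothing_spline(ux, uy)
    except Exception as exc:  # degenerate GCV problem
        log.warning("spline fallback to linear: %s", exc)
        return interpolate_linear(ages, values, age0)
    return float(spl(age0))


def make_mm_interpolator(measure: str = "weight", allow_rescue: bool = True,
                         control: FitControl | None = None) -> Callable:
    """Interpolator backed by the Michaelis-Menten growth fit itself.

    Raises ``RuntimeError`` when the fit fails (optionally after one retry
    from the rescue start), so the holdout harness can count the failure.
    """

    def _mm(ages, values, age0: float) -> float:
        model = MichaelisMentenModel(values, ages, measure=measure)
        res = model.fit(control=control)
        if not res.converged and allow_rescue:
            res = model.fit(start=rescue_start(measure), control=control)
        if not res.converged:
            raise RuntimeError(f"growth-curve fit failed: {res.status}")
        return float(res.predict(age0))

    _mm.__name__ = "interpolate_mm"
    return _mm


INTERPOLATORS: dict[str, Callable] = {
    "locf": interpolate_locf,
    "linear": interpolate_linear,
    "loess": interpolate_loess,
    "spline": interpolate_spline,
}


def register_interpolator(name: str, func: Callable) -> None:
    """Register a pluggable external method under ``name``."""
    INTERPOLATORS[name] = func


def get_interpolator(name: str, measure: str = "weight") -> Callable:
    """Resolve a method name; ``"mm"`` builds the growth-fit interpolator."""
    if name == "mm":
        return make_mm_interpolator(measure=measure)
    try:
        return INTERPOLATORS[name]
    except KeyError:
        raise ValueError(f"unknown interpolation method: {name!r}") from None
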