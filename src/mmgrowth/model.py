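"""Modified Michaelis-Menten growth curve and per-subject nonlinear fitting.

Individual growth in weight (kg) or height/length (cm) from birth to roughly
36 months is described by a saturating hyperbola with a nonzero intercept::

    P(age) = c1 + a1 * age / (b1 + age)

where ``age`` is in days since birth, ``c1`` is the size at age 0 (empirically
close to birth weight or birth length), ``a1`` is the asymptotic gain above
birth size (the curve approaches ``a1 + c1`` as age grows), and ``b1`` is the
half-saturation age — the age in days at which half of ``a1`` has been
attained.  The form is the Michaelis-Menten enzyme-saturation curve with an
added intercept.

Each child is fitted independently by unconstrained nonlinear least squares
using Gauss-Newton iterations with a step-halving line search.  Children whose
growth is close to linear drive ``a1`` and ``b1`` to arbitrarily large values
(the hyperbola degenerates into a line); the fitter detects this and reports
``diverged_unbounded`` instead of a parameter estimate.  Goodness of fit is
the root-mean-squared residual (RMSE), in measurement units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "MMParams",
    "FitControl",
    "FitResult",
    "MichaelisMentenModel",
    "mm_value",
    "default_start",
    "rescue_start",
    "fit_mm",
    "rmse",
    "residual_profile",
    "rmse_by_age",
    "STATUS_CONVERGED",
    "STATUS_DIVERGED",
    "STATUS_SINGULAR",
    "STATUS_MAX_ITER",
]

STATUS_CONVERGED = "converged"
STATUS_DIVERGED = "diverged_unbounded"
STATUS_SINGULAR = "singular"
STATUS_MAX_ITER = "max_iter"


class MMParams(NamedTuple):
    """Parameter triple of the modified Michaelis-Menten curve.

    a1 : asymptotic gain above birth size (kg or cm)
    b1 : half-saturation age (days)
    c1 : intercept at age 0, approximately birth size (kg or cm)
    """

    a1: float
    b1: float
    c1: float


#: Manually tuned nonlinear-least-squares start values, per measure kind.
_DEFAULT_STARTS = {
    "weight": MMParams(5.0, 20.0, 2.5),
    "height": MMParams(60.0, 530.0, 50.0),
}

#: Higher a1/b1 starts that partly rescue fits lacking a birth record.
_RESCUE_STARTS = {
    "weight": MMParams(15.0, 500.0, 2.5),
    "height": MMParams(90.0, 800.0, 50.0),
}


def default_start(measure: str) -> MMParams:
    """Default start values for Gauss-Newton fitting of one measure kind."""
    try:
        return _DEFAULT_STARTS[measure]
    except KeyError:
        raise ValueError(f"unknown measure kind: {measure!r}") from None


def rescue_start(measure: str) -> MMParams:
    """Alternative start with larger a1/b1, useful when visit 1 is missing."""
    try:
        return _RESCUE_STARTS[measure]
    except KeyError:
        raise ValueError(f"unknown measure kind: {measure!r}") from None


def mm_value(params: MMParams | Sequence[float], age):
    """Evaluate the growth curve c1 + a1*age/(b1+age) at one or many ages.

    Raises ``ValueError`` where ``b1 + age`` is zero (the curve's pole).
    """
    a1, b1, c1 = params
    age = np.asarray(age, dtype=float)
    denom = b1 + age
    if np.any(denom == 0):
        raise ValueError("mm_value undefined at age = -b1 (pole of the hyperbola)")
    out = c1 + a1 * age / denom
    return float(out) if out.ndim == 0 else out


def rmse(residuals: Sequence[float]) -> float:
    """Root-mean-squared error, denominator n (no degrees-of-freedom correction)."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("rmse of an empty residual list is undefined")
    return float(np.sqrt(np.mean(r * r)))


@dataclass(frozen=True)
class FitControl:
    """Tuning knobs of the Gauss-Newton fitter.

    start may be None, in which case the measure-specific default is used.
    convergence_tol is the relative SSE-improvement threshold; step_tol the
    relative parameter-step threshold; divergence_bound the |a1| / |b1|
    magnitude at which the fit is declared unbounded.
    """

    start: MMParams | None = None
    max_iterations: int = 50
    convergence_tol: float = 1e-10
    step_tol: float = 1e-8
    divergence_bound: float = 1e7
    max_halvings: int = 10

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0 or self.step_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.divergence_bound <= 0:
            raise ValueError("divergence_bound must be > 0")


@dataclass
class FitResult:
    """Outcome of one per-subject fit (the results object).

    ``params`` is present exactly when ``status == "converged"``; residuals
    are observed minus predicted in measurement units, and ``rmse`` is their
    root mean square.
    """

    status: str
    iterations: int
    params: MMParams | None = None
    residuals: np.ndarray | None = None
    rmse: float | None = None
    sse: float | None = None
    start: MMParams | None = None
    model: "MichaelisMentenModel | None" = field(default=None, repr=False)

    @property
    def converged(self) -> bool:
        return self.status == STATUS_CONVERGED

    def predict(self, ages) -> np.ndarray:
        if self.params is None:
            raise ValueError(f"no parameters available (status: {self.status})")
        return mm_value(self.params, ages)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of a regression results print."""
        lines = [
            "Modified Michaelis-Menten growth fit",
            "=" * 44,
            f"status:      {self.status}",
            f"iterations:  {self.iterations}",
        ]
        if self.model is not None:
            lines.append(f"n obs:       {self.model.nobs}")
            lines.append(f"measure:     {self.model.measure}")
        if self.params is not None:
            a1, b1, c1 = self.params
            lines += [
                "-" * 44,
                f"{'param':<10}{'estimate':>12}  interpretation",
                f"{'a1':<10}{a1:>12.4f}  asymptotic gain",
                f"{'b1':<10}{b1:>12.2f}  half-saturation age (days)",
                f"{'c1':<10}{c1:>12.4f}  size at age 0",
                "-" * 44,
                f"asymptote (a1+c1): {a1 + c1:.4f}",
                f"rmse:              {self.rmse:.6g}",
            ]
        return "\n".join(lines)


class MichaelisMentenModel:
    """Modified Michaelis-Menten growth model for one child's series.

    Parameters
    ----------
    values : array-like
        Observed sizes, kg (weight) or cm (height); finite and positive.
    ages : array-like
        Ages in days since birth, same length as ``values``; duplicate ages
        are allowed and all enter the least-squares objective.
    measure : {"weight", "height"}
        Selects default start values and the reporting unit.

    ``fit`` runs unconstrained Gauss-Newton on the sum of squared residuals
    with step-halving (up to ``max_halvings`` halvings per step when the SSE
    does not decrease).  Convergence is declared on a small relative SSE
    improvement or a small relative parameter step; unbounded a1/b1 growth
    (the linear-growth degeneracy) yields ``diverged_unbounded``; rank-
    deficient normal equations or a sign-degenerate optimum (a1 <= 0 or
    b1 <= 0) yield ``singular``.
    """

    def __init__(self, values, ages, measure: str = "weight"):
        values = np.asarray(values, dtype=float)
        ages = np.asarray(ages, dtype=float)
        if values.shape != ages.shape or values.ndim != 1:
            raise ValueError("values and ages must be 1-d arrays of equal length")
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(ages)):
            raise ValueError("non-finite values or ages")
        if np.any(values <= 0):
            raise ValueError("values must be positive (kg or cm)")
        if np.any(ages < 0):
            raise ValueError("ages must be >= 0 days")
        if np.unique(ages).size < 3:
            raise ValueError("need at least 3 distinct ages to fit 3 parameters")
        if measure not in _DEFAULT_STARTS:
            raise ValueError(f"unknown measure kind: {measure!r}")
        order = np.argsort(ages, kind="stable")
        self.ages = ages[order]
        self.values = values[order]
        self.measure = measure

    @classmethod
    def from_series(cls, series) -> "MichaelisMentenModel":
        """Build the model from a :class:`mmgrowth.cohort.GrowthSeries`."""
        return cls(series.values, series.ages, measure=series.measure)

    @property
    def nobs(self) -> int:
        return self.ages.size

    def predict(self, params: MMParams, ages=None) -> np.ndarray:
        return mm_value(params, self.ages if ages is None else ages)

    # -- Gauss-Newton machinery -------------------------------------------

    def _residuals_sse(self, theta: np.ndarray):
        with np.errstate(all="ignore"):
            denom = theta[1] + self.ages
            pred = theta[2] + theta[0] * self.ages / denom
            r = self.values - pred
            sse = float(np.dot(r, r)) if np.all(np.isfinite(r)) else math.inf
        return r, sse

    def _jacobian(self, theta: np.ndarray) -> np.ndarray:
        denom = theta[1] + self.ages
        g = self.ages / denom
        return np.column_stack([g, -theta[0] * self.ages / denom**2, np.ones_like(g)])

    def fit(self, start: MMParams | None = None, control: FitControl | None = None,
            **control_overrides) -> FitResult:
        """Fit by Gauss-Newton least squares; never raises on non-convergence.

        Keyword overrides (``max_iterations=``, ``divergence_bound=``, ...)
        are applied on top of ``control``.
        """
        ctl = control or FitControl()
        if control_overrides:
            ctl = replace(ctl, **control_overrides)
        if start is None:
            start = ctl.start or default_start(self.measure)
        theta = np.asarray(start, dtype=float)
        bound = ctl.divergence_bound

        def _diverged(th, s) -> bool:
            return (not math.isfinite(s)) or abs(th[0]) > bound or abs(th[1]) > bound

        r, sse = self._residuals_sse(theta)
        if _diverged(theta, sse):
            return FitResult(STATUS_DIVERGED, 0, start=MMParams(*start), model=self)

        status = STATUS_MAX_ITER
        it = 0
        for it in range(1, ctl.max_iterations + 1):
            J = self._jacobian(theta)
            if not np.all(np.isfinite(J)):
                status = STATUS_DIVERGED
                break
            step, _, rank, _ = np.linalg.lstsq(J, r)
            if rank < 3:
                # Collinear Jacobian columns: either the linear-growth
                # degeneracy (huge a1/b1) or genuinely singular equations.
                status = STATUS_DIVERGED if _diverged(theta, sse) else STATUS_SINGULAR
                break
            grad = J.T @ r
            lam = 1.0
            accepted = False
            for _ in range(ctl.max_halvings + 1):
                cand = theta + lam * step
                r2, sse2 = self._residuals_sse(cand)
                if sse2 < sse:
                    accepted = True
                    break
                lam *= 0.5
            if not accepted:
                # Step-halving exhausted: at (numerical) stationarity this is
                # convergence, otherwise a stalled line search.
                if np.max(np.abs(grad)) <= 1e-8 * max(1.0, float(np.linalg.norm(r))):
                    status = STATUS_CONVERGED
                break
            rel_impr = (sse - sse2) / max(sse2, 1e-300)
            rel_step = float(np.linalg.norm(lam * step)) / max(float(np.linalg.norm(theta)), 1e-300)
            theta, r, sse = cand, r2, sse2
            if _diverged(theta, sse):
                status = STATUS_DIVERGED
                break
            if rel_impr < ctl.convergence_tol or rel_step < ctl.step_tol:
                status = STATUS_CONVERGED
                break

        if status != STATUS_DIVERGED and _diverged(theta, sse):
            status = STATUS_DIVERGED
        if status == STATUS_CONVERGED and (theta[0] <= 0 or theta[1] <= 0):
            # Converged to a sign-degenerate optimum; treated as a failure.
            status = STATUS_SINGULAR

        if status != STATUS_CONVERGED:
            return FitResult(status, it, start=MMParams(*start), model=self)
        return FitResult(
            STATUS_CONVERGED,
            it,
            params=MMParams(*theta),
            residuals=r.copy(),
            rmse=rmse(r),
            sse=sse,
            start=MMParams(*start),
            model=self,
        )


def fit_mm(series, control: FitControl | None = None,
           rescue_on_failure: bool = False) -> FitResult:
    """Fit the growth curve to one :class:`~mmgrowth.cohort.GrowthSeries`.

    With ``rescue_on_failure`` a failed fit is retried once from the
    larger-a1/b1 rescue start (helpful when the birth record is missing).
    """
    model = MichaelisMentenModel.from_series(series)
    result = model.fit(control=control)
    if not result.converged and rescue_on_failure:
        retry = model.fit(start=rescue_start(series.measure), control=control)
        if retry.converged:
            return retry
    return result


def residual_profile(fit: FitResult, series=None) -> list[tuple[float, float]]:
    """Per-measurement (age, observed - predicted) pairs of a converged fit.

    ``series`` may re-supply the measurements; by default the fit's own model
    data are used.  Raises if the fit did not converge.
    """
    if not fit.converged:
        raise ValueError(f"residual profile requires a converged fit (status: {fit.status})")
    if series is None:
        ages, resid = fit.model.ages, fit.residuals
    else:
        ages = np.asarray(series.ages, dtype=float)
        resid = np.asarray(series.values, dtype=float) - mm_value(fit.params, ages)
    return [(float(a), float(r)) for a, r in zip(ages, resid)]


def rmse_by_age(profile: Sequence[tuple[float, float]], bin_edges) -> list[tuple[float, float, int]]:
    """Aggregate a residual profile into per-age-bin RMSE for plotting.

    Returns (bin_midpoint, rmse, n) per non-empty bin; bins are
    [edge_i, edge_{i+1}) with the last bin closed on the right.
    """
    edges = np.asarray(bin_edges, dtype=float)
    ages = np.array([p[0] for p in profile])
    resid = np.array([p[1] for p in profile])
    out = []
    for i in range(edges.size - 1):
        lo, hi = edges[i], edges[i + 1]
        mask = (ages >= lo) & ((ages < hi) | ((i == edges.size - 2) & (ages <= hi)))
        if mask.any():
            out.append((float((lo + hi) / 2), rmse(resid[mask]), int(mask.sum())))
    return out
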