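"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the observational setting the fitter is built for:
per-child curve parameters (a1, b1 log-normal with right skew, c1 normal,
rank-coupled through a Gaussian copula), visit ages drawn inside the 12
well-baby windows (visit 1 = day 1), independent per-visit dropout, additive
Gaussian measurement noise, and a small fraction of linear growers — children
whose size rises linearly with age, the regime in which the saturating fit
diverges.  Default parameter locations and spreads follow the large-cohort
weight/height estimates by sex.

All randomness flows from one seed through per-subject spawned streams, so
enlarging the cohort never reshuffles earlier subjects' draws, and the
linear-grower flag is assigned by a deterministic exact-count rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import GrowthSeries, Measurement, VisitSchedule, WELL_BABY_SCHEDULE, write_cohort
from .model import MMParams, mm_value

__all__ = [
    "ParamDistribution",
    "CohortConfig",
    "TruthRecord",
    "sample_params",
    "generate_series",
    "generate_cohort",
    "truth_frame",
    "DEFAULT_PARAM_DISTRIBUTIONS",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


@dataclass(frozen=True)
class ParamDistribution:
    """Marginals for one sex/measure: a1, b1 log-normal (median & IQR),
    c1 normal (mean & sd)."""

    a1_median: float
    a1_iqr: float
    b1_median: float
    b1_iqr: float
    c1_mean: float
    c1_sd: float

    def __post_init__(self):
        for name in ("a1_median", "a1_iqr", "b1_median", "b1_iqr", "c1_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def lognormal_sigma(self, which: str) -> float:
        """Log-scale sd giving the configured IQR at the configured median."""
        med = getattr(self, f"{which}_median")
        iqr = getattr(self, f"{which}_iqr")
        return math.asinh(iqr / (2 * med)) / _Z75


#: Per (measure, sex) defaults from the large-cohort estimates.
DEFAULT_PARAM_DISTRIBUTIONS = {
    ("weight", "male"): ParamDistribution(14.1, 5.77, 393, 327, 3.34, 0.58),
    ("weight", "female"): ParamDistribution(14.7, 6.77, 499, 425, 3.28, 0.54),
    ("height", "male"): ParamDistribution(62.0, 17.7, 502, 266, 51.1, 2.50),
    ("height", "female"): ParamDistribution(64.5, 19.6, 547, 320, 50.3, 2.40),
}

_DEFAULT_NOISE = {"weight": 0.2, "height": 1.0}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    sex_ratio is the male fraction.  noise_sd defaults to 0.2 kg for weight
    and 1.0 cm for height (None selects by measure).  age_noise_factor > 0
    makes the noise sd grow linearly with age, reaching
    noise_sd * (1 + age_noise_factor) at 1125 days.
    """

    n_subjects: int = 500
    measure: str = "weight"
    sex_ratio: float = 0.5
    param_distributions: dict = field(default_factory=dict)
    rank_correlation_c1_a1: float = 0.30
    rank_correlation_c1_b1: float = 0.30
    rank_correlation_a1_b1: float = 0.50
    noise_sd: float | None = None
    age_noise_factor: float = 0.0
    visit_schedule: VisitSchedule = WELL_BABY_SCHEDULE
    visit_missingness: float = 0.0
    linear_grower_fraction: float = 0.01
    seed: int = 1234

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for p in (self.sex_ratio, self.visit_missingness, self.linear_grower_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.measure not in ("weight", "height"):
            raise ValueError(f"unknown measure kind: {self.measure!r}")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def effective_noise_sd(self) -> float:
        return _DEFAULT_NOISE[self.measure] if self.noise_sd is None else self.noise_sd

    def distribution(self, sex: str) -> ParamDistribution:
        return self.param_distributions.get(
            sex, DEFAULT_PARAM_DISTRIBUTIONS[(self.measure, sex)])


@dataclass
class TruthRecord:
    """Ground truth for one generated subject."""

    subject_id: str
    sex: str
    params: MMParams
    is_linear_grower: bool
    linear_slope: float | None = None
    noise_draws: np.ndarray | None = None


def _copula_cov(config: CohortConfig) -> np.ndarray:
    """Latent normal correlation matrix hitting the target rank correlations."""
    def pearson(rho_s):
        return 2 * math.sin(math.pi * rho_s / 6)

    r_ab = pearson(config.rank_correlation_a1_b1)
    r_ac = pearson(config.rank_correlation_c1_a1)
    r_bc = pearson(config.rank_correlation_c1_b1)
    cov = np.array([[1, r_ab, r_ac], [r_ab, 1, r_bc], [r_ac, r_bc, 1]])
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("rank-correlation targets give a non-positive-definite copula")
    return cov


def sample_params(config: CohortConfig, sex: str, rng: np.random.Generator) -> MMParams:
    """Draw one (a1, b1, c1) triple from the copula-coupled marginals."""
    dist = config.distribution(sex)
    z = np.linalg.cholesky(_copula_cov(config)) @ rng.standard_normal(3)
    a1 = dist.a1_median * math.exp(dist.lognormal_sigma("a1") * z[0])
    b1 = dist.b1_median * math.exp(dist.lognormal_sigma("b1") * z[1])
    c1 = max(dist.c1_mean + dist.c1_sd * z[2], 0.2)  # sizes stay positive
    return MMParams(a1, b1, c1)


def generate_series(params: MMParams, config: CohortConfig, rng: np.random.Generator,
                    subject_id: str = "S0", sex: str = "male",
                    is_linear: bool = False, max_retries: int = 10,
                    ) -> tuple[GrowthSeries, TruthRecord]:
    """Generate one child's series from its true parameters.

    Visit ages are uniform integers inside each window (visit 1 = day 1);
    visits drop out independently with ``visit_missingness``.  Values are the
    curve (or, for linear growers, the line through c1 whose value at day 1095
    matches a fresh draw from the curve cohort's 1095-day distribution) plus
    Gaussian noise, floored at 0.1 units.
    """
    slope = None
    if is_linear:
        other = sample_params(config, sex, rng)
        slope = max((mm_value(other, 1095.0) - params.c1) / 1095.0, 1e-4)

    sd0 = config.effective_noise_sd
    for _ in range(max_retries):
        ages = []
        for idx, lo, hi in config.visit_schedule:
            if rng.random() < config.visit_missingness:
                continue
            ages.append(int(rng.integers(lo, hi + 1)))
        if ages:
            break
    else:
        truth = TruthRecord(subject_id, sex, params, is_linear, slope,
                            np.array([]))
        return GrowthSeries(subject_id, sex, config.measure, []), truth

    ages_arr = np.array(ages, dtype=float)
    clean = (params.c1 + slope * ages_arr) if is_linear else mm_value(params, ages_arr)
    sd = sd0 * (1 + config.age_noise_factor * ages_arr / 1125.0)
    noise = rng.standard_normal(len(ages)) * sd
    values = np.maximum(clean + noise, 0.1)
    measurements = [Measurement(a, float(v), config.measure)
                    for a, v in zip(ages, values)]
    truth = TruthRecord(subject_id, sex, params, is_linear, slope, noise)
    return GrowthSeries(subject_id, sex, config.measure, measurements), truth


def _linear_indices(n: int, fraction: float) -> set[int]:
    """Deterministic exact-count assignment, stable under growing n."""
    return {i for i in range(n)
            if math.floor((i + 1) * fraction) > math.floor(i * fraction)}


def generate_cohort(config: CohortConfig) -> tuple[list[GrowthSeries], list[TruthRecord]]:
    """Generate the full cohort; fully determined by ``config.seed``."""
    linear_ids = _linear_indices(config.n_subjects, config.linear_grower_fraction)
    cohort, truths = [], []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(i,)))
        sex = "male" if rng.random() < config.sex_ratio else "female"
        params = sample_params(config, sex, rng)
        series, truth = generate_series(params, config, rng,
                                        subject_id=f"S{i:05d}", sex=sex,
                                        is_linear=i in linear_ids)
        if len(series):
            cohort.append(series)
        truths.append(truth)
    return cohort, truths


def truth_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject_id": t.subject_id, "sex": t.sex, "a1": t.params.a1,
         "b1": t.params.b1, "c1": t.params.c1,
         "is_linear_grower": t.is_linear_grower}
        for t in truths
    ])


def simulate_to_files(config: CohortConfig, cohort_path, truth_path=None
                      ) -> tuple[list[GrowthSeries], list[TruthRecord]]:
    """Generate and write the cohort CSV (and optionally the truth CSV)."""
    cohort, truths = generate_cohort(config)
    write_cohort(cohort, cohort_path)
    if truth_path is not None:
        truth_frame(truths).to_csv(truth_path, index=False, float_format="%.10g")
    return cohort, truths
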