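"""Fibre-quality kinetics: potential logistic growth and temperature reduction.

Each fruit's fibre length (mm), strength (cN tex⁻¹) and micronaire
(dimensionless) follow a logistic *potential* curve in physiological fruit
age (days after squaring).  The realised daily increment is the potential
increment along that curve multiplied by temperature reduction factors:

* length      — daily mean temperature only (quadratic, optimum near 25 °C);
* strength    — daily mean (linear, saturating at 1 above 30 °C) × diurnal
                range (linear, decreasing);
* micronaire  — daily minimum temperature (linear, saturating at 1 above
                25 °C).

All factors are clamped to [0, 1]; raw (unclamped) values are available for
diagnostics via ``clamp=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .weather import WeatherDay

__all__ = [
    "INDICES",
    "LogisticParams",
    "QualityParams",
    "QualityState",
    "ReductionFactors",
    "potential_quality",
    "potential_rate",
    "length_mean_temp_factor",
    "strength_mean_temp_factor",
    "strength_td_factor",
    "micronaire_tmin_factor",
    "reduction_factor",
    "daily_quality_increment",
]

INDICES = ("length", "strength", "micronaire")


@dataclass(frozen=True)
class LogisticParams:
    """Logistic constants for one quality index.

    q_max  — asymptotic (potential) value, in the index's units;
    k      — relative growth rate, per physiological day;
    t_m    — inflection age (physiological days after squaring) at which the
             growth rate is maximal.
    """

    q_max: float
    k: float
    t_m: float

    def __post_init__(self) -> None:
        if self.q_max <= 0 or self.k <= 0 or self.t_m <= 0:
            raise ValueError("q_max, k and t_m must all be positive")


@dataclass(frozen=True)
class QualityParams:
    """Calibrated quality-kinetics parameter set for one cultivar group.

    Defaults are the Anyang 2007 nonlinear-regression estimates for the
    pooled cultivars, plus the multi-site temperature-response regression
    coefficients.
    """

    length: LogisticParams = LogisticParams(30.47, 0.28, 33.78)
    strength: LogisticParams = LogisticParams(30.94, 0.23, 39.97)
    micronaire: LogisticParams = LogisticParams(4.648, 0.22, 47.03)
    # f(T̄)_L = a·T̄² + b·T̄ + c
    length_mean_coeffs: tuple[float, float, float] = (-0.0038, 0.1904, -1.3694)
    # f(T̄)_S = slope·T̄ + intercept, = 1 above saturation temperature
    strength_mean_coeffs: tuple[float, float] = (0.0198, 0.4657)
    strength_mean_saturation: float = 30.0
    # f(TD)_S = slope·TD + intercept
    strength_td_coeffs: tuple[float, float] = (-0.0216, 1.136)
    # f(Tmin)_M = slope·Tmin + intercept, = 1 above saturation temperature
    micronaire_tmin_coeffs: tuple[float, float] = (0.0244, 0.3874)
    micronaire_tmin_saturation: float = 25.0

    def logistic(self, index: str) -> LogisticParams:
        if index not in INDICES:
            raise KeyError(f"unknown quality index {index!r}")
        return getattr(self, index)


def potential_quality(age, params: LogisticParams):
    """Potential value of a quality index at physiological fruit ``age``.

    Q(t) = q_max / (1 + exp(−k·(t − t_m))).
    """
    age = np.asarray(age, dtype=float)
    out = params.q_max / (1.0 + np.exp(-params.k * (age - params.t_m)))
    return float(out) if out.ndim == 0 else out


def potential_rate(age, params: LogisticParams):
    """Analytic derivative dQ/dt of the potential logistic (units per pd)."""
    age = np.asarray(age, dtype=float)
    e = np.exp(-params.k * (age - params.t_m))
    out = params.q_max * params.k * e / (1.0 + e) ** 2
    return float(out) if out.ndim == 0 else out


def _clamp01(x: float, clamp: bool) -> float:
    return min(1.0, max(0.0, x)) if clamp else x


def length_mean_temp_factor(
    t_mean: float, params: QualityParams = QualityParams(), clamp: bool = True
) -> float:
    """Mean-temperature effect on fibre-length growth (quadratic, peak ≈ 25 °C)."""
    a, b, c = params.length_mean_coeffs
    return _clamp01(a * t_mean**2 + b * t_mean + c, clamp)


def strength_mean_temp_factor(
    t_mean: float, params: QualityParams = QualityParams(), clamp: bool = True
) -> float:
    """Mean-temperature effect on strength; 1 above the ~30 °C saturation."""
    slope, intercept = params.strength_mean_coeffs
    if clamp and t_mean > params.strength_mean_saturation:
        return 1.0
    return _clamp01(slope * t_mean + intercept, clamp)


def strength_td_factor(
    t_range: float, params: QualityParams = QualityParams(), clamp: bool = True
) -> float:
    """Diurnal-range effect on strength; large day–night swings reduce growth."""
    if t_range < 0:
        raise ValueError("t_range must be >= 0")
    slope, intercept = params.strength_td_coeffs
    return _clamp01(slope * t_range + intercept, clamp)


def micronaire_tmin_factor(
    t_min: float, params: QualityParams = QualityParams(), clamp: bool = True
) -> float:
    """Minimum-temperature effect on micronaire; 1 above 25 °C."""
    if clamp and t_min > params.micronaire_tmin_saturation:
        return 1.0
    slope, intercept = params.micronaire_tmin_coeffs
    return _clamp01(slope * t_min + intercept, clamp)


@dataclass(frozen=True)
class ReductionFactors:
    """The four clamped daily reduction factors, all in [0, 1]."""

    f_mean_length: float
    f_mean_strength: float
    f_td_strength: float
    f_tmin_micronaire: float

    @classmethod
    def for_day(cls, day: WeatherDay, params: QualityParams) -> "ReductionFactors":
        return cls(
            f_mean_length=length_mean_temp_factor(day.t_mean, params),
            f_mean_strength=strength_mean_temp_factor(day.t_mean, params),
            f_td_strength=strength_td_factor(day.t_range, params),
            f_tmin_micronaire=micronaire_tmin_factor(day.t_min, params),
        )

    def combined(self, index: str) -> float:
        """Product of the factors that act on ``index`` (others count as 1)."""
        if index == "length":
            return self.f_mean_length
        if index == "strength":
            return self.f_mean_strength * self.f_td_strength
        if index == "micronaire":
            return self.f_tmin_micronaire
        raise KeyError(f"unknown quality index {index!r}")


def reduction_factor(index: str, day: WeatherDay, params: QualityParams) -> float:
    """Combined daily reduction factor for one index on one day."""
    return ReductionFactors.for_day(day, params).combined(index)


def daily_quality_increment(
    age_before: float,
    age_after: float,
    day: WeatherDay,
    index: str,
    params: QualityParams,
) -> float:
    """Realised daily increment ΔQ_a for one index.

    The potential increment is taken along the fruit's own physiological-age
    trajectory, ΔQ = Q(age_after) − Q(age_before); the realised increment is
    ΔQ times the index's combined temperature factor.  Cold days therefore
    both slow the clock (smaller ΔQ) and shrink the increment (factor < 1).
    """
    if age_after < age_before:
        raise ValueError("age_after must be >= age_before")
    lp = params.logistic(index)
    dq = potential_quality(age_after, lp) - potential_quality(age_before, lp)
    return dq * reduction_factor(index, day, params)


@dataclass
class QualityState:
    """Accumulated actual quality and last potential value per index."""

    actual: dict[str, float] = field(
        default_factory=lambda: {i: 0.0 for i in INDICES}
    )
    potential: dict[str, float] = field(
        default_factory=lambda: {i: 0.0 for i in INDICES}
    )

    def update(
        self,
        age_before: float,
        age_after: float,
        day: WeatherDay,
        params: QualityParams,
    ) -> None:
        factors = ReductionFactors.for_day(day, params)
        for index in INDICES:
            lp = params.logistic(index)
            q_before = potential_quality(age_before, lp)
            q_after = potential_quality(age_after, lp)
            self.actual[index] += (q_after - q_before) * factors.combined(index)
            self.potential[index] = q_after
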