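"""Physiological time: converting daily mean temperature into development.

One physiological day is one calendar day's development at or above the
optimum temperature.  The daily increment is a clamped linear ramp between a
base temperature (no development) and an optimum (full development); organ
and plant ages are the running sums of these daily increments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ThermalParams", "PhysiologicalClock", "daily_temperature_effect"]


@dataclass(frozen=True)
class ThermalParams:
    """Cardinal temperatures for the physiological-day ramp (°C).

    Defaults (base 12 °C, optimum 25 °C) are the boll-development values used
    for cotton; a single set serves plant and organ clocks alike.
    """

    t_base: float = 12.0
    t_opt: float = 25.0

    def __post_init__(self) -> None:
        if not self.t_base < self.t_opt:
            raise ValueError("t_base must be < t_opt")


def daily_temperature_effect(t_mean, params: ThermalParams = ThermalParams()):
    """Daily development fraction E(T) ∈ [0, 1].

    E(T) = (T − Tb)/(To − Tb), clamped to 0 below the base temperature and to
    1 above the optimum.  Accepts scalars or arrays.
    """
    frac = (np.asarray(t_mean, dtype=float) - params.t_base) / (
        params.t_opt - params.t_base
    )
    out = np.clip(frac, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class PhysiologicalClock:
    """Accumulated physiological days; non-decreasing by construction."""

    accumulated_days: float = 0.0

    def accumulate(self, effect: float) -> "PhysiologicalClock":
        if effect < 0:
            raise ValueError("daily effect must be non-negative")
        self.accumulated_days += effect
        return self

    def __float__(self) -> float:
        return self.accumulated_days
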