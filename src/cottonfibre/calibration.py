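"""Calibration of the potential-quality logistic and goodness-of-fit metrics.

`fit_logistic` estimates (q_max, k, t_m) for one quality index from observed
quality-vs-fruit-age data by bounded nonlinear least squares with a small
deterministic multi-start, returning a results object with estimates,
standard errors, R² and RMSE.  `rmse` and `relative_error` are the two
evaluation statistics used to judge simulated against observed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .fibre_quality import LogisticParams, potential_quality

__all__ = ["FitResult", "fit_logistic", "rmse", "relative_error"]


@dataclass(frozen=True)
class FitResult:
    """Logistic-fit estimates with uncertainties and fit diagnostics."""

    q_max: float
    k: float
    t_m: float
    se_q_max: float
    se_k: float
    se_t_m: float
    r_squared: float
    rmse: float
    n: int

    @property
    def params(self) -> LogisticParams:
        return LogisticParams(self.q_max, self.k, self.t_m)

    def summary(self) -> str:
        lines = [
            f"Logistic potential-quality fit (n = {self.n})",
            f"  q_max = {self.q_max:.4g} ± {self.se_q_max:.2g}",
            f"  k     = {self.k:.4g} ± {self.se_k:.2g}  (pd⁻¹)",
            f"  t_m   = {self.t_m:.4g} ± {self.se_t_m:.2g}  (pd)",
            f"  R² = {self.r_squared:.4f}   RMSE = {self.rmse:.4g}",
        ]
        return "\n".join(lines)


def _logistic(t, q_max, k, t_m):
    return q_max / (1.0 + np.exp(-k * (t - t_m)))


def fit_logistic(
    ages: np.ndarray,
    values: np.ndarray,
    k_bounds: tuple[float, float] = (1e-4, 2.0),
    t_m_bounds: tuple[float, float] = (1e-3, 120.0),
) -> FitResult:
    """Fit Q(t) = q_max / (1 + exp(−k (t − t_m))) to observed (age, value) data.

    Bounded least squares with three deterministic starting points (spread in
    k); the best-SSR solution is kept.  Raises on under-determined (< 3
    points) or degenerate (constant) data, and on non-convergence of all
    starts.
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("ages and values must be 1-D arrays of equal length")
    if len(t) < 3:
        raise ValueError("at least 3 observations required to fit 3 parameters")
    if np.any(t < 0):
        raise ValueError("ages must be non-negative")
    if np.ptp(y) == 0:
        raise ValueError("degenerate (constant) series cannot identify the logistic")

    ymax = float(np.max(y))
    bounds = (
        [1e-8, k_bounds[0], t_m_bounds[0]],
        [2.0 * ymax, k_bounds[1], t_m_bounds[1]],
    )
    t_mid = float(np.median(t))
    starts = [
        (ymax, 0.05, t_mid),
        (ymax, 0.2, t_mid),
        (1.1 * ymax, 0.5, 0.5 * t_mid),
    ]

    best = None
    errors = []
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                _logistic, t, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            errors.append(str(exc))
            continue
        resid = y - _logistic(t, *popt)
        ssr = float(resid @ resid)
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        raise RuntimeError(
            "logistic fit failed to converge from all starting points: "
            + "; ".join(errors)
        )

    popt, pcov, ssr = best
    se = np.sqrt(np.diag(pcov))
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ssr / sst if sst > 0 else float("nan")
    return FitResult(
        q_max=float(popt[0]),
        k=float(popt[1]),
        t_m=float(popt[2]),
        se_q_max=float(se[0]),
        se_k=float(se[1]),
        se_t_m=float(se[2]),
        r_squared=min(1.0, max(0.0, r_squared)),
        rmse=float(np.sqrt(ssr / len(t))),
        n=len(t),
    )


def rmse(observed, simulated) -> float:
    """Root mean square error, sqrt(mean((Y − X)²))."""
    y = np.asarray(observed, dtype=float)
    x = np.asarray(simulated, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("observed and simulated must be equal-length nonempty 1-D")
    return float(np.sqrt(np.mean((y - x) ** 2)))


def relative_error(observed, simulated, form: str = "rms") -> float:
    """Relative error in percent.

    form="rms" (default): 100·sqrt(mean(((Y − X)/X)²)), the root-mean-square
    relative deviation conventional in crop-model evaluation.
    form="mean_abs": 100·mean(|Y − X|/|X|).
    """
    y = np.asarray(observed, dtype=float)
    x = np.asarray(simulated, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("observed and simulated must be equal-length nonempty 1-D")
    if np.any(x == 0):
        raise ValueError("simulated values must be nonzero for relative error")
    rel = (y - x) / x
    if form == "rms":
        return float(100.0 * np.sqrt(np.mean(rel**2)))
    if form == "mean_abs":
        return float(100.0 * np.mean(np.abs(rel)))
    raise ValueError("form must be 'rms' or 'mean_abs'")
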