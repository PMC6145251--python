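"""Derived process quantities: equilibrium, rates, process times.

Everything here operates on a fitted (or assumed) model in
concentration space, X(t) = x_eq * (1 - f(t)):

- the equilibrium concentration is estimated as the arithmetic mean of
  the last few observations of a near-plateau series;
- the extraction rate is the positive quantity dX/dt = -x_eq * df/dt
  (for the Page model, x_eq * a * b * t^(b-1) * exp(-a t^b));
- the process time for a target fraction p of equilibrium follows from
  the model's closed-form inverse at X* = 1 - p;
- percent extracted at a time t is 100 * (1 - X*(t)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .fitting import DataValidationError, KineticsSeries
from .models import (
    ModelLike,
    ParameterVector,
    dimensionless_rate,
    evaluate_dimensionless,
    time_to_dimensionless,
)

__all__ = [
    "DEFAULT_EQUILIBRIUM_TAIL",
    "DEFAULT_TARGET_FRACTION",
    "DEFAULT_RATE_T_MIN",
    "PredictionReport",
    "estimate_equilibrium",
    "extraction_rate_curve",
    "time_to_fraction",
    "percent_extracted_at",
]

#: observations averaged for the equilibrium estimate
DEFAULT_EQUILIBRIUM_TAIL = 3
#: fraction of equilibrium defining the reported process time (X* = 0.03)
DEFAULT_TARGET_FRACTION = 0.97
#: first sampled time of rate curves, avoiding the t=0 singularity of
#: the silva and sub-linear page rates
DEFAULT_RATE_T_MIN = 0.1


def estimate_equilibrium(series: KineticsSeries, tail: int = DEFAULT_EQUILIBRIUM_TAIL) -> float:
    """Arithmetic mean of the last ``tail`` concentrations (mg/100 g).

    Intended for a series that has visibly reached its plateau; a
    warning (not an error) is issued when the tail still trends upward
    by more than 5% of its mean.
    """
    if tail < 1:
        raise DataValidationError(f"tail must be >= 1, got {tail}")
    if tail > len(series):
        raise DataValidationError(
            f"tail ({tail}) exceeds number of observations ({len(series)})"
        )
    tail_values = series.x[-tail:]
    mean = float(np.mean(tail_values))
    if tail >= 2 and mean > 0 and (tail_values[-1] - tail_values[0]) > 0.05 * mean:
        warnings.warn(
            f"series {series.condition_label!r} may not have reached equilibrium: "
            f"tail still rises from {tail_values[0]:.4g} to {tail_values[-1]:.4g}",
            stacklevel=2,
        )
    return mean


def extraction_rate_curve(
    model: ModelLike,
    params: ParameterVector,
    x_eq: float,
    t_grid,
) -> np.ndarray:
    """Positive extraction rate dX/dt = -x_eq * df/dt (mg/100 g/min).

    ``t_grid`` must be strictly positive for models whose dimensionless
    rate diverges at t=0 (silva, page with b < 1); start grids at
    :data:`DEFAULT_RATE_T_MIN` in that case.
    """
    if x_eq <= 0.0:
        raise DataValidationError(f"x_eq must be > 0, got {x_eq}")
    rate = dimensionless_rate(model, params, t_grid)
    return -x_eq * np.asarray(rate)


def time_to_fraction(model: ModelLike, params: ParameterVector, fraction: float) -> float:
    """Minutes for X(t) to reach ``fraction`` of the equilibrium value.

    X(t) = fraction * x_eq corresponds to X* = 1 - fraction, so this
    delegates to the model's closed-form inverse.  ``fraction`` must lie
    in (0, 1); report tables round the result to the nearest minute but
    the raw value is returned here.
    """
    f = float(fraction)
    if not (0.0 < f < 1.0):
        raise DataValidationError(f"fraction must lie in (0, 1), got {f!r}")
    return time_to_dimensionless(model, params, 1.0 - f)


def percent_extracted_at(model: ModelLike, params: ParameterVector, t) -> float:
    """Concentration at time t as a percentage of equilibrium: 100*(1 - X*)."""
    x_star = evaluate_dimensionless(model, params, t)
    return 100.0 * (1.0 - np.asarray(x_star)) if np.ndim(t) else 100.0 * (1.0 - x_star)


@dataclass(frozen=True)
class PredictionReport:
    """Bundle of derived quantities across experimental conditions."""

    x_eq: float
    equilibrium_tail: int
    target_fraction: float
    comparison_time_min: float
    #: condition -> raw process time in minutes at the target fraction
    process_times_min: Mapping[str, float]
    #: condition -> percent of equilibrium extracted at the comparison time
    percent_extracted: Mapping[str, float]
    #: condition -> (t, dX/dt) samples
    rate_curves: Mapping[str, tuple[tuple[float, ...], tuple[float, ...]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for cond, p in self.percent_extracted.items():
            if not (0.0 <= p <= 100.0):
                raise DataValidationError(
                    f"percent extracted for {cond!r} outside [0, 100]: {p}"
                )
        for cond, t in self.process_times_min.items():
            if t <= 0.0:
                raise DataValidationError(f"process time for {cond!r} not positive: {t}")

    def process_times_rounded(self) -> dict[str, int]:
        """Process times rounded to the nearest minute, for reports."""
        return {c: round(t) for c, t in self.process_times_min.items()}

    def to_dict(self) -> dict:
        return {
            "equilibrium": {
                "x_eq_mg_per_100g": self.x_eq,
                "tail_observations": self.equilibrium_tail,
            },
            "process_times": {
                "target_fraction": self.target_fraction,
                "minutes": dict(self.process_times_min),
                "minutes_rounded": self.process_times_rounded(),
            },
            "percent_extracted": {
                "at_time_min": self.comparison_time_min,
                "percent": dict(self.percent_extracted),
            },
            "rate_curve": {
                cond: {"t_min": list(ts), "rate_mg_per_100g_min": list(rs)}
                for cond, (ts, rs) in self.rate_curves.items()
            },
        }
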