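"""Nonlinear least-squares fitting of extraction-kinetics series.

A :class:`KineticsSeries` holds one experiment's time/concentration
observations.  Each empirical model is fitted in concentration space:
with the equilibrium concentration ``x_eq`` held fixed the predicted
curve is ``X(t) = x_eq * (1 - f(t; a, b))`` and the objective is the
unweighted residual sum of squares.  Goodness of fit is summarised by
chi-square — defined here as the residual sum of squares, with an
optional per-point sigma vector for users who have measurement
uncertainties — and the coefficient of determination R^2.  Models are
ranked by chi-square ascending, ties broken by R^2 then parsimony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (
    ModelLike,
    ParameterVector,
    evaluate_dimensionless,
    get_model,
)

__all__ = [
    "DataValidationError",
    "KineticsSeries",
    "FitResult",
    "ModelRanking",
    "goodness_of_fit",
    "initial_guess",
    "fit_model",
    "fit_all_models",
    "rank_models",
    "read_series_csv",
    "write_series_csv",
]

#: R^2 sentinel when the total sum of squares is zero (constant observations)
R2_UNDEFINED = float("nan")

_LOWER_BOUND = 1e-10
_FIT_TOL = 1e-10
_MAX_NFEV = 10_000


class DataValidationError(ValueError):
    """Input series violates the contract (ordering, lengths, degeneracy)."""


@dataclass(frozen=True)
class KineticsSeries:
    """One experiment: solvent-phase concentration vs time.

    times
        Strictly increasing sampling instants in minutes; the first may
        be 0 (where the noiseless concentration is 0).
    concentrations
        Nonnegative analyte concentrations in mg/100 g, same length.
    condition_label
        Free-text experimental condition, e.g. ``"150 rpm"``.
    temperature_c
        Extraction temperature in Celsius (metadata only).
    x_eq
        Optional known equilibrium concentration in mg/100 g.
    """

    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    condition_label: str = ""
    temperature_c: float = 35.0
    x_eq: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", tuple(t.tolist()))
        object.__setattr__(self, "concentrations", tuple(c.tolist()))
        if t.size != c.size:
            raise DataValidationError(
                f"times ({t.size}) and concentrations ({c.size}) differ in length"
            )
        if t.size == 0:
            raise DataValidationError("series is empty")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise DataValidationError("times and concentrations must be finite")
        if np.any(t < 0.0):
            raise DataValidationError("times must be >= 0")
        if np.any(np.diff(t) <= 0.0):
            raise DataValidationError("times must be strictly increasing")
        if np.any(c < 0.0):
            raise DataValidationError("concentrations must be >= 0")
        if self.x_eq is not None and self.x_eq <= 0.0:
            raise DataValidationError(f"x_eq must be > 0, got {self.x_eq}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "concentration": self.concentrations}
        )


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters and goodness-of-fit for one model on one series."""

    model_id: str
    params: ParameterVector
    x_eq: float
    chi_square: float
    r_squared: float
    n_obs: int
    converged: bool
    residuals: tuple[float, ...]
    condition_label: str = ""

    @property
    def n_params(self) -> int:
        return get_model(self.model_id).n_params

    def predicted(self, t) -> np.ndarray:
        """Model concentration x_eq * (1 - f(t)) at the given times."""
        return self.x_eq * (1.0 - np.asarray(
            evaluate_dimensionless(self.model_id, self.params, t)
        ))

    def to_row(self) -> dict:
        row = {
            "condition": self.condition_label,
            "model": self.model_id,
            "a": self.params.a,
            "b": self.params.b,
            "r_squared": self.r_squared,
            "chi_square": self.chi_square,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }
        return row


def goodness_of_fit(
    observed: Sequence[float],
    predicted: Sequence[float],
    sigma: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Chi-square and R^2 for a fitted curve.

    chi_square is the residual sum of squares, optionally weighted as
    sum((obs - pred)^2 / sigma^2) when per-point uncertainties are
    supplied.  r_squared is 1 - RSS/TSS about the observed mean; when
    the observations are constant (TSS = 0) it is reported as NaN.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise DataValidationError("observed and predicted must be 1-d of equal length")
    if obs.size < 2:
        raise DataValidationError("need at least 2 observations")
    resid = obs - pred
    if sigma is not None:
        w = np.asarray(sigma, dtype=float)
        if w.shape != obs.shape or np.any(w <= 0.0):
            raise DataValidationError("sigma must be positive and match observations")
        chi2 = float(np.sum((resid / w) ** 2))
    else:
        chi2 = float(np.sum(resid**2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        return chi2, R2_UNDEFINED
    rss = float(np.sum(resid**2))
    return chi2, 1.0 - rss / tss


# ---------------------------------------------------------------------------
# deterministic, derivative-free initial guesses
# ---------------------------------------------------------------------------


def initial_guess(model: ModelLike, series: KineticsSeries, x_eq: float) -> np.ndarray:
    """Starting parameters from linearisations of each model.

    Observed dimensionless values X*_i = 1 - X_i/x_eq with 0 < X* < 1
    (and t > 0) enter the initialisation only:

    - lewis / page: -ln X* vs t; lewis by a through-the-origin slope,
      page by an ordinary regression of ln(-ln X*) on ln t.
    - peleg: the linear form t/(1 - X*) = a + b t.
    - henderson_pabis: lewis's rate as b with a = 1.
    - silva: lewis's rate as a with a small b.
    """
    spec = get_model(model)
    t = series.t
    xstar = 1.0 - series.x / x_eq
    mask = (t > 0.0) & (xstar > 0.0) & (xstar < 1.0)
    tv, xv = t[mask], xstar[mask]

    def lewis_rate_guess() -> float:
        if tv.size == 0:
            return 0.05
        y = -np.log(xv)
        a0 = float(np.sum(tv * y) / np.sum(tv * tv))
        return a0 if a0 > 0.0 and math.isfinite(a0) else 0.05

    if spec.model_id == "lewis":
        return np.array([lewis_rate_guess()])
    if spec.model_id == "henderson_pabis":
        return np.array([1.0, lewis_rate_guess()])
    if spec.model_id == "silva":
        return np.array([lewis_rate_guess(), 0.01])
    if spec.model_id == "page":
        if tv.size >= 2:
            y = np.log(-np.log(xv))
            slope, intercept = np.polyfit(np.log(tv), y, 1)
            a0, b0 = float(np.exp(intercept)), float(slope)
            if math.isfinite(a0) and a0 > 0.0 and math.isfinite(b0) and b0 > 0.0:
                return np.array([a0, b0])
        return np.array([lewis_rate_guess(), 1.0])
    if spec.model_id == "peleg":
        if tv.size >= 2:
            w = tv / (1.0 - xv)
            b0, a0 = np.polyfit(tv, w, 1)
            if math.isfinite(a0) and a0 > 0.0 and math.isfinite(b0) and b0 > 0.0:
                return np.array([float(a0), float(b0)])
        a0 = 1.0 / lewis_rate_guess()
        return np.array([a0, 1.0])
    raise KeyError(spec.model_id)  # pragma: no cover


def fit_model(
    series: KineticsSeries,
    model: ModelLike,
    x_eq: float,
    *,
    free_x_eq: bool = False,
    sigma: Sequence[float] | None = None,
) -> FitResult:
    """Fit one model to a series by bounded nonlinear least squares.

    Minimises sum_i [X_i - x_eq * (1 - f(t_i; a, b))]^2 with ``x_eq``
    held fixed (the default) or freed as an extra parameter when
    ``free_x_eq=True``.  Fully deterministic: the start point comes from
    :func:`initial_guess` and the trust-region optimiser uses fixed
    tolerances (1e-10) and bounds (parameters >= 1e-10).
    """
    spec = get_model(model)
    if x_eq <= 0.0 or not math.isfinite(x_eq):
        raise DataValidationError(f"x_eq must be finite and > 0, got {x_eq}")
    n = len(series)
    if n < spec.n_params + 2:
        raise DataValidationError(
            f"need at least {spec.n_params + 2} observations to fit "
            f"{spec.model_id}, got {n}"
        )
    if np.all(series.x == 0.0):
        raise DataValidationError(
            f"series {series.condition_label!r} is all-zero; nothing to fit"
        )

    t, obs = series.t, series.x
    w = None
    if sigma is not None:
        w = np.asarray(sigma, dtype=float)
        if w.shape != obs.shape or np.any(w <= 0.0):
            raise DataValidationError("sigma must be positive and match observations")

    x0 = initial_guess(spec, series, x_eq)
    if free_x_eq:
        x0 = np.append(x0, x_eq)

    def unpack(theta: np.ndarray) -> tuple[ParameterVector, float]:
        k = spec.n_params
        pv = ParameterVector(theta[0]) if k == 1 else ParameterVector(theta[0], theta[1])
        return pv, (theta[k] if free_x_eq else x_eq)

    def resid(theta: np.ndarray) -> np.ndarray:
        pv, xe = unpack(theta)
        r = obs - xe * (1.0 - spec.forward(t, pv.a, pv.b))
        return r / w if w is not None else r

    x0 = np.maximum(x0, _LOWER_BOUND)
    sol = least_squares(
        resid,
        x0,
        bounds=(_LOWER_BOUND, np.inf),
        method="trf",
        ftol=_FIT_TOL,
        xtol=_FIT_TOL,
        gtol=_FIT_TOL,
        max_nfev=_MAX_NFEV,
    )
    pv, xe = unpack(sol.x)
    pred = xe * (1.0 - spec.forward(t, pv.a, pv.b))
    chi2, r2 = goodness_of_fit(obs, pred, sigma=sigma)
    return FitResult(
        model_id=spec.model_id,
        params=pv,
        x_eq=float(xe),
        chi_square=chi2,
        r_squared=r2,
        n_obs=n,
        converged=bool(sol.status > 0),
        residuals=tuple((obs - pred).tolist()),
        condition_label=series.condition_label,
    )


def fit_all_models(
    series: KineticsSeries,
    x_eq: float,
    models: Iterable[ModelLike] | None = None,
    **kwargs,
) -> list[FitResult]:
    """Fit every requested model (default: all five) to one series."""
    from .models import MODEL_IDS

    return [fit_model(series, m, x_eq, **kwargs) for m in (models or MODEL_IDS)]


@dataclass(frozen=True)
class ModelRanking:
    """Fit results ordered best-first by the ranking criterion."""

    results: tuple[FitResult, ...]

    @property
    def best(self) -> FitResult:
        return self.results[0]

    def to_frame(self) -> pd.DataFrame:
        """Report table: condition, model, a, b, R^2, chi-square."""
        return pd.DataFrame([r.to_row() for r in self.results])


def rank_models(results: Sequence[FitResult]) -> ModelRanking:
    """Order fits by chi-square ascending.

    Ties break by R^2 descending, then by fewer parameters (parsimony).
    """
    if not results:
        raise DataValidationError("rank_models needs at least one FitResult")

    def key(r: FitResult):
        r2 = -math.inf if math.isnan(r.r_squared) else r.r_squared
        return (r.chi_square, -r2, r.n_params)

    return ModelRanking(tuple(sorted(results, key=key)))


# ---------------------------------------------------------------------------
# CSV interchange: columns time_min, concentration [, condition]
# ---------------------------------------------------------------------------


def read_series_csv(
    path: str | Path,
    condition_label: str | None = None,
    temperature_c: float = 35.0,
) -> list[KineticsSeries]:
    """Read one or more series from a delimited text file.

    Wide form needs columns ``time_min`` and ``concentration`` (one
    condition per file); long form adds a ``condition`` column and
    yields one series per distinct condition, in order of appearance.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataValidationError(f"input file {path} is empty") from None
    missing = {"time_min", "concentration"} - set(df.columns)
    if missing:
        raise DataValidationError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    if df.empty:
        raise DataValidationError(f"input file {path} has no data rows")

    def build(sub: pd.DataFrame, label: str) -> KineticsSeries:
        sub = sub.sort_values("time_min")
        return KineticsSeries(
            times=tuple(sub["time_min"].astype(float)),
            concentrations=tuple(sub["concentration"].astype(float)),
            condition_label=label,
            temperature_c=temperature_c,
        )

    if "condition" in df.columns:
        return [
            build(df[df["condition"] == cond], str(cond))
            for cond in df["condition"].drop_duplicates()
        ]
    return [build(df, condition_label if condition_label is not None else path.stem)]


def write_series_csv(series: KineticsSeries, path: str | Path) -> None:
    """Write a series in the same dialect :func:`read_series_csv` reads."""
    series.to_frame().to_csv(path, index=False)
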