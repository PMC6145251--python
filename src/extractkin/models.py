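"""Empirical kinetic models for solid–liquid extraction.

Five one- and two-parameter model families widely used for sorption,
drying, and extraction kinetics, each expressed on the dimensionless
concentration scale

    X*(t) = (X(t) - X_eq) / (X_i - X_eq),

which runs from 1 at the start of the process to 0 at equilibrium.  With
zero initial solvent-phase concentration (X_i = 0) the observable
concentration is X(t) = X_eq * (1 - X*(t)).

Each model carries three closed-form expressions:

===================  =======================  =========================
model                X* = f(t; a, b)          inverse t(X*)
===================  =======================  =========================
lewis                exp(-a t)                -ln X* / a
henderson_pabis      a exp(-b t)              -ln(X*/a) / b
peleg                1 - t/(a + b t)          a (1 - X*) / (1 - b + b X*)
page                 exp(-a t^b)              (-ln X* / a)^(1/b)
silva                exp(-a t - b sqrt(t))    positive root of
                                              a u^2 + b u + ln X* = 0,
                                              t = u^2
===================  =======================  =========================

together with the analytic derivative df/dt used for extraction-rate
curves.  Time is in minutes throughout; parameter units are metadata
only (e.g. ``a`` is min^-1 for lewis, min^-b for page, min for peleg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Union

import numpy as np

__all__ = [
    "ParameterDomainError",
    "UnreachableConcentrationError",
    "ParameterVector",
    "ModelSpec",
    "MODEL_REGISTRY",
    "MODEL_IDS",
    "get_model",
    "evaluate_dimensionless",
    "dimensionless_rate",
    "time_to_dimensionless",
]


class ParameterDomainError(ValueError):
    """A parameter or evaluation point lies outside a model's domain."""


class UnreachableConcentrationError(ValueError):
    """The requested dimensionless concentration is never attained.

    Raised e.g. for the Peleg model when ``x_star`` lies at or below the
    asymptote ``1 - 1/b`` (reached only as t -> infinity), or for
    Henderson–Pabis when ``x_star`` exceeds the t=0 value ``a``.
    """


@dataclass(frozen=True)
class ParameterVector:
    """Parameters of one empirical model.

    ``a`` is required and positive for every model; ``b`` is present
    (and positive) exactly for the two-parameter models, i.e. all of
    them except ``lewis``.
    """

    a: float
    b: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.a) or self.a <= 0.0:
            raise ParameterDomainError(f"parameter a must be finite and > 0, got {self.a!r}")
        if self.b is not None and (not math.isfinite(self.b) or self.b <= 0.0):
            raise ParameterDomainError(f"parameter b must be finite and > 0, got {self.b!r}")

    def to_dict(self) -> dict[str, float]:
        """Flat name -> value mapping (JSON-friendly)."""
        out = {"a": float(self.a)}
        if self.b is not None:
            out["b"] = float(self.b)
        return out

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterVector":
        unknown = set(mapping) - {"a", "b"}
        if unknown:
            raise ParameterDomainError(f"unknown parameter names: {sorted(unknown)}")
        if "a" not in mapping:
            raise ParameterDomainError("parameter mapping must contain 'a'")
        return cls(a=float(mapping["a"]), b=float(mapping["b"]) if "b" in mapping else None)


# ---------------------------------------------------------------------------
# forward / derivative / inverse expressions, vectorised over t
# ---------------------------------------------------------------------------


def _lewis_f(t: np.ndarray, a: float, b: float | None) -> np.ndarray:
    return np.exp(-a * t)


def _lewis_rate(t: np.ndarray, a: float, b: float | None) -> np.ndarray:
    return -a * np.exp(-a * t)


def _lewis_inv(x: float, a: float, b: float | None) -> float:
    return -math.log(x) / a


def _hp_f(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.exp(-b * t)


def _hp_rate(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return -a * b * np.exp(-b * t)


def _hp_inv(x: float, a: float, b: float) -> float:
    ratio = x / a
    if ratio > 1.0:
        raise UnreachableConcentrationError(
            f"henderson_pabis starts at X*(0) = a = {a}; X* = {x} is never attained"
        )
    return -math.log(ratio) / b


def _peleg_f(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return 1.0 - t / (a + b * t)


def _peleg_rate(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return -a / (a + b * t) ** 2


def _peleg_inv(x: float, a: float, b: float) -> float:
    denom = 1.0 - b + b * x
    if denom <= 0.0:
        raise UnreachableConcentrationError(
            f"peleg approaches X* = 1 - 1/b = {1.0 - 1.0 / b:.6g} only as t -> inf; "
            f"X* = {x} is unreachable"
        )
    return a * (1.0 - x) / denom


def _page_f(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return np.exp(-a * np.power(t, b))


def _page_rate(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return -a * b * np.power(t, b - 1.0) * np.exp(-a * np.power(t, b))


def _page_inv(x: float, a: float, b: float) -> float:
    return (-math.log(x) / a) ** (1.0 / b)


def _silva_f(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return np.exp(-a * t - b * np.sqrt(t))


def _silva_rate(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return -(a + 0.5 * b / np.sqrt(t)) * np.exp(-a * t - b * np.sqrt(t))


def _silva_inv(x: float, a: float, b: float) -> float:
    # a u^2 + b u + ln x = 0 with u = sqrt(t) >= 0; ln x <= 0 so the
    # discriminant b^2 - 4 a ln x >= b^2 and only the "+" root is >= 0.
    u = (-b + math.sqrt(b * b - 4.0 * a * math.log(x))) / (2.0 * a)
    return u * u


@dataclass(frozen=True)
class ModelSpec:
    """Identity and algebra of one empirical extraction model."""

    model_id: str
    n_params: int
    param_names: tuple[str, ...]
    forward: Callable[..., np.ndarray]
    rate: Callable[..., np.ndarray]
    inverse: Callable[..., float]
    #: smallest t at which the analytic rate is finite for all valid
    #: parameters (silva and page-with-b<1 diverge as t -> 0+)
    rate_singular_at_zero: bool

    def rate_is_singular(self, params: ParameterVector) -> bool:
        if self.model_id == "page":
            return params.b is not None and params.b < 1.0
        return self.rate_singular_at_zero


MODEL_REGISTRY: dict[str, ModelSpec] = {
    "lewis": ModelSpec("lewis", 1, ("a",), _lewis_f, _lewis_rate, _lewis_inv, False),
    "henderson_pabis": ModelSpec(
        "henderson_pabis", 2, ("a", "b"), _hp_f, _hp_rate, _hp_inv, False
    ),
    "peleg": ModelSpec("peleg", 2, ("a", "b"), _peleg_f, _peleg_rate, _peleg_inv, False),
    "page": ModelSpec("page", 2, ("a", "b"), _page_f, _page_rate, _page_inv, True),
    "silva": ModelSpec("silva", 2, ("a", "b"), _silva_f, _silva_rate, _silva_inv, True),
}

MODEL_IDS: tuple[str, ...] = tuple(MODEL_REGISTRY)

ModelLike = Union[str, ModelSpec]


def get_model(model: ModelLike) -> ModelSpec:
    """Resolve a model name or spec to its :class:`ModelSpec`."""
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODEL_REGISTRY[model]
    except KeyError:
        raise KeyError(
            f"unknown model {model!r}; available: {', '.join(MODEL_IDS)}"
        ) from None


def _check_params(spec: ModelSpec, params: ParameterVector) -> None:
    if spec.model_id == "lewis":
        if params.b is not None:
            raise ParameterDomainError("lewis takes a single parameter a; b must be absent")
    elif params.b is None:
        raise ParameterDomainError(f"{spec.model_id} requires both parameters a and b")


def _as_time_array(t, allow_zero: bool = True):
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ParameterDomainError("time values must be finite")
    if allow_zero:
        if np.any(arr < 0.0):
            raise ParameterDomainError("time values must be >= 0")
    elif np.any(arr <= 0.0):
        raise ParameterDomainError("time values must be > 0")
    return arr, np.ndim(t) == 0


def evaluate_dimensionless(model: ModelLike, params: ParameterVector, t):
    """Dimensionless concentration X* = f(t; a, b) for one model.

    ``t`` (minutes, >= 0) may be a scalar or array.  X* lies in [0, 1]
    for every model except henderson_pabis, whose t=0 value is ``a``.
    """
    spec = get_model(model)
    _check_params(spec, params)
    arr, scalar = _as_time_array(t, allow_zero=True)
    out = spec.forward(arr, params.a, params.b)
    return float(out) if scalar else out


def dimensionless_rate(model: ModelLike, params: ParameterVector, t):
    """Analytic derivative dX*/dt (per minute), always <= 0 on its domain.

    For models whose rate diverges as t -> 0+ (silva, and page with
    b < 1) the evaluation requires t > 0 and raises
    :class:`ParameterDomainError` naming the singularity otherwise.
    """
    spec = get_model(model)
    _check_params(spec, params)
    singular = spec.rate_is_singular(params)
    arr, scalar = _as_time_array(t, allow_zero=True)
    if singular and np.any(arr <= 0.0):
        raise ParameterDomainError(
            f"the {spec.model_id} rate diverges as t -> 0+; require t > 0"
        )
    out = spec.rate(arr, params.a, params.b)
    return float(out) if scalar else out


def time_to_dimensionless(model: ModelLike, params: ParameterVector, x_star: float) -> float:
    """Time (minutes) at which X* first equals ``x_star`` in (0, 1].

    Uses each model's closed-form inverse.  Raises
    :class:`UnreachableConcentrationError` when the model never reaches
    ``x_star`` (Peleg below its asymptote, Henderson–Pabis above a).
    """
    spec = get_model(model)
    _check_params(spec, params)
    x = float(x_star)
    if not (0.0 < x <= 1.0):
        raise ParameterDomainError(f"x_star must lie in (0, 1], got {x!r}")
    t = spec.inverse(x, params.a, params.b)
    # guard against tiny negative round-off at x_star = 1
    return max(t, 0.0)
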