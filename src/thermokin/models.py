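"""Closed-form residual-activity models for enzyme thermal inactivation.

Eight kinetic models classically used to describe the loss of enzyme
activity during isothermal heating, each expressed as the residual-activity
fraction A/A0 as a function of heating time t (in minutes):

======================  =====================================================
model id                A/A0(t)
======================  =====================================================
first_order             exp(-k t)
weibull                 exp(-b t^n)
distinct_isoenzymes     A_L exp(-k_L t) + A_S exp(-k_R t)
two_fraction            a exp(-k_L t) + (1 - a) exp(-k_R t)
multicomponent          [exp(-k_1 t) + r exp(-k_2 t)] / (1 + r)
series_type             two sequential first-order steps, native -> partially
                        active intermediate (specific activity alpha_1) ->
                        inactive; the fully inactive end state (alpha_2 = 0)
                        is the default, the general end state is available by
                        passing alpha_2 explicitly
nth_order               [1 + (n - 1) k t]^(1/(1-n)),  n != 1
fractional_conversion   A_r + (1 - A_r) exp(-k t)
======================  =====================================================

Conventions
-----------
* Activities are fractions: curves are normalised so A/A0(0) = 1. For the
  nth-order model this fixes A0 = 1; for fractional conversion the residual
  plateau A_r is itself a fraction of A0.
* All rate constants (k, k_L, k_R, k_1, k_2) are in min^-1; the Weibull
  scale b is in min^-n; fractions and shape factors are dimensionless.
* The series-type model as printed gives A/A0(0) = 1 + alpha_2; the package
  therefore uses the alpha_2 = 0 restriction by default, which is the usual
  "fully deactivated end state" reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .exceptions import (
    ConfigurationError,
    DomainError,
    SingularParameterizationError,
)

__all__ = [
    "ModelSpec",
    "MODEL_IDS",
    "model_catalog",
    "get_model_spec",
    "evaluate_model",
    "weibull_to_alpha",
    "alpha_to_weibull_scale",
]


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one inactivation model.

    ``param_bounds`` are *not* fitting constraints — estimation is
    unconstrained — they only delimit the region in which multi-start
    initial values are generated.
    """

    model_id: str
    param_names: tuple[str, ...]
    #: admissible interval per parameter, used only to stabilise initial values
    param_bounds: Mapping[str, tuple[float, float]] = field(repr=False, default_factory=dict)
    #: name of the parameter acting as the principal inactivation rate
    #: (None for the Weibull model, whose temperature dependence lives in b)
    primary_rate: str | None = None
    description: str = ""

    @property
    def n_params(self) -> int:
        return len(self.param_names)


_RATE_BOUNDS = (1e-6, 1.0)
_FRACTION_BOUNDS = (0.0, 1.0)


def _spec(model_id, names, bounds, primary_rate, description):
    return ModelSpec(model_id, tuple(names), dict(bounds), primary_rate, description)


_SPECS: tuple[ModelSpec, ...] = (
    _spec(
        "first_order",
        ("k",),
        {"k": _RATE_BOUNDS},
        "k",
        "single-exponential decay of one homogeneous enzyme population",
    ),
    _spec(
        "weibull",
        ("b", "n"),
        {"b": (1e-12, 1.0), "n": (0.05, 12.0)},
        None,
        "stretched-exponential decay; n>1 gives downward-concave semilog curves",
    ),
    _spec(
        "distinct_isoenzymes",
        ("A_L", "A_S", "k_L", "k_R"),
        {"A_L": (0.0, 2.0), "A_S": (0.0, 2.0), "k_L": _RATE_BOUNDS, "k_R": _RATE_BOUNDS},
        "k_L",
        "two isoenzymes with free amplitudes and distinct first-order rates",
    ),
    _spec(
        "two_fraction",
        ("a", "k_L", "k_R"),
        {"a": _FRACTION_BOUNDS, "k_L": _RATE_BOUNDS, "k_R": _RATE_BOUNDS},
        "k_L",
        "labile fraction a and stable fraction 1-a, each first-order",
    ),
    _spec(
        "multicomponent",
        ("k_1", "k_2", "r"),
        {"k_1": _RATE_BOUNDS, "k_2": _RATE_BOUNDS, "r": (0.0, 10.0)},
        "k_1",
        "sum of two first-order components with abundance ratio r",
    ),
    _spec(
        "series_type",
        ("alpha_1", "k_1", "k_2"),
        {"alpha_1": _FRACTION_BOUNDS, "k_1": _RATE_BOUNDS, "k_2": _RATE_BOUNDS},
        "k_1",
        "sequential native -> intermediate -> inactive, intermediate activity alpha_1",
    ),
    _spec(
        "nth_order",
        ("k", "n"),
        {"k": _RATE_BOUNDS, "n": (0.2, 5.0)},
        "k",
        "single decay of reaction order n != 1 (A0 normalised to 1)",
    ),
    _spec(
        "fractional_conversion",
        ("A_r", "k"),
        {"A_r": _FRACTION_BOUNDS, "k": _RATE_BOUNDS},
        "k",
        "first-order decay onto a heat-resistant residual plateau A_r",
    ),
)

_SPEC_BY_ID = {s.model_id: s for s in _SPECS}

MODEL_IDS: tuple[str, ...] = tuple(s.model_id for s in _SPECS)


def model_catalog() -> list[ModelSpec]:
    """Return the eight model specs in their canonical order."""
    return list(_SPECS)


def get_model_spec(model_id: str) -> ModelSpec:
    try:
        return _SPEC_BY_ID[model_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown model_id {model_id!r}; known ids: {', '.join(MODEL_IDS)}"
        ) from None


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def _first_order(t, k):
    return np.exp(-k * t)


def _weibull(t, b, n):
    return np.exp(-b * np.power(t, n))


def _distinct_isoenzymes(t, A_L, A_S, k_L, k_R):
    return A_L * np.exp(-k_L * t) + A_S * np.exp(-k_R * t)


def _two_fraction(t, a, k_L, k_R):
    return a * np.exp(-k_L * t) + (1.0 - a) * np.exp(-k_R * t)


def _multicomponent(t, k_1, k_2, r):
    return (np.exp(-k_1 * t) + r * np.exp(-k_2 * t)) / (1.0 + r)


def _series_type(t, alpha_1, k_1, k_2, alpha_2=0.0):
    if abs(k_2 - k_1) <= 1e-12 * max(abs(k_1), abs(k_2), 1e-30):
        raise SingularParameterizationError(
            "series_type model is singular for k_1 == k_2"
        )
    c = (alpha_1 * k_1 - alpha_2 * k_2) / (k_2 - k_1)
    return alpha_2 + (1.0 + c) * np.exp(-k_1 * t) - c * np.exp(-k_2 * t)


def _nth_order(t, k, n):
    if n == 1.0:
        raise DomainError("nth_order model requires n != 1 (use first_order)")
    base = 1.0 + (n - 1.0) * k * t
    if np.any(base <= 0.0):
        raise DomainError(
            "nth_order model undefined: 1 + (n-1)*k*t must stay positive"
        )
    return np.power(base, 1.0 / (1.0 - n))


def _fractional_conversion(t, A_r, k):
    return A_r + (1.0 - A_r) * np.exp(-k * t)


_EVALUATORS: dict[str, Callable] = {
    "first_order": _first_order,
    "weibull": _weibull,
    "distinct_isoenzymes": _distinct_isoenzymes,
    "two_fraction": _two_fraction,
    "multicomponent": _multicomponent,
    "series_type": _series_type,
    "nth_order": _nth_order,
    "fractional_conversion": _fractional_conversion,
}


def evaluate_model(spec: ModelSpec | str, params: Mapping[str, float], t):
    """Residual-activity fraction A/A0 of ``spec`` at time(s) ``t`` (min).

    Parameters
    ----------
    spec
        A :class:`ModelSpec` or a model id string.
    params
        Mapping of parameter symbol to value. Must contain every symbol in
        ``spec.param_names``; the series-type model additionally accepts an
        optional ``alpha_2`` for the general (non-zero end state) form.
    t
        Scalar or array of times, min, all >= 0.

    Returns
    -------
    float or numpy.ndarray matching the shape of ``t``.
    """
    if isinstance(spec, str):
        spec = get_model_spec(spec)
    elif spec.model_id not in _SPEC_BY_ID:
        raise ConfigurationError(f"unknown model_id {spec.model_id!r}")

    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time t must be nonnegative")

    kwargs = {}
    for name in spec.param_names:
        if name not in params:
            raise ConfigurationError(
                f"model {spec.model_id!r} requires parameter {name!r}"
            )
        value = float(params[name])
        if not math.isfinite(value):
            raise ConfigurationError(
                f"parameter {name!r} of model {spec.model_id!r} is not finite"
            )
        kwargs[name] = value
    if spec.model_id == "series_type" and "alpha_2" in params:
        kwargs["alpha_2"] = float(params["alpha_2"])

    result = _EVALUATORS[spec.model_id](t_arr, **kwargs)
    if np.ndim(t) == 0:
        return float(result)
    return np.asarray(result, dtype=float)


# ---------------------------------------------------------------------------
# Weibull scale reparameterisation
# ---------------------------------------------------------------------------

def weibull_to_alpha(b: float, n: float) -> float:
    """Convert the Weibull scale b (min^-n) to the time-scale alpha (min).

    alpha = b**(-1/n), the characteristic time of the stretched
    exponential; 1/alpha behaves as an apparent first-order rate and is the
    quantity used in Arrhenius analysis of Weibull kinetics.
    """
    if not (b > 0.0) or not (n > 0.0):
        raise DomainError("weibull_to_alpha requires b > 0 and n > 0")
    return float(b ** (-1.0 / n))


def alpha_to_weibull_scale(alpha: float, n: float) -> float:
    """Inverse of :func:`weibull_to_alpha`: b = 1 / alpha**n."""
    if not (alpha > 0.0) or not (n > 0.0):
        raise DomainError("alpha_to_weibull_scale requires alpha > 0 and n > 0")
    return float(alpha ** (-n))
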