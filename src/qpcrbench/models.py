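"""Parametric amplification-curve models.

Five model families are registered:

``b4``    f(x) = c + (d - c) / (1 + exp(b (x - e)))
``b5``    f(x) = c + (d - c) / (1 + exp(b (x - e)))**f
``l4``    f(x) = c + (d - c) / (1 + exp(b (ln x - ln e)))
``l5``    f(x) = c + (d - c) / (1 + exp(b (ln x - ln e)))**f
``linexp`` f(x) = a exp(k x) + m x + o

with b the slope parameter, c/d the lower/upper asymptotes (fluorescence),
e the location (cycles) and f a dimensionless asymmetry exponent.  For an
increasing sigmoid b < 0.  Each spec carries the analytic second derivative
with respect to cycle, used by the cpD2 estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["SigmoidModelSpec", "MODEL_REGISTRY", "get_model", "list_models"]

_EXP_CLIP = 700.0  # exp overflow guard


def _safe_exp(u: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(u, -_EXP_CLIP, _EXP_CLIP))


# -- predictions -----------------------------------------------------------


def _b4(x, b, c, d, e):
    return c + (d - c) / (1.0 + _safe_exp(b * (x - e)))


def _b5(x, b, c, d, e, f):
    return c + (d - c) / (1.0 + _safe_exp(b * (x - e))) ** f


def _l4(x, b, c, d, e):
    return c + (d - c) / (1.0 + _safe_exp(b * (np.log(x) - np.log(e))))


def _l5(x, b, c, d, e, f):
    return c + (d - c) / (1.0 + _safe_exp(b * (np.log(x) - np.log(e)))) ** f


def _linexp(x, a, k, m, o):
    return a * _safe_exp(k * x) + m * x + o


# -- analytic second derivatives ------------------------------------------


def _b5_d2(x, b, c, d, e, f=1.0):
    # g = (1+z)^(-f), z = exp(b(x-e));  g'' = -f b^2 z (1 - f z) (1+z)^(-f-2)
    z = _safe_exp(b * (x - e))
    return (d - c) * (-f * b * b) * z * (1.0 - f * z) * (1.0 + z) ** (-f - 2.0)


def _b4_d2(x, b, c, d, e):
    return _b5_d2(x, b, c, d, e, 1.0)


def _l5_d2(x, b, c, d, e, f=1.0):
    # z = (x/e)^b; g'' = -f b z / x^2 (1+z)^(-f-2) [ (b-1)(1+z) - (f+1) b z ]
    z = _safe_exp(b * (np.log(x) - np.log(e)))
    bracket = (b - 1.0) * (1.0 + z) - (f + 1.0) * b * z
    return (d - c) * (-f * b) * z / (x * x) * (1.0 + z) ** (-f - 2.0) * bracket


def _l4_d2(x, b, c, d, e):
    return _l5_d2(x, b, c, d, e, 1.0)


def _linexp_d2(x, a, k, m, o):
    return a * k * k * _safe_exp(k * np.asarray(x, dtype=float))


# -- closed-form curvature maxima ------------------------------------------


def _b5_d2_argmax(b, c, d, e, f=1.0):
    """Interior argmax of the b4/b5 second derivative.

    Setting d(f'')/dx = 0 gives f^2 z^2 - (3f+1) z + 1 = 0 in z = exp(b(x-e));
    the larger root lies in the region where f'' > 0 (for d > c, b < 0) and is
    the curvature maximum: x* = e + ln(z*)/b.  For f = 1 this reduces to
    z* = 2 + sqrt(3).
    """
    disc = (3.0 * f + 1.0) ** 2 - 4.0 * f * f
    z_star = ((3.0 * f + 1.0) + np.sqrt(disc)) / (2.0 * f * f)
    return e + np.log(z_star) / b


def _b4_d2_argmax(b, c, d, e):
    return _b5_d2_argmax(b, c, d, e, 1.0)


# -- initialization and bounds ---------------------------------------------


def _sigmoid_init(cycles: np.ndarray, y: np.ndarray, log_x: bool, five: bool) -> np.ndarray:
    """Starting values: asymptotes from the data range, location at the
    steepest observed rise, slope from the local finite-difference slope."""
    ymin, ymax = float(np.min(y)), float(np.max(y))
    span = ymax - ymin
    dy = np.diff(y)
    i = int(np.argmax(dy))
    e0 = float(0.5 * (cycles[i] + cycles[i + 1]))
    slope = max(float(dy[i] / (cycles[i + 1] - cycles[i])), 1e-6)
    # at x=e the sigmoid's slope is -b (d-c)/4 (raw x) or -b (d-c)/(4 e) (log x)
    if log_x:
        b0 = -4.0 * e0 * slope / max(span, 1e-12)
    else:
        b0 = -4.0 * slope / max(span, 1e-12)
    b0 = float(np.clip(b0, -45.0, -1e-3))
    params = [b0, ymin, ymax, e0]
    if five:
        params.append(1.0)
    return np.array(params, dtype=float)


def _sigmoid_bounds(cycles: np.ndarray, y: np.ndarray, five: bool):
    ymin, ymax = float(np.min(y)), float(np.max(y))
    span = max(ymax - ymin, 1e-12)
    C = float(np.max(cycles))
    lo = [-50.0, ymin - span, ymin + 0.5 * span, 0.5]
    hi = [-1e-4, ymin + 0.5 * span - 1e-12, ymax + 3.0 * span, 3.0 * C]
    if five:
        lo.append(0.05)
        hi.append(10.0)
    return np.array(lo), np.array(hi)


def _linexp_init(cycles: np.ndarray, y: np.ndarray, five: bool) -> np.ndarray:
    ymin, ymax = float(np.min(y)), float(np.max(y))
    span = max(ymax - ymin, 1e-12)
    C = float(np.max(cycles))
    k0 = 0.15
    a0 = span / np.exp(k0 * C)
    m0 = 0.0
    o0 = ymin
    return np.array([a0, k0, m0, o0], dtype=float)


def _linexp_bounds(cycles: np.ndarray, y: np.ndarray, five: bool):
    ymin, ymax = float(np.min(y)), float(np.max(y))
    span = max(ymax - ymin, 1e-12)
    lo = np.array([0.0, 1e-4, -span, ymin - 2 * span])
    hi = np.array([10.0 * span, 2.0, span, ymax + 2 * span])
    return lo, hi


@dataclass(frozen=True)
class SigmoidModelSpec:
    """One parametric curve family: prediction, curvature, fit scaffolding."""

    model_id: str
    param_names: tuple[str, ...]
    predict: Callable[..., np.ndarray]
    second_derivative: Callable[..., np.ndarray]
    initial_params: Callable[[np.ndarray, np.ndarray], np.ndarray]
    bounds: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
    #: exact interior argmax of the second derivative, where a closed form exists
    d2_argmax: Callable[..., float] | None = None

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __call__(self, x, params: Sequence[float]):
        return self.predict(x, *params)


def _sigmoid_spec(model_id: str, predict, d2, five: bool) -> SigmoidModelSpec:
    log_x = model_id.startswith("l")
    names = ("b", "c", "d", "e", "f") if five else ("b", "c", "d", "e")
    return SigmoidModelSpec(
        model_id=model_id,
        param_names=names,
        predict=predict,
        second_derivative=d2,
        initial_params=lambda cy, y: _sigmoid_init(cy, y, log_x, five),
        bounds=lambda cy, y: _sigmoid_bounds(cy, y, five),
        d2_argmax=None if log_x else (_b5_d2_argmax if five else _b4_d2_argmax),
    )


MODEL_REGISTRY: dict[str, SigmoidModelSpec] = {
    "b4": _sigmoid_spec("b4", _b4, _b4_d2, five=False),
    "b5": _sigmoid_spec("b5", _b5, _b5_d2, five=True),
    "l4": _sigmoid_spec("l4", _l4, _l4_d2, five=False),
    "l5": _sigmoid_spec("l5", _l5, _l5_d2, five=True),
    "linexp": SigmoidModelSpec(
        model_id="linexp",
        param_names=("a", "k", "m", "o"),
        predict=_linexp,
        second_derivative=_linexp_d2,
        initial_params=lambda cy, y: _linexp_init(cy, y, False),
        bounds=lambda cy, y: _linexp_bounds(cy, y, False),
    ),
}


def get_model(model_id: str) -> SigmoidModelSpec:
    try:
        return MODEL_REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {', '.join(sorted(MODEL_REGISTRY))}"
        ) from None


def list_models() -> list[str]:
    return sorted(MODEL_REGISTRY)
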