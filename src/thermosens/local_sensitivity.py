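"""Normalized local sensitivity coefficients (elasticities) by finite differences.

The local coefficient of an objective C with respect to a parameter mu is the
dimensionless elasticity (mu / C) * (dC / dmu): the relative change in the
objective per relative change in the parameter.  It is estimated by central
differences with a relative step, falling back to one-sided differences when a
declared range edge would otherwise be crossed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .parameter_space import ParameterSpace

__all__ = ["LocalSensitivityResult", "local_coefficient", "local_profile"]

DEFAULT_REL_STEP = 1e-4
ABS_STEP_FLOOR = 1e-6


@dataclass
class LocalSensitivityResult:
    names: tuple[str, ...]
    point: np.ndarray
    coefficients: np.ndarray  # signed elasticities; NaN marks undefined entries
    scaled: np.ndarray        # |coefficient| / max |coefficient|, in [0, 1]
    step: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.names, "coefficient": self.coefficients, "scaled": self.scaled}
        )


def _bounded_step(mu: float, rel_step: float, lower: float, upper: float) -> tuple[float, float]:
    h = max(rel_step * abs(mu), ABS_STEP_FLOOR)
    hi = min(mu + h, upper)
    lo = max(mu - h, lower)
    return lo, hi


def local_coefficient(
    objective: Callable[[np.ndarray], float],
    point: np.ndarray,
    param_index: int,
    rel_step: float = DEFAULT_REL_STEP,
    space: Optional[ParameterSpace] = None,
    value_at_point: Optional[float] = None,
) -> float:
    """Elasticity (mu/C)(dC/dmu) at a point, by (clipped) central differences.

    Returns NaN with a warning when the coefficient is undefined (objective or
    parameter value is zero, so relative normalization is impossible).
    ``value_at_point`` may pass a precomputed C(point) to save one evaluation.
    """
    point = np.asarray(point, dtype=float)
    mu = point[param_index]
    C0 = objective(point) if value_at_point is None else value_at_point
    if C0 == 0.0 or not np.isfinite(C0):
        warnings.warn(
            f"objective is {C0} at the evaluation point: elasticity undefined", stacklevel=2
        )
        return float("nan")
    if mu == 0.0:
        warnings.warn(
            f"parameter {param_index} is 0 at the evaluation point: elasticity undefined",
            stacklevel=2,
        )
        return float("nan")
    if space is None:
        lower, upper = -np.inf, np.inf
    else:
        p = space.parameters[param_index]
        lower, upper = p.lower, p.upper
    lo, hi = _bounded_step(mu, rel_step, lower, upper)
    if hi == lo:
        warnings.warn(f"parameter {param_index}: degenerate range, elasticity undefined", stacklevel=2)
        return float("nan")
    x = point.copy()
    x[param_index] = hi
    f_hi = objective(x)
    x[param_index] = lo
    f_lo = objective(x)
    deriv = (f_hi - f_lo) / (hi - lo)
    return float(mu / C0 * deriv)


def local_profile(
    objective: Callable[[np.ndarray], float],
    point: np.ndarray,
    rel_step: float = DEFAULT_REL_STEP,
    space: Optional[ParameterSpace] = None,
) -> LocalSensitivityResult:
    """Elasticities for every parameter at a point, plus 0-to-1 scaled values.

    Undefined coefficients propagate as NaN and are excluded from the scaling
    maximum.
    """
    point = np.asarray(point, dtype=float)
    if space is not None:
        names = space.names
    else:
        names = tuple(f"p{i}" for i in range(point.size))
    C0 = objective(point)
    coeffs = np.array(
        [
            local_coefficient(objective, point, i, rel_step, space, value_at_point=C0)
            for i in range(point.size)
        ]
    )
    finite = np.abs(coeffs[np.isfinite(coeffs)])
    top = finite.max() if finite.size else 0.0
    if top > 0:
        scaled = np.abs(coeffs) / top
    else:
        scaled = np.where(np.isfinite(coeffs), 0.0, np.nan)
    return LocalSensitivityResult(
        names=names, point=point, coefficients=coeffs, scaled=scaled, step=rel_step
    )
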