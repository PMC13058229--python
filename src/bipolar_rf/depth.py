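"""Lesion-depth inversion of a fitted transmurality model.

A transmurality model over (power, duration, initial impedance, thickness),
combined with the linear impedance–thickness relation Z0(t) = a + b*t, gives a
probability of transmural lesion formation as a function of thickness alone
once power and duration are fixed.  "Achievable lesion depth" is
operationalised as the thickness t* at which that probability crosses a target
level (default 0.5): tissue thinner than t* is expected to be lesioned through,
thicker tissue is not.  This requires the substituted logit to *decrease* in
thickness (coef_thickness + coef_impedance * b < 0); a model violating that has
no meaningful depth and is rejected.

The same linear logit solves in closed form for the duration required to make
a given thickness transmural at a given power; solutions outside the bench
protocol's tested 20–180 s range are flagged as extrapolation, and a negative
solution means the target is already exceeded at 0 s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidInputError, NoRootError
from .glm import FittedModel, sigmoid

#: default impedance–thickness relation (ohms from mm)
IMPEDANCE_INTERCEPT = 86.213122
IMPEDANCE_SLOPE = 0.5057449

#: tested protocol range of RF durations (s); outside it, flag extrapolation
TESTED_DURATION_RANGE = (20.0, 180.0)

DEPTH_PREDICTORS = ("rf_power", "init_impedance", "rf_duration", "thickness")


@dataclass(frozen=True)
class InversionQuery:
    rf_power: float
    rf_duration: float
    target_probability: float = 0.5
    thickness_bracket: tuple[float, float] = (1.0, 40.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.target_probability < 1.0):
            raise InvalidInputError("target probability must be in (0, 1)")
        lo, hi = self.thickness_bracket
        if not lo < hi:
            raise InvalidInputError("thickness bracket must satisfy lo < hi")


@dataclass
class DurationResult:
    seconds: float
    extrapolated: bool
    status: str  # "ok" | "extrapolated" | "already exceeded at 0 s"


def _coefs(model: FittedModel) -> dict[str, float]:
    missing = [p for p in DEPTH_PREDICTORS if p not in model.coefficients]
    if missing:
        raise InvalidInputError(
            f"model must include predictors {DEPTH_PREDICTORS}; missing {missing}"
        )
    return model.coefficients


def _logit_of_thickness(
    model: FittedModel,
    rf_power: float,
    rf_duration: float,
    impedance_relation: tuple[float, float],
) -> Callable[[float], float]:
    """L(t) with Z0(t) substituted — affine in t."""
    c = _coefs(model)
    a, b = impedance_relation
    def L(t: float) -> float:
        return (
            model.intercept
            + c["rf_power"] * rf_power
            + c["rf_duration"] * rf_duration
            + c["init_impedance"] * (a + b * t)
            + c["thickness"] * t
        )
    return L


def thickness_slope(model: FittedModel,
                    impedance_relation: tuple[float, float] = (
                        IMPEDANCE_INTERCEPT, IMPEDANCE_SLOPE)) -> float:
    """d logit / d thickness after impedance substitution."""
    c = _coefs(model)
    return c["thickness"] + c["init_impedance"] * impedance_relation[1]


def predict_depth(
    model: FittedModel,
    query: InversionQuery,
    impedance_relation: tuple[float, float] = (IMPEDANCE_INTERCEPT, IMPEDANCE_SLOPE),
    xtol: float = 1e-10,
) -> float:
    """Predicted lesion depth (mm): the thickness at which transmural
    probability falls to the query's target.

    Bisection on the query bracket to ``xtol`` mm.  Raises
    :class:`InvalidInputError` if the substituted logit does not decrease in
    thickness, and :class:`NoRootError` (stating on which side the probability
    sits) if the target is not crossed inside the bracket.
    """
    if thickness_slope(model, impedance_relation) >= 0:
        raise InvalidInputError(
            "thickness direction of the logit is non-negative; "
            "no meaningful depth exists for this model"
        )
    L = _logit_of_thickness(model, query.rf_power, query.rf_duration,
                            impedance_relation)
    target_logit = float(np.log(query.target_probability
                                / (1.0 - query.target_probability)))
    f = lambda t: L(t) - target_logit
    lo, hi = query.thickness_bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        side = "above" if flo > 0 else "below"
        raise NoRootError(
            f"transmural probability is everywhere {side} the target "
            f"{query.target_probability} on the bracket {query.thickness_bracket}"
        )
    return float(brentq(f, lo, hi, xtol=xtol))


def required_duration(
    model: FittedModel,
    rf_power: float,
    thickness: float,
    target_probability: float = 0.5,
    impedance_relation: tuple[float, float] = (IMPEDANCE_INTERCEPT, IMPEDANCE_SLOPE),
) -> DurationResult:
    """Duration (s) at which the given thickness reaches the target transmural
    probability at the given power; closed-form solve of the linear logit."""
    if not (0.0 < target_probability < 1.0):
        raise InvalidInputError("target probability must be in (0, 1)")
    c = _coefs(model)
    if c["rf_duration"] == 0:
        raise InvalidInputError("degenerate model: zero duration coefficient")
    a, b = impedance_relation
    target_logit = float(np.log(target_probability / (1.0 - target_probability)))
    d = (
        target_logit
        - model.intercept
        - c["rf_power"] * rf_power
        - c["init_impedance"] * (a + b * thickness)
        - c["thickness"] * thickness
    ) / c["rf_duration"]
    if d < 0:
        return DurationResult(seconds=float(d), extrapolated=True,
                              status="already exceeded at 0 s")
    lo, hi = TESTED_DURATION_RANGE
    extrap = not (lo <= d <= hi)
    return DurationResult(seconds=float(d), extrapolated=extrap,
                          status="extrapolated" if extrap else "ok")


def depth_curves(
    model: FittedModel,
    powers,
    durations,
    target_probability: float = 0.5,
    impedance_relation: tuple[float, float] = (IMPEDANCE_INTERCEPT, IMPEDANCE_SLOPE),
):
    """Depth-vs-duration look-up table, one curve per power level.

    Grid points whose probability never crosses the target inside the default
    bracket get NaN depth (reported, not dropped).
    """
    import pandas as pd

    rows = []
    for e in np.atleast_1d(np.asarray(powers, float)):
        for d in np.atleast_1d(np.asarray(durations, float)):
            q = InversionQuery(rf_power=float(e), rf_duration=float(d),
                               target_probability=target_probability)
            try:
                depth = predict_depth(model, q, impedance_relation)
            except NoRootError:
                depth = float("nan")
            rows.append({"rf_power": float(e), "rf_duration": float(d),
                         "depth_mm": depth})
    return pd.DataFrame(rows)
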