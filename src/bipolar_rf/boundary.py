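"""The two-predictor steam-pop risk boundary in the thickness x power plane.

A published two-predictor logistic model of steam-pop occurrence,

    logit L = -4.9498 + 1.0729 * thickness_mm - 0.09030 * power_W,

is summarised by the boundary statistic

    Z = 0.0743 * (1 + e^L)  =  0.0743 / (1 - p),     p = sigmoid(L),

so Z is a strictly increasing function of the event probability p, Z -> 0.0743
as p -> 0, and the isopleth Z = 1 coincides with the probability contour
p = 1 - 0.0743 = 0.9257 (92.6%).  The printed source formula is typographically
mangled; this multiplicative reading is the unique parse under which Z = 1
corresponds to the reported 92.6% probability, and it is adopted here (see the
methods note).

Caveat of record: the positive thickness coefficient says thicker tissue pops
more, which contradicts the univariate observation that pops favour thin
tissue.  The constants are kept as printed — they are constants of record, not
refit — and ``BoundaryModel(flip_signs=True)`` exposes the sign-flipped variant
for exploration.  Nothing is silently corrected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError
from . import glm as _glm


@dataclass(frozen=True)
class BoundaryModel:
    intercept: float = -4.9498
    coef_thickness: float = 1.0729
    coef_power: float = -0.09030
    z_scale: float = 0.0743
    flip_signs: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.z_scale < 1.0):
            raise InvalidInputError("z_scale must lie in (0, 1)")

    def linear_predictor(self, thickness, power):
        sign = -1.0 if self.flip_signs else 1.0
        return (
            self.intercept
            + sign * self.coef_thickness * np.asarray(thickness, float)
            + sign * self.coef_power * np.asarray(power, float)
        )


def z_statistic(thickness, power, model: BoundaryModel | None = None):
    """Boundary statistic Z = z_scale * (1 + e^L); total function of (t, E).

    Z = 1 marks the probability contour p = 1 - z_scale; as L -> -inf, Z floors
    at z_scale.
    """
    m = model or BoundaryModel()
    L = m.linear_predictor(thickness, power)
    z = m.z_scale * (1.0 + np.exp(np.clip(L, -700, 700)))
    if np.ndim(thickness) == 0 and np.ndim(power) == 0:
        return float(z)
    return z


def boundary_probability(model: BoundaryModel | None = None, z: float = 1.0) -> float:
    """Event probability on the Z = z contour: p = 1 - z_scale / z."""
    m = model or BoundaryModel()
    if z <= m.z_scale:
        raise InvalidInputError(f"no probability contour for z <= z_scale ({m.z_scale})")
    return 1.0 - m.z_scale / z

def boundary_power(thickness: float, model: BoundaryModel | None = None,
                   z: float = 1.0) -> float:
    """The power E* (watts) at which Z(thickness, E*) = z; affine in thickness.

    Closed form: L* = ln(z / z_scale - 1) and
    E* = (intercept + coef_thickness * t - L*) / (-coef_power).
    Raises for z at or below the Z floor, and for a power-free model.
    """
    m = model or BoundaryModel()
    if z <= m.z_scale:
        raise InvalidInputError(f"z must exceed z_scale ({m.z_scale}); got {z}")
    if m.coef_power == 0:
        raise InvalidInputError("degenerate model: coef_power = 0")
    sign = -1.0 if m.flip_signs else 1.0
    l_star = np.log(z / m.z_scale - 1.0)
    return float(
        (m.intercept + sign * m.coef_thickness * thickness - l_star)
        / (-sign * m.coef_power)
    )


def probability_surface(
    model: "_glm.FittedModel",
    grid: Mapping[str, Sequence[float]],
    fixed: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Event probabilities over the Cartesian product of ``grid``.

    ``fixed`` pins the remaining predictors (e.g. initial impedance held at the
    training-cohort mean of 92.0 ohms); grid and fixed together must cover
    every predictor of the model.  Long-format output: one row per grid point
    with the predictor values, the linear predictor and the probability.
    """
    fixed = dict(fixed or {})
    covered = set(grid) | set(fixed)
    missing = [p for p in model.spec.predictors if p not in covered]
    if missing:
        raise SchemaError(f"predictors not covered by grid/fixed: {missing}")
    names = list(grid.keys())
    values = [np.atleast_1d(np.asarray(grid[k], float)) for k in names]
    rows = []
    for combo in itertools.product(*values) if names else [()]:
        row = dict(zip(names, (float(v) for v in combo)))
        row.update(fixed)
        rows.append(row)
    table = pd.DataFrame(rows) if rows else pd.DataFrame([fixed])
    eta = _glm.linear_predictor(model, table)
    table = table.copy()
    table["linear_predictor"] = eta
    table["probability"] = np.asarray(_glm.sigmoid(eta))
    return table
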