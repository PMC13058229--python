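"""Shapley-style attribution of validation AUC to individual predictors.

Each predictor is a "player" whose worth is its marginal gain in validation
AUC when added to a subset of the other predictors; the empty coalition is
assigned the chance AUC of 0.5.  Two weightings over subsets are supported:

* ``shapley`` (default): the Shapley kernel w(S) = |S|! (p-|S|-1)! / p!, which
  makes the attribution satisfy efficiency (contributions sum exactly to
  AUC(full) - 0.5), symmetry and the dummy axiom;
* ``uniform``: the plain average over all 2^(p-1) subsets, the literal
  "average gain" reading, which in general does not satisfy efficiency.

Enumeration is exact (every subset is fitted once, cached by its frozenset, so
symmetric predictors receive bitwise-identical treatment); no sampling
approximation is offered, which caps p at 12.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Sequence

import pandas as pd

from .errors import InvalidInputError
from .glm import FitOptions, ModelSpec, fit_logistic, predict_probability
from .roc import roc_auc

BASELINE_AUC = 0.5  # worth of the empty coalition: chance discrimination


@dataclass
class AttributionEntry:
    predictor: str
    contribution: float
    n_subsets: int
    weighting: str


def _subset_aucs(
    dev: pd.DataFrame,
    val: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    fit_options: FitOptions | None,
) -> dict[frozenset, float]:
    """Validation AUC of every predictor subset, keyed by frozenset.

    Constant-score subsets (all predictors constant in validation) fall out of
    the midrank convention as AUC 0.5 automatically.
    """
    y_val = val[outcome].to_numpy(dtype=int)
    aucs: dict[frozenset, float] = {frozenset(): BASELINE_AUC}
    for size in range(1, len(predictors) + 1):
        for combo in combinations(predictors, size):
            key = frozenset(combo)
            if key in aucs:
                continue
            model = fit_logistic(dev, ModelSpec(outcome, tuple(sorted(combo))),
                                 fit_options)
            aucs[key] = roc_auc(predict_probability(model, val), y_val).auc
    return aucs


def attribute_auc(
    dev: pd.DataFrame,
    val: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    weighting: str = "shapley",
    fit_options: FitOptions | None = None,
) -> list[AttributionEntry]:
    """Per-predictor mean marginal validation-AUC contribution, sorted descending."""
    preds = list(predictors)
    if not preds or len(set(preds)) != len(preds):
        raise InvalidInputError("predictors must be non-empty and unique")
    p = len(preds)
    if p > 12:
        raise InvalidInputError("exact enumeration limited to p <= 12")
    if weighting not in ("shapley", "uniform"):
        raise InvalidInputError(f"unknown weighting {weighting!r}")

    if fit_options is None:
        # collinear subsets (duplicated columns) must stay well-posed
        fit_options = FitOptions(auto_ridge=True)
    aucs = _subset_aucs(dev, val, outcome, preds, fit_options)

    entries = []
    for i in preds:
        # canonical subset order: contributions are bit-identical under any
        # permutation of the predictor input order
        others = sorted(q for q in preds if q != i)
        total = 0.0
        n_sub = 0
        for size in range(0, len(others) + 1):
            if weighting == "shapley":
                w = factorial(size) * factorial(p - size - 1) / factorial(p)
            else:
                w = 1.0 / 2 ** (p - 1)
            for combo in combinations(others, size):
                s = frozenset(combo)
                total += w * (aucs[s | {i}] - aucs[s])
                n_sub += 1
        entries.append(
            AttributionEntry(predictor=i, contribution=total,
                             n_subsets=n_sub, weighting=weighting)
        )
    entries.sort(key=lambda e: (-e.contribution, e.predictor))
    return entries


def attribution_frame(entries: Sequence[AttributionEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "predictor": e.predictor,
                "contribution": e.contribution,
                "n_subsets": e.n_subsets,
                "weighting": e.weighting,
            }
            for e in entries
        ]
    )
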