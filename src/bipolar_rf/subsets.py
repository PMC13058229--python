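"""Exhaustive predictor-subset screening with temporal train/validation split.

Every non-empty subset of the candidate predictors (2^p - 1 models; 63 for the
six ablation predictors) is fitted on the development cohort and scored on the
validation cohort.  Discrimination is summarised by validation AUC with a
DeLong 95% CI, the in-sample (train) AUC with its own DeLong CI, and a
validation operating point.  No stepwise shortcuts, no information criteria:
the procedure is deliberately exhaustive, mirroring a published 63-model
screen.

A subset whose every predictor is constant in the validation cohort (e.g. the
duration-only model when validation fixes duration) produces constant scores;
by convention it is reported with AUC 0.500 and the degenerate CI 0.500–0.500
and flagged ``excluded`` with a reason, rather than dropped or NaN'd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateOutcomeError, InvalidInputError
from .glm import FitOptions, FittedModel, ModelSpec, fit_logistic, predict_probability
from .roc import ROCResult, operating_point, roc_auc


@dataclass
class ModelEvaluation:
    spec: ModelSpec
    auc_validation: float
    ci_validation: tuple[float, float]
    auc_train: float
    ci_train: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    excluded: bool = False
    exclusion_reason: str = ""
    model: FittedModel | None = None


def enumerate_predictor_subsets(
    predictors: Sequence[str], outcome: str = "steam_pop"
) -> list[ModelSpec]:
    """All 2^p - 1 non-empty subsets, ordered by size then lexicographically."""
    preds = list(predictors)
    if not preds:
        raise InvalidInputError("predictor set must be non-empty")
    if len(set(preds)) != len(preds):
        raise InvalidInputError("duplicate predictor names")
    if len(preds) > 16:
        raise InvalidInputError("more than 16 predictors: enumeration refused")
    specs = []
    for size in range(1, len(preds) + 1):
        for combo in sorted(combinations(sorted(preds), size)):
            specs.append(ModelSpec(outcome, combo))
    return specs


def _constant_predictors(data: pd.DataFrame, predictors: Iterable[str]) -> list[str]:
    return [p for p in predictors if data[p].nunique(dropna=False) <= 1]


def evaluate_all(
    dev: pd.DataFrame,
    val: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    exclusions: Iterable[tuple[str, ...]] = (),
    fit_options: FitOptions | None = None,
    operating_rule: str = "youden",
    sort: bool = True,
) -> list[ModelEvaluation]:
    """Fit every predictor subset on ``dev`` and score it on ``val``.

    ``exclusions`` lists predictor tuples to flag (not drop) — e.g. the
    duration-only model when the validation protocol fixed duration.  Returned
    list is sorted by descending validation AUC (ties broken by the subset
    label) unless ``sort=False``, in which case enumeration order is kept.
    """
    for name, table in (("development", dev), ("validation", val)):
        y = table[outcome]
        if y.nunique() < 2:
            raise DegenerateOutcomeError(f"outcome constant in {name} cohort")
    excluded_keys = {frozenset(e) for e in exclusions}
    y_val = val[outcome].to_numpy(dtype=int)
    y_dev = dev[outcome].to_numpy(dtype=int)

    out: list[ModelEvaluation] = []
    for spec in enumerate_predictor_subsets(predictors, outcome):
        model = fit_logistic(dev, spec, fit_options)
        s_train = predict_probability(model, dev)
        r_train = roc_auc(s_train, y_dev)

        const = _constant_predictors(val, spec.predictors)
        all_const = len(const) == len(spec.predictors)
        if all_const:
            # constant scores: AUC 1/2 by the tie convention, zero variance
            r_val = ROCResult(0.5, 0.0, (0.5, 0.5), int(y_val.sum()),
                              int((1 - y_val).sum()))
            thr, sens, spec_ = np.nan, np.nan, np.nan
        else:
            s_val = predict_probability(model, val)
            r_val = roc_auc(s_val, y_val)
            thr, sens, spec_ = operating_point(s_val, y_val, operating_rule)

        excluded = all_const or spec.key in excluded_keys
        reason = ""
        if all_const:
            reason = f"all predictors constant in validation: {const}"
        elif spec.key in excluded_keys:
            reason = "excluded by protocol"
        out.append(
            ModelEvaluation(
                spec=spec,
                auc_validation=r_val.auc,
                ci_validation=r_val.ci95,
                auc_train=r_train.auc,
                ci_train=r_train.ci95,
                sensitivity=sens,
                specificity=spec_,
                threshold=thr,
                excluded=excluded,
                exclusion_reason=reason,
                model=model,
            )
        )
    if sort:
        out.sort(key=lambda e: (-e.auc_validation, e.spec.label()))
    return out


def evaluations_frame(evaluations: Sequence[ModelEvaluation],
                      predictors: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabular view: one row per model, checkmark matrix plus metrics."""
    if predictors is None:
        seen: list[str] = []
        for e in evaluations:
            for p in e.spec.predictors:
                if p not in seen:
                    seen.append(p)
        predictors = seen
    rows = []
    for e in evaluations:
        row = {"model": e.spec.label()}
        for p in predictors:
            row[p] = p in e.spec.predictors
        row.update(
            auc=e.auc_validation,
            ci_lo=e.ci_validation[0],
            ci_hi=e.ci_validation[1],
            auc_train=e.auc_train,
            ci_train_lo=e.ci_train[0],
            ci_train_hi=e.ci_train[1],
            sensitivity=e.sensitivity,
            specificity=e.specificity,
            excluded=e.excluded,
            exclusion_reason=e.exclusion_reason,
        )
        rows.append(row)
    return pd.DataFrame(rows)
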