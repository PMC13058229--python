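"""Cohort summaries, pop-vs-no-pop group comparisons, and table export.

Rounding follows the reporting convention of the source experiment: outcome
rates as percentages rounded half-up — integer precision for transmurality,
one decimal for steam-pops.  Group comparisons report medians and linear-
interpolation quartiles with a two-sided Wilcoxon rank-sum (Mann–Whitney U)
p-value: exact enumeration for small tie-free groups, normal approximation
with tie correction otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateGroupError, InvalidInputError
from .shapley import AttributionEntry, attribution_frame
from .subsets import ModelEvaluation, evaluations_frame

#: variables compared between pop and no-pop applications
DEFAULT_COMPARISON_VARIABLES = (
    "rf_power",
    "init_impedance",
    "thickness",
    "imp_drop5",
    "pct_imp_drop5",
)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero upward)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rate_percent(count: int, n: int, decimals: int = 0) -> float:
    """100 * count / n, rounded half-up to the given precision."""
    if n <= 0:
        raise InvalidInputError("n must be positive")
    return round_half_up(100.0 * count / n, decimals)


@dataclass
class CohortSummary:
    n: int
    n_transmural: int
    rate_transmural: float  # percent, integer precision
    n_pop: int
    rate_pop: float  # percent, one decimal
    by_pop_status: pd.DataFrame | None = None  # per-variable comparison table


def summarize_outcomes(data: pd.DataFrame,
                       variables: Sequence[str] | None = None) -> CohortSummary:
    """Outcome counts and rounded rates, plus the pop-vs-no-pop comparison
    when both groups are represented."""
    if len(data) == 0:
        raise InvalidInputError("empty cohort table")
    n = len(data)
    n_trans = int(data["transmural"].sum())
    n_pop = int(data["steam_pop"].sum())
    comparison = None
    if 0 < n_pop < n:
        vars_ = variables or [v for v in DEFAULT_COMPARISON_VARIABLES
                              if v in data.columns]
        comparison = compare_groups(data, by="steam_pop", variables=vars_)
    return CohortSummary(
        n=n,
        n_transmural=n_trans,
        rate_transmural=rate_percent(n_trans, n, 0),
        n_pop=n_pop,
        rate_pop=rate_percent(n_pop, n, 1),
        by_pop_status=comparison,
    )


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney p: exact for small tie-free samples, otherwise
    normal approximation with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(x), len(y)) < 10 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def compare_groups(
    data: pd.DataFrame,
    by: str,
    variables: Sequence[str],
) -> pd.DataFrame:
    """Medians, quartiles and rank-sum p per variable, split on binary ``by``.

    Quartiles use linear-interpolation quantiles.  Raises
    :class:`DegenerateGroupError` when either group is empty.
    """
    flags = data[by].to_numpy(dtype=int)
    g1 = data[flags == 1]
    g0 = data[flags == 0]
    if len(g1) == 0 or len(g0) == 0:
        raise DegenerateGroupError(f"both levels of {by!r} must be represented")
    rows = []
    for v in variables:
        a = g1[v].to_numpy(dtype=float)
        b = g0[v].to_numpy(dtype=float)
        rows.append(
            {
                "variable": v,
                "median_event": float(np.median(a)),
                "q1_event": float(np.quantile(a, 0.25)),
                "q3_event": float(np.quantile(a, 0.75)),
                "median_nonevent": float(np.median(b)),
                "q1_nonevent": float(np.quantile(b, 0.25)),
                "q3_nonevent": float(np.quantile(b, 0.75)),
                "p_value": rank_sum_test(a, b),
                "n_event": len(a),
                "n_nonevent": len(b),
            }
        )
    return pd.DataFrame(rows)


def export_tables(
    evaluations: Sequence[ModelEvaluation],
    attributions: Sequence[AttributionEntry] | None,
    path: str | Path,
    stem: str = "models",
) -> dict[str, Path]:
    """Write the evaluation table (CSV + JSON), forest-plot data and, when
    given, the attribution table under ``path``.  Returns the file map."""
    if len(evaluations) == 0:
        raise InvalidInputError("no evaluations to export")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    table = evaluations_frame(evaluations)
    out: dict[str, Path] = {}

    csv_path = path / f"{stem}.csv"
    table.to_csv(csv_path, index=False, float_format="%.17g")
    out["models_csv"] = csv_path

    json_path = path / f"{stem}.json"
    json_path.write_text(table.to_json(orient="records", indent=2))
    out["models_json"] = json_path

    forest = pd.DataFrame(
        {
            "model": [e.spec.label() for e in evaluations],
            "auc": [e.auc_validation for e in evaluations],
            "lo": [e.ci_validation[0] for e in evaluations],
            "hi": [e.ci_validation[1] for e in evaluations],
        }
    )
    forest_path = path / f"{stem}_forest.csv"
    forest.to_csv(forest_path, index=False, float_format="%.17g")
    out["forest_csv"] = forest_path

    if attributions is not None:
        attr_path = path / f"{stem}_attribution.csv"
        attribution_frame(attributions).to_csv(attr_path, index=False,
                                               float_format="%.12g")
        out["attribution_csv"] = attr_path
    return out
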