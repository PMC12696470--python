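"""Physiological panel analysis: per-cultivar change rates, control-vs-stress
significance tests, and the correlation structure of the change rates.

The change rate of indicator j for cultivar i is the relative change of the
condition means, (mean stress - mean control) / mean control. Its sign is
preserved so that indicator directionality (positive vs negative effect on
tolerance) can be applied downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study import ValidationError

log = logging.getLogger(__name__)

DIRECTIONS = ("positive", "negative")


@dataclass
class ChangeRateMatrix:
    """Cultivar x indicator relative change rates with direction labels."""

    x: pd.DataFrame
    directions: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.x.columns) - set(self.directions)
        if missing:
            raise ValidationError(f"directions missing for indicators: {sorted(missing)}")
        bad = set(self.directions.values()) - set(DIRECTIONS)
        if bad:
            raise ValidationError(f"unknown direction labels: {sorted(bad)}")
        if self.x.isna().any().any():
            raise ValidationError("change-rate matrix contains missing entries")


@dataclass
class CorrelationResult:
    """Pairwise correlations among indicator change rates.

    ``method`` records per pair whether Pearson or Spearman was used (the
    pair falls back to Spearman when either column fails the normality
    gate); ``significant`` flags pairs at the configured alpha.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    method: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    normal_columns: dict[str, bool]


def validate_panel(panel: pd.DataFrame, min_reps: int = 2) -> None:
    """Check the tidy-panel contract: complete cells with >= min_reps values."""
    cultivars = panel["cultivar"].unique()
    indicators = panel["indicator"].unique()
    if not np.isfinite(panel["value"]).all():
        raise ValidationError("panel contains non-finite values")
    counts = panel.groupby(["cultivar", "indicator", "condition"]).size()
    for c in cultivars:
        for ind in indicators:
            for cond in ("control", "stress"):
                n = counts.get((c, ind, cond), 0)
                if n == 0:
                    raise ValidationError(f"missing cell ({c}, {ind}, {cond})")
                if n < min_reps:
                    raise ValidationError(
                        f"cell ({c}, {ind}, {cond}) has {n} replicate(s); >= {min_reps} required"
                    )


def change_rates(panel: pd.DataFrame, directions: Mapping[str, str]) -> ChangeRateMatrix:
    """Relative change of condition means per (cultivar, indicator) cell.

    Raises
    ------
    ValidationError
        If a cell is missing, has fewer than two replicates, or has a
        control mean of zero (the rate would be undefined).
    """
    validate_panel(panel)
    means = panel.groupby(["cultivar", "indicator", "condition"])["value"].mean()
    table = means.unstack("condition")
    zero = table.index[table["control"] == 0]
    if len(zero):
        cells = ", ".join(f"({c}, {i})" for c, i in zero[:5])
        raise ValidationError(f"zero control mean in cell(s): {cells}")
    rates = ((table["stress"] - table["control"]) / table["control"]).unstack("indicator")
    rates = rates.loc[sorted(rates.index), list(panel["indicator"].unique())]
    return ChangeRateMatrix(rates, dict(directions))


def welch_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample unequal-variance (Welch) t-test p-value with the
    documented degenerate-case convention: both groups constant and equal
    -> p = 1; both constant but different -> p = 0 (warned)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        warnings.warn("zero variance with unequal means; reporting p = 0")
        return 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def star_label(p: float, alpha_levels: Sequence[float]) -> str:
    """Star annotation from the finest alpha level the p-value beats."""
    levels = sorted(alpha_levels)  # finest first
    for i, alpha in enumerate(levels):
        if p < alpha:
            return "*" * (len(levels) - i)
    return "ns"


def indicator_tests(
    panel: pd.DataFrame, alpha_levels: Sequence[float] = (0.05, 0.01, 0.001)
) -> pd.DataFrame:
    """Welch t-test of stress vs control per (cultivar, indicator) cell.

    Returns a table with columns ``cultivar, indicator, p, label`` where the
    label is the conventional star annotation ("***" for the finest level).
    """
    validate_panel(panel)
    rows = []
    for (c, ind), cell in panel.groupby(["cultivar", "indicator"], sort=False):
        ctl = cell.loc[cell["condition"] == "control", "value"].to_numpy()
        str_ = cell.loc[cell["condition"] == "stress", "value"].to_numpy()
        p = welch_test(ctl, str_)
        rows.append({"cultivar": c, "indicator": ind, "p": p, "label": star_label(p, alpha_levels)})
    return pd.DataFrame(rows)


def changerate_correlations(
    x: ChangeRateMatrix | pd.DataFrame,
    alpha: float = 0.01,
    normality_alpha: float = 0.05,
) -> CorrelationResult:
    """Pairwise correlation of indicator change rates across cultivars.

    Each column is gated by a Shapiro-Wilk normality test at
    ``normality_alpha``; a pair uses Pearson only when both columns pass,
    otherwise Spearman. Constant columns yield undefined correlations which
    are reported as missing (with a warning), never silently NaN-propagated
    into significance calls.
    """
    table = x.x if isinstance(x, ChangeRateMatrix) else x
    if len(table) < 3:
        raise ValidationError("correlation analysis needs >= 3 cultivars")
    cols = list(table.columns)
    normal: dict[str, bool] = {}
    constant: set[str] = set()
    for c in cols:
        v = table[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            constant.add(c)
            normal[c] = False
            warnings.warn(f"indicator {c} is constant; its correlations are undefined")
            continue
        normal[c] = stats.shapiro(v).pvalue >= normality_alpha
    n = len(cols)
    r = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    p = pd.DataFrame(np.full((n, n), np.nan), index=cols, columns=cols)
    method = pd.DataFrame("", index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            if a in constant or b in constant:
                r.loc[a, b] = r.loc[b, a] = np.nan
                method.loc[a, b] = method.loc[b, a] = "undefined"
                continue
            use_pearson = normal[a] and normal[b]
            if use_pearson:
                res = stats.pearsonr(table[a], table[b])
            else:
                res = stats.spearmanr(table[a], table[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
            method.loc[a, b] = method.loc[b, a] = "pearson" if use_pearson else "spearman"
    significant = p < alpha
    return CorrelationResult(r, p, method, significant, alpha, normal)
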