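"""Threshold-based differential expression and cross-set intersection.

Per (cultivar, tissue) group, each gene gets a log2 fold change between
condition means on the log2(FPKM + pseudocount) scale, a Welch t-test
p-value on those log2 values, and a Benjamini-Hochberg FDR across all genes
of the group. A gene is called up (down) when its linear fold change
exceeds the threshold, 2^|log2fc| > fc_threshold, AND fdr < fdr_threshold,
with the direction given by the sign of log2fc. The shared gene set is the
intersection of differential calls (up or down) across all groups.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study import ExpressionStudy, ValidationError

log = logging.getLogger(__name__)


@dataclass
class DEGSet:
    group: str
    table: pd.DataFrame  # index gene; columns log2fc, p, fdr, call

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])

    @property
    def differential(self) -> set[str]:
        return set(self.table.index[self.table["call"] != "ns"])


@dataclass
class DEGIntersection:
    shared: set[str]
    venn_counts: dict[str, int]  # key = membership bitmask over set order
    set_names: tuple[str, ...]


def _welch_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-test p-values for row-wise groups a, b.

    Degenerate rows (zero variance in both groups) get p = 1 when the means
    agree and p = 0 (with a warning) otherwise.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    if degenerate.any():
        equal = degenerate & (m1 == m2)
        unequal = degenerate & (m1 != m2)
        p[equal] = 1.0
        if unequal.any():
            warnings.warn(
                f"{int(unequal.sum())} gene(s) with zero variance but unequal means; p = 0"
            )
            p[unequal] = 0.0
    return p


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment (scipy's implementation)."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


def differential_expression(
    study: ExpressionStudy,
    group: str,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> DEGSet:
    """Replicate-based surrogate DE test for one (cultivar, tissue) group.

    The fold-change criterion is read on the linear scale
    (2^|log2fc| > fc_threshold), so both up- and down-regulated genes are
    captured symmetrically.
    """
    if group not in study.groups():
        raise ValidationError(f"unknown group {group!r}; have {study.groups()}")
    study.check_replicates(min_reps=2)
    logm = study.log2_matrix(pseudocount)
    ctl = logm[study.group_samples(group, "control")].to_numpy()
    strs = logm[study.group_samples(group, "stress")].to_numpy()
    log2fc = strs.mean(axis=1) - ctl.mean(axis=1)
    p = _welch_arrays(strs, ctl)
    fdr = benjamini_hochberg(p)
    passes = (2.0 ** np.abs(log2fc) > fc_threshold) & (fdr < fdr_threshold)
    call = np.where(passes & (log2fc > 0), "up", np.where(passes & (log2fc < 0), "down", "ns"))
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "call": call}, index=study.genes
    )
    log.info(
        "group %s: %d up, %d down of %d genes",
        group, int((call == "up").sum()), int((call == "down").sum()), len(table),
    )
    return DEGSet(group, table)


def intersect_deg_sets(sets: Sequence[DEGSet]) -> DEGIntersection:
    """Shared differential genes and all 2^k - 1 Venn region cardinalities.

    A gene counts as differential in a set iff its call is not "ns". Venn
    keys are bitmask strings over the given set order ("1011" = in sets
    1, 3 and 4 only).
    """
    if len(sets) < 2:
        raise ValidationError("intersection needs >= 2 DEG sets")
    universes = [set(s.table.index) for s in sets]
    universe = set.union(*universes)
    if not universe:
        raise ValidationError("empty gene universe")
    diffs = [s.differential for s in sets]
    shared = set.intersection(*diffs)
    venn: dict[str, int] = {}
    union = set.union(*diffs)
    membership = {g: "".join("1" if g in d else "0" for d in diffs) for g in union}
    for key in ("".join(bits) for bits in itertools.product("01", repeat=len(sets))):
        if key == "0" * len(sets):
            continue
        venn[key] = sum(1 for g in union if membership[g] == key)
    return DEGIntersection(shared, venn, tuple(s.group for s in sets))
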