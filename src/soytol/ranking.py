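"""Saline-alkaline tolerance ranking: directional min-max standardization,
membership-function composite scoring, entropy weighting, TOPSIS, and
cross-method rank concordance.

The evaluation model works on the cultivar x indicator change-rate matrix.
Positive-effect indicators are min-max standardized, negative-effect
indicators reverse standardized, so that in the standardized matrix X a
larger value always means "more tolerant". The membership-function score of
cultivar i is the (weighted) mean of its standardized values,
u_i = sum_j w_j X_ij, with equal weights w_j = 1/m by default. TOPSIS ranks
the same matrix by the relative closeness C_i = D_i- / (D_i+ + D_i-) to the
per-column best (A+) and worst (A-) profiles, using Euclidean distances.
Both scores increase with tolerance; their orderings are compared by
rank-level Spearman/Kendall statistics and a reversal count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .physiology import ChangeRateMatrix, change_rates
from .study import ValidationError

log = logging.getLogger(__name__)

WEIGHT_TOL = 1e-9


@dataclass
class StandardizedMatrix:
    """Cultivar x indicator matrix in [0, 1], larger = more tolerant.

    ``constant_columns`` lists indicators whose change rates were identical
    across cultivars; they are filled with the neutral membership 0.5 and
    carry no information for entropy weighting.
    """

    X: pd.DataFrame
    directions: Mapping[str, str]
    constant_columns: tuple[str, ...] = ()


@dataclass
class MembershipResult:
    U: pd.DataFrame
    u: pd.Series
    weights: pd.Series
    ranking: list[str]


@dataclass
class TopsisResult:
    a_plus: pd.Series
    a_minus: pd.Series
    d_plus: pd.Series
    d_minus: pd.Series
    c: pd.Series
    ranking: list[str]


@dataclass
class ConcordanceResult:
    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    n_reversals: int
    rank_table: pd.DataFrame


@dataclass
class PCASummary:
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame


@dataclass
class RankingBundle:
    """All intermediates of the end-to-end ranking chain."""

    change_rates: ChangeRateMatrix
    standardized: StandardizedMatrix
    membership: MembershipResult
    topsis: TopsisResult
    concordance: ConcordanceResult
    pca: PCASummary
    score_spearman: float  # Spearman between u_i and C_i values
    score_pearson: float


def standardize(x: ChangeRateMatrix) -> StandardizedMatrix:
    """Directional min-max standardization of the change-rate matrix.

    Positive indicators map their column minimum to 0 and maximum to 1;
    negative indicators are reversed (minimum change rate -> 1). A constant
    column makes the formula 0/0 and is filled with the neutral value 0.5
    with a warning.
    """
    if len(x.x) < 2:
        raise ValidationError("standardization needs >= 2 cultivars")
    X = pd.DataFrame(index=x.x.index, columns=x.x.columns, dtype=float)
    constant = []
    for col in x.x.columns:
        v = x.x[col].to_numpy(dtype=float)
        lo, hi = v.min(), v.max()
        if hi == lo:
            constant.append(col)
            warnings.warn(f"indicator {col} is constant; standardized to neutral 0.5")
            X[col] = 0.5
            continue
        if x.directions[col] == "positive":
            X[col] = (v - lo) / (hi - lo)
        else:
            X[col] = (hi - v) / (hi - lo)
    return StandardizedMatrix(X, dict(x.directions), tuple(constant))


def _resolve_weights(X: pd.DataFrame, weights) -> pd.Series:
    m = X.shape[1]
    if weights is None:
        return pd.Series(np.full(m, 1.0 / m), index=X.columns)
    if len(np.asarray(weights)) != m:
        raise ValidationError(f"expected {m} weights, got {len(np.asarray(weights))}")
    w = pd.Series(np.asarray(weights, dtype=float), index=X.columns) \
        if not isinstance(weights, pd.Series) else weights.reindex(X.columns)
    if w.isna().any() or (w < 0).any():
        raise ValidationError("weights must be nonnegative and cover all indicators")
    if abs(w.sum() - 1.0) > WEIGHT_TOL:
        raise ValidationError(f"weights must sum to 1 (got {w.sum()!r})")
    return w


def _order(scores: pd.Series) -> list[str]:
    # Stable: score descending, then lexicographic cultivar id.
    return sorted(scores.index, key=lambda c: (-scores[c], str(c)))


def membership_scores(X: StandardizedMatrix, weights=None) -> MembershipResult:
    """Comprehensive membership value u_i = sum_j w_j X_ij (equal weights by
    default); ranking by decreasing u_i with deterministic tie-break."""
    w = _resolve_weights(X.X, weights)
    U = X.X.copy()
    u = U.mul(w, axis=1).sum(axis=1)
    return MembershipResult(U, u, w, _order(u))


def entropy_weights(X: StandardizedMatrix | pd.DataFrame) -> pd.Series:
    """Entropy weights: low-entropy (informative) columns weigh more.

    p_ij = X_ij / sum_i X_ij; e_j = -(1/ln n) sum_i p_ij ln p_ij with
    0 ln 0 = 0; divergence d_j = 1 - e_j; w_j = d_j / sum_j d_j. An all-zero
    column carries no information (e_j = 1, d_j = 0, warned); if every
    column is zero-information the weights are undefined.
    """
    table = X.X if isinstance(X, StandardizedMatrix) else X
    arr = table.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("entropy weighting requires a nonnegative matrix")
    n = arr.shape[0]
    colsum = arr.sum(axis=0)
    e = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        if colsum[j] == 0:
            warnings.warn(
                f"indicator {table.columns[j]} is all-zero; treated as zero-information"
            )
            continue
        p = arr[:, j] / colsum[j]
        terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        e[j] = -terms.sum() / np.log(n)
    d = 1.0 - e
    # Numerical guard: entropies can overshoot 1 by rounding.
    d[np.abs(d) < 1e-12] = 0.0
    if d.sum() == 0:
        raise ValidationError("all indicators are zero-information; entropy weights undefined")
    return pd.Series(d / d.sum(), index=table.columns)


def topsis(X: StandardizedMatrix, weights=None) -> TopsisResult:
    """TOPSIS on the standardized matrix.

    By default the distances are computed on X directly (unweighted); if
    weights are given each column is scaled by w_j first. The ideal profile
    A+ takes per-column maxima, the anti-ideal A- the minima; C_i is the
    relative closeness D_i- / (D_i+ + D_i-).
    """
    table = X.X
    w = _resolve_weights(table, weights) if weights is not None else None
    V = table.mul(w, axis=1) if w is not None else table
    a_plus = V.max(axis=0)
    a_minus = V.min(axis=0)
    if (a_plus == a_minus).all():
        degenerate = list(table.columns)
        raise ValidationError(
            f"all columns are constant ({degenerate}); relative closeness undefined"
        )
    d_plus = np.sqrt(((V - a_plus) ** 2).sum(axis=1))
    d_minus = np.sqrt(((V - a_minus) ** 2).sum(axis=1))
    c = d_minus / (d_plus + d_minus)
    return TopsisResult(a_plus, a_minus, d_plus, d_minus, c, _order(c))


def pca_summary(X: StandardizedMatrix | pd.DataFrame) -> PCASummary:
    """Principal components of the column-centered standardized matrix.

    Diagnostic only: the composite score is the membership average and PCA
    never alters the ranking. Rank-deficient input simply yields
    zero-variance trailing components.
    """
    table = X.X if isinstance(X, StandardizedMatrix) else X
    if len(table) < 3:
        raise ValidationError("PCA summary needs >= 3 cultivars")
    n_comp = min(table.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(table.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCASummary(
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(pca.components_.T, index=table.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
    )


def compare_rankings(order_a: Sequence[str], order_b: Sequence[str]) -> ConcordanceResult:
    """Concordance between two orderings of the same items.

    Ranks are positions (1 = best). Spearman's rho uses the tie-free closed
    form 1 - 6 sum d^2 / (n (n^2 - 1)) (permutation ranks cannot tie);
    Kendall's tau is computed on the same ranks; n_reversals counts items
    whose positions differ.
    """
    if set(order_a) != set(order_b) or len(order_a) != len(set(order_a)):
        diff = set(order_a).symmetric_difference(set(order_b))
        raise ValidationError(f"orderings are not permutations of the same ids: {sorted(diff)}")
    n = len(order_a)
    pos_a = {c: i + 1 for i, c in enumerate(order_a)}
    pos_b = {c: i + 1 for i, c in enumerate(order_b)}
    ids = sorted(order_a)
    ra = np.array([pos_a[c] for c in ids], dtype=float)
    rb = np.array([pos_b[c] for c in ids], dtype=float)
    d2 = float(((ra - rb) ** 2).sum())
    if n > 1:
        rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
        spearman_p = float(stats.spearmanr(ra, rb).pvalue)
        tau = float(stats.kendalltau(ra, rb).statistic)
    else:
        rho, spearman_p, tau = 1.0, 0.0, 1.0
    n_reversals = int((ra != rb).sum())
    table = pd.DataFrame({"rank_a": ra.astype(int), "rank_b": rb.astype(int)}, index=ids)
    return ConcordanceResult(rho, spearman_p, tau, n_reversals, table)


def rank_cultivars(
    panel: pd.DataFrame,
    directions: Mapping[str, str],
    weights: str | Sequence[float] = "equal",
) -> RankingBundle:
    """End-to-end chain: change rates -> standardize -> {membership, TOPSIS}
    -> concordance, recording all intermediates.

    ``weights`` is "equal", "entropy", or an explicit vector; it applies to
    the membership composite. TOPSIS stays unweighted by default (its
    distances are defined on the standardized matrix directly) unless an
    explicit vector is supplied.
    """
    rates = change_rates(panel, directions)
    X = standardize(rates)
    if isinstance(weights, str):
        if weights == "equal":
            w = None
        elif weights == "entropy":
            w = entropy_weights(X)
        else:
            raise ValidationError(f"unknown weights mode {weights!r}")
        topsis_w = None
    else:
        w = weights
        topsis_w = weights
    membership = membership_scores(X, w)
    top = topsis(X, topsis_w)
    concordance = compare_rankings(membership.ranking, top.ranking)
    pca = pca_summary(X)
    ids = sorted(membership.u.index)
    u = membership.u[ids].to_numpy()
    c = top.c[ids].to_numpy()
    score_spearman = float(stats.spearmanr(u, c).statistic)
    score_pearson = float(stats.pearsonr(u, c).statistic)
    return RankingBundle(rates, X, membership, top, concordance, pca, score_spearman, score_pearson)
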