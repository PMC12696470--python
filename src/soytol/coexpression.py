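"""Weighted co-expression core, written from scratch.

The network is built on Pearson correlations of (log-scale) expression
profiles. Soft thresholding raises |cor| (unsigned) or (1+cor)/2 (signed)
to a power beta chosen as the smallest candidate whose scale-free topology
fit index reaches a target (0.9 by default). Adjacency is transformed into
a topological overlap matrix (TOM),

    t_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with connectivity k_i = sum_{u != i} a_iu and t_ii = 1. Modules come from
average-linkage hierarchical clustering of the TOM dissimilarity 1 - t with
a static cut, a minimum-size filter (module 0 collects unassigned genes),
and iterative merging of modules whose eigengenes correlate above
1 - merge_threshold. Eigengenes are first principal components of the
per-gene standardized module expression; hub (core) genes are the top-k by
intramodular connectivity, and candidate genes are hubs of trait-linked
modules that are also in the shared differential set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .study import ExpressionStudy, ValidationError

log = logging.getLogger(__name__)


@dataclass
class AdjacencyMatrix:
    a: pd.DataFrame  # symmetric, entries in [0, 1], unit diagonal
    power: int
    mode: str = "unsigned"


@dataclass
class TOMMatrix:
    t: pd.DataFrame

    @property
    def dissimilarity(self) -> pd.DataFrame:
        return 1.0 - self.t


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> module id, 0 = unassigned
    eigengenes: pd.DataFrame  # module id x sample
    merge_log: list[tuple[int, int, float]] = field(default_factory=list)
    k_within: pd.Series | None = None

    def module_sizes(self) -> dict[int, int]:
        return self.labels[self.labels > 0].value_counts().sort_index().to_dict()


@dataclass
class ModuleTraitResult:
    correlation: pd.DataFrame  # module x trait
    p: pd.DataFrame
    best_module: dict[str, int]


@dataclass
class SoftThresholdResult:
    power: int
    table: pd.DataFrame  # power, fit_r2, mean_k, median_k
    reached_target: bool


def filter_low_expression(study: ExpressionStudy, threshold: float = 2.0) -> ExpressionStudy:
    """Keep genes whose maximum abundance across samples is >= threshold
    (inclusive boundary)."""
    keep = study.matrix.max(axis=1) >= threshold
    if not keep.any():
        raise ValidationError(f"all genes fall below the expression threshold {threshold}")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("expression filter at %g removed %d of %d genes", threshold, n_drop, len(keep))
    return ExpressionStudy(study.matrix.loc[keep], study.samples, study.traits)


def _correlation(expr: pd.DataFrame) -> np.ndarray:
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    constant = expr.index[sd == 0]
    if len(constant):
        raise ValidationError(
            f"constant expression profiles (correlation undefined): {list(constant[:10])}"
        )
    return np.corrcoef(arr)


def adjacency(
    expr: ExpressionStudy | pd.DataFrame, power: int, mode: str = "unsigned"
) -> AdjacencyMatrix:
    """Soft-thresholded adjacency from Pearson correlations across samples.

    unsigned: a_ij = |cor|^beta; signed: a_ij = ((1 + cor)/2)^beta.
    """
    table = expr.matrix if isinstance(expr, ExpressionStudy) else expr
    if table.shape[1] < 3:
        raise ValidationError("adjacency needs >= 3 samples")
    cor = _correlation(table)
    if mode == "unsigned":
        a = np.abs(cor) ** power
    elif mode == "signed":
        a = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValidationError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(a, 1.0)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    return AdjacencyMatrix(pd.DataFrame(a, index=table.index, columns=table.index), power, mode)


def connectivity(a: AdjacencyMatrix | pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum_{u != i} a_iu (self-adjacency
    excluded)."""
    table = a.a if isinstance(a, AdjacencyMatrix) else a
    arr = table.to_numpy(dtype=float).copy()
    np.fill_diagonal(arr, 0.0)
    return pd.Series(arr.sum(axis=1), index=table.index)


def scale_free_fit(k: Sequence[float], n_bins: int = 10) -> float:
    """Signed scale-free topology fit index.

    Connectivities are binned into equal-width bins; log10 bin frequency is
    regressed on log10 mean bin connectivity over non-empty bins. The R^2
    is signed by -sign(slope), so a decaying degree distribution gives a
    positive index. Fewer than 3 non-empty bins -> NaN (undefined).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) == 0 or np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(k[mask].mean())
        ys.append(mask.sum() / len(k))
    if len(xs) < 3:
        return float("nan")
    if np.ptp(ys) == 0:  # flat histogram: no decay either way
        return 0.0
    fit = stats.linregress(np.log10(xs), np.log10(ys))
    return float(fit.rvalue**2 * -np.sign(fit.slope))


def pick_soft_threshold(
    expr: ExpressionStudy | pd.DataFrame,
    candidate_powers: Iterable[int] = range(1, 21),
    target: float = 0.9,
    mode: str = "unsigned",
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Choose the first power whose scale-free fit index reaches the target;
    fall back to the argmax with a warning when none does."""
    powers = list(candidate_powers)
    if not powers or sorted(powers) != powers:
        raise ValidationError("candidate powers must be a nonempty ascending list")
    table = expr.matrix if isinstance(expr, ExpressionStudy) else expr
    cor = _correlation(table)
    base = np.abs(cor) if mode == "unsigned" else (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in powers:
        a = base**beta
        k = a.sum(axis=1)
        rows.append(
            {
                "power": beta,
                "fit_r2": scale_free_fit(k, n_bins),
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
            }
        )
    result = pd.DataFrame(rows)
    ok = result["fit_r2"] >= target
    if ok.any():
        power = int(result.loc[ok.idxmax(), "power"])
        reached = True
    else:
        power = int(result.loc[result["fit_r2"].idxmax(), "power"])
        reached = False
        warnings.warn(
            f"no candidate power reached fit {target}; falling back to argmax (power {power})"
        )
    return SoftThresholdResult(power, result, reached)


def tom_similarity(a: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap from adjacency (self-edges excluded from the
    shared-neighbor sums and connectivities; diagonal fixed at 1)."""
    arr = a.a.to_numpy(dtype=float).copy()
    np.fill_diagonal(arr, 0.0)
    k = arr.sum(axis=1)
    shared = arr @ arr  # sum_u a_iu a_uj, u != i and u != j on off-diagonal
    numer = shared + arr
    denom = np.minimum.outer(k, k) + 1.0 - arr
    with np.errstate(divide="ignore", invalid="ignore"):
        t = numer / denom
    # Isolated pair with a_ij = 1 and no other edges: limit value 1.
    degenerate = denom == 0
    if degenerate.any():
        log.warning("%d TOM pair(s) with zero denominator set to limit 1", degenerate.sum() // 2)
        t[degenerate] = 1.0
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(pd.DataFrame(t, index=a.a.index, columns=a.a.columns))


def module_eigengenes(
    expr: ExpressionStudy | pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Genes are z-scored across samples before the SVD; the eigengene is
    scaled to unit variance and oriented so that it correlates positively
    with the module's mean standardized profile. A single-gene module's
    eigengene is that gene's z-scored profile. Module 0 (unassigned) gets
    no eigengene.
    """
    table = expr.matrix if isinstance(expr, ExpressionStudy) else expr
    modules = sorted(m for m in labels.unique() if m > 0)
    rows = {}
    for m in modules:
        genes = labels.index[labels == m]
        sub = table.loc[genes].to_numpy(dtype=float)
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0  # constant gene contributes a flat profile
        z = (sub - mean) / sd
        if z.shape[0] == 1:
            me = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            me = vt[0]
        ref = z.mean(axis=0)
        if np.dot(me, ref) < 0:
            me = -me
        sd_me = me.std()
        me = (me - me.mean()) / (sd_me if sd_me > 0 else 1.0)
        rows[m] = me
    return pd.DataFrame(rows, index=table.columns).T


def detect_modules(
    tom: TOMMatrix,
    expr: ExpressionStudy | pd.DataFrame,
    min_size: int = 30,
    merge_threshold: float = 0.25,
    cut_height_frac: float = 0.99,
) -> ModuleAssignment:
    """Static-cut module detection with size filter and eigengene merging.

    Average-linkage clustering on 1 - TOM is cut at
    cut_height_frac x (max merge height); clusters below min_size go to
    module 0; module pairs whose eigengene correlation exceeds
    1 - merge_threshold are merged iteratively; final modules are relabeled
    1..K by decreasing size.
    """
    genes = tom.t.index
    n = len(genes)
    if n < min_size:
        warnings.warn(f"{n} genes < min module size {min_size}; all genes unassigned")
        return ModuleAssignment(
            pd.Series(0, index=genes), module_eigengenes(expr, pd.Series(0, index=genes))
        )
    diss = tom.dissimilarity.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    cut = cut_height_frac * Z[:, 2].max()
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(raw, index=genes)
    # Size filter: small clusters join the unassigned pool (module 0).
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_size]
    labels[labels.isin(small)] = 0
    merge_log: list[tuple[int, int, float]] = []
    while True:
        modules = sorted(m for m in labels.unique() if m > 0)
        if len(modules) < 2:
            break
        mes = module_eigengenes(expr, labels)
        cor = np.corrcoef(mes.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        best = cor[i, j]
        if best <= 1.0 - merge_threshold:
            break
        keep, drop = modules[min(i, j)], modules[max(i, j)]
        labels[labels == drop] = keep
        merge_log.append((keep, drop, float(best)))
    # Relabel by decreasing size, deterministic tie-break by old label.
    modules = sorted(m for m in labels.unique() if m > 0)
    sizes = labels.value_counts()
    order = sorted(modules, key=lambda m: (-sizes[m], m))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    relabel[0] = 0
    labels = labels.map(relabel)
    return ModuleAssignment(labels, module_eigengenes(expr, labels), merge_log)


def intramodular_connectivity(
    a: AdjacencyMatrix | TOMMatrix, labels: pd.Series
) -> pd.Series:
    """k_within(g) = sum of g's adjacency to the other genes of its module
    (0 for unassigned genes). Accepts a TOM for the TOM-based variant."""
    table = a.a if isinstance(a, AdjacencyMatrix) else a.t
    arr = table.to_numpy(dtype=float).copy()
    np.fill_diagonal(arr, 0.0)
    lab = labels.reindex(table.index)
    if lab.isna().any():
        raise ValidationError("labels do not cover all genes in the adjacency")
    k = np.zeros(len(table))
    vals = lab.to_numpy()
    for m in np.unique(vals):
        if m == 0:
            continue
        mask = vals == m
        k[mask] = arr[np.ix_(mask, mask)].sum(axis=1)
    return pd.Series(k, index=table.index)


def hub_genes(
    a: AdjacencyMatrix | TOMMatrix, labels: pd.Series, top_k: int = 30
) -> dict[int, pd.DataFrame]:
    """Per module, the top_k genes by intramodular connectivity (all genes
    when the module is smaller); ties broken by gene id."""
    k_within = intramodular_connectivity(a, labels)
    hubs: dict[int, pd.DataFrame] = {}
    for m in sorted(m for m in labels.unique() if m > 0):
        genes = labels.index[labels == m]
        ranked = sorted(genes, key=lambda g: (-k_within[g], str(g)))[:top_k]
        hubs[m] = pd.DataFrame({"gene": ranked, "k_within": [k_within[g] for g in ranked]})
    return hubs


def module_trait_correlations(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> ModuleTraitResult:
    """Pearson correlation and p-value per (module eigengene, trait);
    best_module per trait maximizes |r|."""
    if set(eigengenes.columns) != set(traits.index):
        diff = set(eigengenes.columns).symmetric_difference(set(traits.index))
        raise ValidationError(f"sample mismatch between eigengenes and traits: {sorted(diff)[:10]}")
    traits = traits.loc[list(eigengenes.columns)]
    modules = list(eigengenes.index)
    cols = list(traits.columns)
    r = pd.DataFrame(index=modules, columns=cols, dtype=float)
    p = pd.DataFrame(index=modules, columns=cols, dtype=float)
    for m in modules:
        for t in cols:
            res = stats.pearsonr(eigengenes.loc[m], traits[t])
            r.loc[m, t] = res.statistic
            p.loc[m, t] = res.pvalue
    best = {t: int(r[t].abs().idxmax()) for t in cols}
    return ModuleTraitResult(r, p, best)


def candidate_genes(
    hub_sets: Mapping[int, pd.DataFrame],
    trait_modules: Iterable[int],
    shared: Iterable[str],
) -> pd.DataFrame:
    """Hub genes of trait-linked modules intersected with the shared
    differential set; sorted by gene id with (module, k_within) provenance."""
    shared = set(shared)
    rows = []
    for m in sorted(set(trait_modules)):
        if m == 0 or m not in hub_sets:
            continue
        for _, rec in hub_sets[m].iterrows():
            if rec["gene"] in shared:
                rows.append({"gene": rec["gene"], "module": m, "k_within": rec["k_within"]})
    if not rows:
        log.info("no candidate genes: hub sets and shared set are disjoint")
        return pd.DataFrame(columns=["gene", "module", "k_within"])
    out = pd.DataFrame(rows).drop_duplicates(subset="gene").sort_values("gene")
    return out.reset_index(drop=True)
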