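"""Seeded synthetic data with known ground truth.

Two generators drive every downstream stage without any external data:

``gen_physio_panel``
    Replicated control/stress measurements for a panel of cultivars with a
    planted, evenly spaced latent tolerance gradient. Positive-direction
    indicators respond to stress more strongly in tolerant cultivars;
    negative-direction indicators (MDA- and Pro-like) respond more strongly
    in sensitive ones, so their change rates decrease with tolerance.

``gen_expression_study``
    A gene x sample FPKM-like matrix over (cultivar, tissue) groups with
    both conditions and replicates, containing planted co-expression
    modules tied to named traits, planted per-group up/down DEG sets with a
    known four-way shared subset, and planted hub genes. Module latent
    factors vary across (cultivar, tissue) units (plus small replicate
    noise) but are condition-balanced, so module membership alone never
    creates differential expression; DE is planted as a centered additive
    log2 contrast (+delta/2 on stress, -delta/2 on control samples of the
    group), with an independent random sign per group so shared genes do
    not form a correlated block of their own.
    Hub genes follow their module factor much more tightly than ordinary
    members, which keeps them at the top of intramodular connectivity even
    when they also carry DE shifts.

Randomness contract: every draw comes from ``numpy`` generators seeded from
a single ``SeedSequence(seed)`` with fixed spawn keys, and per-cultivar /
per-gene sub-streams, so the same arguments and seed reproduce the output
byte-for-byte and adding genes does not perturb earlier genes' draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .study import ExpressionStudy, ValidationError, group_id


@dataclass(frozen=True)
class IndicatorSpec:
    name: str
    direction: str  # positive | negative
    baseline: float  # control-condition mean, indicator units
    effect_slope: float  # strength of the stress response along the gradient


# Baselines in conventional units (enzyme activities U/g FW, SP mg/g,
# AOC % scavenging, MDA nmol/g, Pro ug/g); slopes sized so change rates
# span roughly 0-80% across the gradient.
DEFAULT_INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("SOD", "positive", 160.0, 0.55),
    IndicatorSpec("CAT", "positive", 45.0, 0.65),
    IndicatorSpec("POD", "positive", 310.0, 0.50),
    IndicatorSpec("SP", "positive", 22.0, 0.25),
    IndicatorSpec("AOC", "positive", 58.0, 0.45),
    IndicatorSpec("MDA", "negative", 9.0, 0.60),
    IndicatorSpec("Pro", "negative", 30.0, 0.80),
)


@dataclass
class PhysioGroundTruth:
    tolerance_scores: dict[str, float]  # latent, higher = more tolerant
    indicator_directions: dict[str, str]
    effect_slopes: dict[str, float]

    @property
    def order(self) -> list[str]:
        return sorted(self.tolerance_scores, key=lambda c: -self.tolerance_scores[c])


def gen_physio_panel(
    n_cultivars: int = 9,
    indicators: Sequence[IndicatorSpec] = DEFAULT_INDICATORS,
    n_reps: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    cultivars: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, PhysioGroundTruth]:
    """Simulate a replicated control/stress physiological panel.

    Control replicates are baseline x (1 + N(0, noise_sd)); stress
    replicates baseline x (1 + slope * g(t) + N(0, noise_sd)) with g(t) = t
    for positive indicators and g(t) = 1 - t for negative ones, where t is
    the cultivar's tolerance on the evenly spaced [0, 1] gradient.
    """
    if n_cultivars < 2:
        raise ValidationError("need >= 2 cultivars")
    if n_reps < 2:
        raise ValidationError("need >= 2 replicates (downstream tests need within-group variance)")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    for spec in indicators:
        if spec.baseline <= 0:
            raise ValidationError(f"indicator {spec.name} has non-positive baseline")
        if spec.effect_slope < 0:
            raise ValidationError(f"indicator {spec.name} has negative effect slope")
    if cultivars is None:
        cultivars = [f"cv{i + 1:02d}" for i in range(n_cultivars)]
    elif len(cultivars) != n_cultivars:
        raise ValidationError("cultivar name list length differs from n_cultivars")
    tolerance = np.linspace(0.0, 1.0, n_cultivars)
    records = []
    for ci, cultivar in enumerate(cultivars):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, ci)))
        t = tolerance[ci]
        for spec in indicators:
            g = t if spec.direction == "positive" else 1.0 - t
            for cond, shift in (("control", 0.0), ("stress", spec.effect_slope * g)):
                noise = rng.normal(0.0, noise_sd, size=n_reps) if noise_sd > 0 else np.zeros(n_reps)
                values = spec.baseline * (1.0 + shift + noise)
                for r, v in enumerate(values, start=1):
                    records.append(
                        {
                            "cultivar": cultivar,
                            "indicator": spec.name,
                            "condition": cond,
                            "replicate": r,
                            "value": float(v),
                        }
                    )
    truth = PhysioGroundTruth(
        dict(zip(cultivars, tolerance.tolist())),
        {s.name: s.direction for s in indicators},
        {s.name: s.effect_slope for s in indicators},
    )
    return pd.DataFrame.from_records(records), truth


@dataclass(frozen=True)
class ModuleSpec:
    size: int
    trait: str
    corr_sign: int = 1
    within_corr: float = 0.8  # expected pairwise correlation of ordinary members
    n_hubs: int = 5
    hub_within_corr: float = 0.995


@dataclass(frozen=True)
class GroupSpec:
    cultivar: str
    tissue: str  # above | below
    n_reps: int = 3

    @property
    def id(self) -> str:
        return group_id(self.cultivar, self.tissue)


@dataclass(frozen=True)
class DEGSpec:
    n_up: int = 80  # per-group up calls, shared genes included
    n_down: int = 80
    shared_count: int = 39  # genes differential in every group
    log2fc_effect: float = 2.0
    shared_hub_count: int = 13  # shared genes that are also planted module hubs


DEFAULT_MODULES: tuple[ModuleSpec, ...] = (
    ModuleSpec(60, "SOD", 1),
    ModuleSpec(50, "POD", 1),
    ModuleSpec(40, "Pro", -1),
)

DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("QN52", "above"),
    GroupSpec("QN52", "below"),
    GroupSpec("JD49", "above"),
    GroupSpec("JD49", "below"),
)

DEFAULT_TRAITS: tuple[str, ...] = ("SOD", "CAT", "POD", "SP", "AOC", "MDA", "Pro")


@dataclass
class ExpressionGroundTruth:
    module_labels: pd.Series  # gene -> module id, 0 = unassigned/noise
    planted_hubs: dict[int, list[str]]
    trait_links: dict[int, tuple[str, int]]  # module -> (trait, corr sign)
    planted_deg_sets: dict[str, tuple[set[str], set[str]]]  # group -> (up, down)
    shared_set: set[str]

    @property
    def candidate_set(self) -> set[str]:
        hubs = set().union(*self.planted_hubs.values()) if self.planted_hubs else set()
        return hubs & self.shared_set

    def to_dict(self) -> dict:
        return {
            "module_labels": {g: int(m) for g, m in self.module_labels.items()},
            "planted_hubs": {int(m): sorted(v) for m, v in self.planted_hubs.items()},
            "trait_links": {int(m): list(v) for m, v in self.trait_links.items()},
            "planted_deg_sets": {
                g: {"up": sorted(u), "down": sorted(d)}
                for g, (u, d) in self.planted_deg_sets.items()
            },
            "shared_set": sorted(self.shared_set),
            "candidate_set": sorted(self.candidate_set),
        }


def _module_factors(
    seed: int,
    samples: pd.DataFrame,
    n_modules: int,
    rep_sd: float,
) -> list[np.ndarray]:
    """Condition-balanced latent factors, one per module.

    Each factor takes one value per (cultivar, tissue) unit, shared by both
    conditions of that unit so that module membership alone never creates a
    stress/control contrast, plus per-sample replicate noise. The unit-level
    values of the different modules are centered and orthogonalized (QR), so
    planted modules are mutually uncorrelated up to replicate noise; this is
    possible for at most n_units - 1 modules, beyond which raw centered
    draws are used with a warning. Every factor is standardized across
    samples.
    """
    units = list(
        samples[["cultivar", "tissue"]].drop_duplicates().itertuples(index=False, name=None)
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    raw = rng.standard_normal((len(units), n_modules))
    raw = raw - raw.mean(axis=0, keepdims=True)
    if n_modules <= len(units) - 1:
        q, r = np.linalg.qr(raw)
        unit_vals = q * np.sign(np.diag(r))  # deterministic sign convention
    else:
        warnings.warn(
            f"{n_modules} modules exceed the {len(units) - 1} orthogonal "
            "condition-balanced factors available; modules may correlate by chance"
        )
        unit_vals = raw
    unit_index = {u: i for i, u in enumerate(units)}
    sample_unit = [
        unit_index[(r["cultivar"], r["tissue"])] for _, r in samples.iterrows()
    ]
    factors = []
    for m in range(n_modules):
        f = unit_vals[sample_unit, m] + rep_sd * rng.standard_normal(len(sample_unit))
        sd = f.std()
        factors.append((f - f.mean()) / sd if sd > 0 else np.zeros(len(f)))
    return factors


def gen_expression_study(
    n_genes: int = 1000,
    module_specs: Sequence[ModuleSpec] = DEFAULT_MODULES,
    group_specs: Sequence[GroupSpec] = DEFAULT_GROUPS,
    deg_spec: DEGSpec = DEGSpec(),
    noise_sd: float = 0.2,
    rep_sd: float = 0.05,
    trait_noise_sd: float = 0.2,
    mu_range: tuple[float, float] = (3.0, 8.0),
    trait_names: Sequence[str] = DEFAULT_TRAITS,
    seed: int = 0,
) -> tuple[ExpressionStudy, ExpressionGroundTruth]:
    """Simulate an expression study with planted modules, DEGs and hubs.

    See the module docstring for the generative model. All abundances are
    returned on a non-negative FPKM-like scale (2 ** latent log2 value).
    """
    total_module = sum(m.size for m in module_specs)
    if total_module > n_genes:
        raise ValidationError("module sizes exceed n_genes")
    for m in module_specs:
        if not 0.0 < m.within_corr < 1.0 or not 0.0 < m.hub_within_corr < 1.0:
            raise ValidationError("within-module correlations must lie in (0, 1)")
        if m.n_hubs > m.size:
            raise ValidationError("more hubs than module genes")
        if m.trait not in trait_names:
            raise ValidationError(f"module trait {m.trait!r} not among trait names")
    for g in group_specs:
        if g.n_reps < 2:
            raise ValidationError("each group needs >= 2 replicates per condition")
    if deg_spec.shared_count > deg_spec.n_up + deg_spec.n_down:
        raise ValidationError("shared_count exceeds a group's total DEG count")
    total_hubs = sum(m.n_hubs for m in module_specs)
    if deg_spec.shared_hub_count > min(deg_spec.shared_count, total_hubs):
        raise ValidationError("shared_hub_count exceeds shared_count or available hubs")

    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    samples = pd.DataFrame(
        [
            {
                "sample": f"{g.cultivar}_{g.tissue}_{cond[0].upper()}{r}",
                "cultivar": g.cultivar,
                "tissue": g.tissue,
                "condition": cond,
                "replicate": r,
            }
            for g in group_specs
            for cond in ("control", "stress")
            for r in range(1, g.n_reps + 1)
        ]
    ).set_index("sample")
    n_samples = len(samples)
    # Centered condition contrast per group: +1 on stress, -1 on control
    # samples of that group, 0 elsewhere.
    contrast = {}
    for g in group_specs:
        in_group = (
            (samples["cultivar"] == g.cultivar) & (samples["tissue"] == g.tissue)
        ).to_numpy()
        stress = in_group & (samples["condition"] == "stress").to_numpy()
        contrast[g.id] = stress.astype(float) - (in_group & ~stress).astype(float)

    # Gene bookkeeping: module blocks first, remaining genes form the pool.
    labels = pd.Series(0, index=pd.Index(genes, name="gene"))
    planted_hubs: dict[int, list[str]] = {}
    trait_links: dict[int, tuple[str, int]] = {}
    cursor = 0
    module_gene_ids: dict[int, list[str]] = {}
    for mi, spec in enumerate(module_specs, start=1):
        block = genes[cursor : cursor + spec.size]
        cursor += spec.size
        labels[block] = mi
        module_gene_ids[mi] = block
        planted_hubs[mi] = block[: spec.n_hubs]
        trait_links[mi] = (spec.trait, int(np.sign(spec.corr_sign) or 1))
    pool = list(genes[cursor:])

    rng_deg = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    # Shared genes: hub-resident ones round-robin across modules, the rest
    # from the unassigned pool.
    hub_cycle: list[str] = []
    if module_specs:
        per_module = [list(planted_hubs[mi]) for mi in module_gene_ids]
        i = 0
        while len(hub_cycle) < deg_spec.shared_hub_count:
            bucket = per_module[i % len(per_module)]
            if bucket:
                hub_cycle.append(bucket.pop(0))
            elif not any(per_module):
                break
            i += 1
    shared_from_hubs = hub_cycle[: deg_spec.shared_hub_count]
    n_pool_shared = deg_spec.shared_count - len(shared_from_hubs)
    if n_pool_shared > len(pool):
        raise ValidationError("not enough unassigned genes for the shared DEG set")
    shared = list(shared_from_hubs) + pool[:n_pool_shared]
    pool = pool[n_pool_shared:]

    # Per-group signs for shared genes: balanced split, random assignment,
    # independent across groups.
    shared_signs: dict[str, dict[str, int]] = {}
    for g in group_specs:
        n_up_shared = deg_spec.shared_count // 2 + int(rng_deg.integers(0, 2)) * (
            deg_spec.shared_count % 2
        )
        n_up_shared = min(n_up_shared, deg_spec.n_up)
        if deg_spec.shared_count - n_up_shared > deg_spec.n_down:
            raise ValidationError("shared genes cannot fit the per-group down count")
        perm = rng_deg.permutation(deg_spec.shared_count)
        shared_signs[g.id] = {
            shared[i]: (1 if rank < n_up_shared else -1) for rank, i in enumerate(perm)
        }

    planted_deg_sets: dict[str, tuple[set[str], set[str]]] = {}
    gene_shifts: dict[str, list[tuple[str, int]]] = {gg: [] for gg in genes}
    for g in group_specs:
        up = {gid for gid, s in shared_signs[g.id].items() if s > 0}
        down = {gid for gid, s in shared_signs[g.id].items() if s < 0}
        need_up, need_down = deg_spec.n_up - len(up), deg_spec.n_down - len(down)
        if need_up + need_down > len(pool):
            raise ValidationError("not enough unassigned genes for group-specific DEG sets")
        own_up, pool = pool[:need_up], pool[need_up:]
        own_down, pool = pool[:need_down], pool[need_down:]
        up |= set(own_up)
        down |= set(own_down)
        planted_deg_sets[g.id] = (up, down)
        for gid in up:
            gene_shifts[gid].append((g.id, 1))
        for gid in down:
            gene_shifts[gid].append((g.id, -1))

    # Latent log2 matrix.
    rng_mu = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    mu = rng_mu.uniform(*mu_range, size=n_genes)
    factor_list = _module_factors(seed, samples, len(module_specs), rep_sd)
    factors = {mi: f for mi, f in enumerate(factor_list, start=1)}

    Y = np.empty((n_genes, n_samples))
    spec_by_label = {mi: spec for mi, spec in enumerate(module_specs, start=1)}
    for gi, gid in enumerate(genes):
        rng_g = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5, gi)))
        eps = rng_g.standard_normal(n_samples)
        row = mu[gi] + noise_sd * eps
        m = int(labels[gid])
        if m > 0:
            spec = spec_by_label[m]
            w = spec.hub_within_corr if gid in planted_hubs[m] else spec.within_corr
            b = (noise_sd if noise_sd > 0 else 1.0) * np.sqrt(w / (1.0 - w))
            # Baseline grows with factor amplitude so the abundance stays
            # well above the DE pseudocount over the factor's full swing
            # (keeps planted log2 fold changes interpretable).
            row = row + 2.0 * b + b * factors[m]
        for grp, sign in gene_shifts[gid]:
            row = row + sign * (deg_spec.log2fc_effect / 2.0) * contrast[grp]
        Y[gi] = row
    matrix = pd.DataFrame(2.0**Y, index=pd.Index(genes, name="gene"), columns=samples.index)

    # Traits: linked traits track their module factor; the rest are noise.
    rng_t = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(6,)))
    linked = {trait: (mi, sign) for mi, (trait, sign) in trait_links.items()}
    traits = pd.DataFrame(index=samples.index, columns=list(trait_names), dtype=float)
    for name in trait_names:
        if name in linked:
            mi, sign = linked[name]
            traits[name] = sign * factors[mi] + trait_noise_sd * rng_t.standard_normal(n_samples)
        else:
            traits[name] = rng_t.standard_normal(n_samples)

    study = ExpressionStudy(matrix, samples, traits)
    truth = ExpressionGroundTruth(labels, planted_hubs, trait_links, planted_deg_sets, set(shared))
    return study, truth
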