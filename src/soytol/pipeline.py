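"""End-to-end orchestration: simulate or load inputs, then run the
physiology, ranking, differential-expression, co-expression and
candidate-gene stages with one seed, persisting every intermediate and a
machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import coexpression as cx
from . import deg as degmod
from . import io as soio
from . import physiology, ranking, simulate
from .study import ExpressionStudy, ValidationError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run.

    Exactly one of ``inputs`` (paths to panel/directions/matrix/samples/
    traits TSVs) or ``simulation`` (keyword blocks for the two generators)
    must be given.
    """

    seed: int = 0
    out_dir: str = "soytol_out"
    inputs: dict[str, str] | None = None
    simulation: dict[str, Any] | None = None
    ranking: dict[str, Any] = field(default_factory=dict)
    deg: dict[str, Any] = field(default_factory=dict)
    coexpression: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(raw))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValidationError(
                "config must provide exactly one of 'inputs' or 'simulation'"
            )
        for name, value, lo, hi in (
            ("deg.fc_threshold", self.deg.get("fc_threshold", 1.5), 1.0, None),
            ("deg.fdr_threshold", self.deg.get("fdr_threshold", 0.05), 0.0, 1.0),
            ("coexpression.merge_threshold", self.coexpression.get("merge_threshold", 0.25), 0.0, 1.0),
            ("coexpression.cut_height_frac", self.coexpression.get("cut_height_frac", 0.99), 0.0, 1.0),
        ):
            if (lo is not None and value < lo) or (hi is not None and value > hi):
                raise ValidationError(f"{name} = {value} outside documented range")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "inputs": self.inputs,
            "simulation": self.simulation,
            "ranking": self.ranking,
            "deg": self.deg,
            "coexpression": self.coexpression,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineReport:
    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True, default=str) + "\n"

    def __getitem__(self, key):
        return self.data[key]


class StageError(RuntimeError):
    pass


def demo_config(seed: int = 0, out_dir: str = "soytol_demo") -> PipelineConfig:
    """Fully simulated demonstration configuration.

    Uses the generator defaults (9 cultivars x 7 indicators x 3 replicates;
    1000 genes in 4 groups with three trait-linked modules, 39 shared DEGs
    and 13 hub-resident candidates) except that each expression group gets
    5 replicates per condition: with triplicates the Welch surrogate test
    has ~2 degrees of freedom and cannot push p-values low enough for an
    exact recovery of the planted shared set, whereas 5 replicates give the
    scenario the precision an exact-recovery demonstration needs.
    """
    groups = [
        {"cultivar": c, "tissue": t, "n_reps": 5}
        for c in ("QN52", "JD49")
        for t in ("above", "below")
    ]
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        simulation={
            "physio": {"noise_sd": 0.02},
            "expression": {"groups": groups},
        },
    )


def _simulation_objects(sim: Mapping[str, Any], seed: int):
    physio_kw = dict(sim.get("physio", {}))
    expr_kw = dict(sim.get("expression", {}))
    if "modules" in expr_kw:
        expr_kw["module_specs"] = [simulate.ModuleSpec(**m) for m in expr_kw.pop("modules")]
    if "groups" in expr_kw:
        expr_kw["group_specs"] = [simulate.GroupSpec(**g) for g in expr_kw.pop("groups")]
    if "deg" in expr_kw:
        expr_kw["deg_spec"] = simulate.DEGSpec(**expr_kw.pop("deg"))
    panel, physio_truth = simulate.gen_physio_panel(seed=seed, **physio_kw)
    study, expr_truth = simulate.gen_expression_study(seed=seed, **expr_kw)
    directions = physio_truth.indicator_directions
    return panel, directions, study, physio_truth, expr_truth


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis; any stage failure aborts with the stage
    name and leaves partial outputs plus a FAILED marker in out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("soytol")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "setup"
    report: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
    }
    try:
        # ---- inputs -------------------------------------------------
        stage = "inputs"
        physio_truth = expr_truth = None
        if config.simulation is not None:
            panel, directions, study, physio_truth, expr_truth = _simulation_objects(
                config.simulation, config.seed
            )
            inputs_dir = out / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            soio.write_panel(panel, inputs_dir / "physio_panel.tsv")
            soio.write_directions(directions, inputs_dir / "directions.tsv")
            soio.write_study(study, inputs_dir)
            soio.write_json(expr_truth.to_dict(), inputs_dir / "ground_truth.json")
        else:
            paths = config.inputs
            panel = soio.read_panel(paths["panel"])
            directions = soio.read_directions(paths["directions"])
            study = soio.read_study(paths["matrix"], paths["samples"], paths.get("traits"))
        # ---- physiology ---------------------------------------------
        stage = "physiology"
        rates = physiology.change_rates(panel, directions)
        tests = physiology.indicator_tests(panel)
        corr = physiology.changerate_correlations(rates, alpha=config.ranking.get("alpha", 0.01))
        rates.x.rename_axis("cultivar").to_csv(out / "change_rates.tsv", sep="\t")
        tests.to_csv(out / "indicator_tests.tsv", sep="\t", index=False)
        corr.r.rename_axis("indicator").to_csv(out / "changerate_correlations.tsv", sep="\t")
        corr.method.rename_axis("indicator").to_csv(out / "correlation_methods.tsv", sep="\t")
        # ---- ranking ------------------------------------------------
        stage = "ranking"
        weights_mode = config.ranking.get("weights", "equal")
        bundle = ranking.rank_cultivars(panel, directions, weights=weights_mode)
        bundle.standardized.X.rename_axis("cultivar").to_csv(out / "standardized.tsv", sep="\t")
        pd.DataFrame(
            {"u": bundle.membership.u, "rank": pd.Series(
                {c: i + 1 for i, c in enumerate(bundle.membership.ranking)})}
        ).rename_axis("cultivar").to_csv(out / "membership.tsv", sep="\t")
        pd.DataFrame(
            {
                "d_plus": bundle.topsis.d_plus,
                "d_minus": bundle.topsis.d_minus,
                "c": bundle.topsis.c,
                "rank": pd.Series({c: i + 1 for i, c in enumerate(bundle.topsis.ranking)}),
            }
        ).rename_axis("cultivar").to_csv(out / "topsis.tsv", sep="\t")
        concordance = {
            "spearman_rho": bundle.concordance.spearman_rho,
            "spearman_p": bundle.concordance.spearman_p,
            "kendall_tau": bundle.concordance.kendall_tau,
            "n_reversals": bundle.concordance.n_reversals,
            "score_spearman": bundle.score_spearman,
            "score_pearson": bundle.score_pearson,
        }
        soio.write_json(concordance, out / "concordance.json")
        report["ranking"] = {
            "membership_order": bundle.membership.ranking,
            "topsis_order": bundle.topsis.ranking,
            "membership_scores": {c: float(v) for c, v in bundle.membership.u.items()},
            "topsis_closeness": {c: float(v) for c, v in bundle.topsis.c.items()},
            "concordance": concordance,
            "weights": {c: float(v) for c, v in bundle.membership.weights.items()},
            "pca_explained_variance_ratio": [
                float(v) for v in bundle.pca.explained_variance_ratio
            ],
        }
        # ---- differential expression --------------------------------
        stage = "deg"
        deg_kw = {
            "fc_threshold": config.deg.get("fc_threshold", 1.5),
            "fdr_threshold": config.deg.get("fdr_threshold", 0.05),
            "pseudocount": config.deg.get("pseudocount", 1.0),
        }
        deg_sets = [
            degmod.differential_expression(study, grp, **deg_kw) for grp in study.groups()
        ]
        for ds in deg_sets:
            ds.table.rename_axis("gene").to_csv(out / f"deg_{ds.group}.tsv", sep="\t")
        intersection = degmod.intersect_deg_sets(deg_sets)
        soio.write_gene_list(intersection.shared, out / "shared_genes.txt")
        soio.write_json(
            {"sets": list(intersection.set_names), "regions": intersection.venn_counts},
            out / "venn_counts.json",
        )
        report["deg"] = {
            "counts": {
                ds.group: {"up": len(ds.up), "down": len(ds.down)} for ds in deg_sets
            },
            "shared_count": len(intersection.shared),
            "shared_genes": sorted(intersection.shared),
        }
        # ---- co-expression ------------------------------------------
        stage = "coexpression"
        cxc = config.coexpression
        filtered = cx.filter_low_expression(study, cxc.get("expression_threshold", 2.0))
        log_expr = filtered.log2_matrix(config.deg.get("pseudocount", 1.0))
        power_setting = cxc.get("power", "auto")
        if power_setting == "auto":
            sft = cx.pick_soft_threshold(log_expr, mode=cxc.get("mode", "unsigned"))
            power = sft.power
            sft.table.to_csv(out / "power_table.tsv", sep="\t", index=False)
        else:
            power = int(power_setting)
        adj = cx.adjacency(log_expr, power, mode=cxc.get("mode", "unsigned"))
        tom = cx.tom_similarity(adj)
        assignment = cx.detect_modules(
            tom,
            log_expr,
            min_size=cxc.get("min_size", 30),
            merge_threshold=cxc.get("merge_threshold", 0.25),
            cut_height_frac=cxc.get("cut_height_frac", 0.99),
        )
        conn_source = tom if cxc.get("k_within_on", "adjacency") == "tom" else adj
        assignment.k_within = cx.intramodular_connectivity(conn_source, assignment.labels)
        pd.DataFrame(
            {"module": assignment.labels, "k_within": assignment.k_within}
        ).rename_axis("gene").to_csv(out / "modules.tsv", sep="\t")
        assignment.eigengenes.rename_axis("module").to_csv(out / "eigengenes.tsv", sep="\t")
        hubs = cx.hub_genes(conn_source, assignment.labels, top_k=cxc.get("top_k", 30))
        hub_table = pd.concat(
            [df.assign(module=m) for m, df in hubs.items()], ignore_index=True
        ) if hubs else pd.DataFrame(columns=["gene", "k_within", "module"])
        hub_table.to_csv(out / "hubs.tsv", sep="\t", index=False)
        if filtered.traits is None:
            raise ValidationError("trait table required for module-trait correlation")
        trait_result = cx.module_trait_correlations(assignment.eigengenes, filtered.traits)
        trait_result.correlation.rename_axis("module").to_csv(out / "module_trait.tsv", sep="\t")
        report["coexpression"] = {
            "power": int(power),
            "module_sizes": {int(m): int(s) for m, s in assignment.module_sizes().items()},
            "n_modules": len(assignment.module_sizes()),
            "n_unassigned": int((assignment.labels == 0).sum()),
            "best_module": {t: int(m) for t, m in trait_result.best_module.items()},
        }
        # ---- candidates ---------------------------------------------
        stage = "candidates"
        trait_modules = set(trait_result.best_module.values())
        candidates = cx.candidate_genes(hubs, trait_modules, intersection.shared)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        report["candidates"] = {
            "n": len(candidates),
            "genes": list(candidates["gene"]),
            "trait_modules": sorted(int(m) for m in trait_modules),
        }
        # ---- ground-truth comparison (simulated runs only) ----------
        if expr_truth is not None:
            planted = sorted(expr_truth.candidate_set)
            recovered = set(candidates["gene"])
            report["truth"] = {
                "planted_shared": len(expr_truth.shared_set),
                "shared_recovered": len(intersection.shared & expr_truth.shared_set),
                "shared_spurious": len(intersection.shared - expr_truth.shared_set),
                "planted_candidates": planted,
                "candidates_recovered": len(recovered & expr_truth.candidate_set),
                "candidates_spurious": len(recovered - expr_truth.candidate_set),
                "planted_order": physio_truth.order if physio_truth else None,
            }
        stage = "report"
        rep = PipelineReport(report)
        (out / "report.json").write_text(rep.to_json())
        (out / "report.txt").write_text(_text_summary(report))
        return rep
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _text_summary(report: dict) -> str:
    lines = [
        "soytol pipeline report",
        f"seed: {report['seed']}  config hash: {report['config_hash']}",
    ]
    if "ranking" in report:
        r = report["ranking"]
        lines += [
            "",
            "tolerance ranking (membership): " + " > ".join(r["membership_order"]),
            "tolerance ranking (TOPSIS):     " + " > ".join(r["topsis_order"]),
            "concordance: rho={spearman_rho:.4f} tau={kendall_tau:.4f} "
            "reversals={n_reversals}".format(**r["concordance"]),
        ]
    if "deg" in report:
        counts = ", ".join(
            f"{g}: {c['up']}up/{c['down']}down" for g, c in report["deg"]["counts"].items()
        )
        lines += ["", f"DEGs per group: {counts}", f"shared DEGs: {report['deg']['shared_count']}"]
    if "coexpression" in report:
        c = report["coexpression"]
        lines += [
            "",
            f"soft power: {c['power']}; modules: {c['module_sizes']} "
            f"(unassigned: {c['n_unassigned']})",
            f"trait-linked modules: {report['candidates']['trait_modules']}",
            f"candidate genes ({report['candidates']['n']}): "
            + ", ".join(report["candidates"]["genes"]),
        ]
    if "truth" in report:
        t = report["truth"]
        lines += [
            "",
            f"ground truth: shared {t['shared_recovered']}/{t['planted_shared']} recovered "
            f"({t['shared_spurious']} spurious); candidates "
            f"{t['candidates_recovered']}/{len(t['planted_candidates'])} recovered "
            f"({t['candidates_spurious']} spurious)",
        ]
    return "\n".join(lines) + "\n"


def validate_io(files: Mapping[str, str]) -> list[str]:
    """Schema checks for the input TSVs; returns a list of findings
    (empty when everything is well-formed)."""
    findings: list[str] = []
    panel = directions = matrix = samples = None
    if "panel" in files:
        try:
            panel = soio.read_panel(files["panel"])
            physiology.validate_panel(panel)
        except Exception as exc:
            findings.append(f"panel: {exc}")
    if "directions" in files:
        try:
            directions = soio.read_directions(files["directions"])
        except Exception as exc:
            findings.append(f"directions: {exc}")
    if panel is not None and directions is not None:
        missing = set(panel["indicator"].unique()) - set(directions)
        if missing:
            findings.append(f"directions: missing indicators {sorted(missing)}")
    if "matrix" in files:
        try:
            matrix = soio.read_matrix(files["matrix"])
            if matrix.index.duplicated().any():
                findings.append("matrix: duplicate gene ids")
        except Exception as exc:
            findings.append(f"matrix: {exc}")
    if "samples" in files:
        try:
            samples = soio.read_samples(files["samples"])
        except Exception as exc:
            findings.append(f"samples: {exc}")
    if matrix is not None and samples is not None:
        try:
            traits = soio.read_traits(files["traits"]) if "traits" in files else None
            study = ExpressionStudy(matrix, samples, traits)
            study.check_replicates()
        except Exception as exc:
            findings.append(f"study: {exc}")
    return findings
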