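"""Plain-text (TSV/JSON) readers and writers for every artifact the
pipeline consumes or persists.

Schemas
-------
physiological panel : tidy TSV, columns ``cultivar, indicator, condition,
    replicate, value`` with condition in {control, stress}
directions          : TSV, columns ``indicator, direction`` with direction in
    {positive, negative}
expression matrix   : TSV, first column ``gene``, remaining columns samples
sample sheet        : TSV, columns ``sample, cultivar, tissue, condition,
    replicate``
trait table         : TSV, first column ``sample``, one column per indicator
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .study import ExpressionStudy, ValidationError

PANEL_COLUMNS = ("cultivar", "indicator", "condition", "replicate", "value")


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t")
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValidationError(f"panel {path} missing columns: {sorted(missing)}")
    return panel


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.loc[:, list(PANEL_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_directions(path: str | Path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    if not {"indicator", "direction"} <= set(table.columns):
        raise ValidationError(f"directions {path} needs columns indicator, direction")
    bad = set(table["direction"]) - {"positive", "negative"}
    if bad:
        raise ValidationError(f"unknown directions: {sorted(bad)}")
    return dict(zip(table["indicator"], table["direction"]))


def write_directions(directions: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"indicator": list(directions), "direction": list(directions.values())}
    ).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = "gene"
    matrix.columns.name = "sample"
    return matrix


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene").to_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col="sample")
    return samples


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.rename_axis("sample").to_csv(path, sep="\t")


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.rename_axis("sample").to_csv(path, sep="\t")


def read_study(
    matrix_path: str | Path,
    samples_path: str | Path,
    traits_path: str | Path | None = None,
) -> ExpressionStudy:
    traits = read_traits(traits_path) if traits_path else None
    return ExpressionStudy(read_matrix(matrix_path), read_samples(samples_path), traits)


def write_study(study: ExpressionStudy, out_dir: str | Path, prefix: str = "") -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{prefix}expression_matrix.tsv",
        "samples": out / f"{prefix}sample_sheet.tsv",
    }
    write_matrix(study.matrix, paths["matrix"])
    write_samples(study.samples, paths["samples"])
    if study.traits is not None:
        paths["traits"] = out / f"{prefix}traits.tsv"
        write_traits(study.traits, paths["traits"])
    return {k: str(v) for k, v in paths.items()}


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
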