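"""In-memory containers shared across the analysis stages.

An :class:`ExpressionStudy` bundles a gene x sample abundance matrix on an
FPKM-like (non-negative, linear) scale with a sample sheet mapping each
sample to its cultivar, tissue, condition and replicate, plus an optional
per-sample trait table used for module-trait correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("control", "stress")
SAMPLE_COLUMNS = ("cultivar", "tissue", "condition", "replicate")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def group_id(cultivar: str, tissue: str) -> str:
    return f"{cultivar}_{tissue}"


@dataclass
class ExpressionStudy:
    """Gene x sample abundance matrix plus sample metadata.

    Parameters
    ----------
    matrix
        Genes as rows, samples as columns, non-negative FPKM-like values.
    samples
        One row per sample (index = sample id) with columns
        ``cultivar, tissue, condition, replicate``.
    traits
        Optional sample x indicator table, aligned on sample id.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    traits: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.matrix.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in matrix columns")
        if self.samples.index.duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        mat_ids = set(self.matrix.columns)
        sheet_ids = set(self.samples.index)
        if mat_ids != sheet_ids:
            diff = mat_ids.symmetric_difference(sheet_ids)
            raise ValidationError(
                f"sample ids differ between matrix and sheet: {sorted(diff)[:10]}"
            )
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown conditions: {sorted(bad)}")
        if (self.matrix.to_numpy() < 0).any():
            raise ValidationError("negative abundances in expression matrix")
        if self.traits is not None and set(self.traits.index) != sheet_ids:
            diff = set(self.traits.index).symmetric_difference(sheet_ids)
            raise ValidationError(
                f"trait table samples differ from sample sheet: {sorted(diff)[:10]}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def groups(self) -> list[str]:
        pairs = self.samples[["cultivar", "tissue"]].drop_duplicates()
        return [group_id(c, t) for c, t in pairs.itertuples(index=False)]

    def group_samples(self, group: str, condition: str | None = None) -> list[str]:
        ids = [
            s
            for s, row in self.samples.iterrows()
            if group_id(row["cultivar"], row["tissue"]) == group
            and (condition is None or row["condition"] == condition)
        ]
        return ids

    def check_replicates(self, min_reps: int = 2) -> None:
        """Require both conditions with >= min_reps replicates per group."""
        for grp in self.groups():
            for cond in CONDITIONS:
                n = len(self.group_samples(grp, cond))
                if n < min_reps:
                    raise ValidationError(
                        f"group {grp} has {n} {cond} replicates; >= {min_reps} required"
                    )

    def log2_matrix(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return np.log2(self.matrix + pseudocount)
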