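"""Expression-matrix container and tab-separated I/O.

The pipeline's canonical in-memory object is an :class:`ExpressionMatrix`:
a genes x samples :class:`pandas.DataFrame` of non-negative abundances
(FPKM for mRNA/lncRNA, read counts for miRNA) together with the molecular
level and a per-sample condition label (HF vs control).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

LEVELS = ("mRNA", "lncRNA", "miRNA")
CONDITIONS = ("HF", "control")


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with condition labels.

    Attributes
    ----------
    level
        Molecular level: ``"mRNA"``, ``"lncRNA"`` or ``"miRNA"``.
    values
        DataFrame indexed by gene id with sample ids as columns.  NaN is
        allowed only for miRNA matrices, where it encodes a missing
        measurement (distinct from a zero count).
    condition
        Series mapping sample id -> ``"HF"`` or ``"control"``.
    """

    level: str
    values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative abundances")
        if self.level != "miRNA" and np.isnan(vals).any():
            raise ValueError("missing values only allowed at miRNA level")
        missing = set(self.values.columns) - set(self.condition.index)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")
        self.condition = self.condition.loc[self.values.columns]
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_where(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.level, self.values[sample_ids].copy(),
                                self.condition.loc[sample_ids].copy())

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        return ExpressionMatrix(self.level, self.values.loc[gene_ids].copy(),
                                self.condition.copy())

    def hf_samples(self) -> "ExpressionMatrix":
        return self.subset_samples(self.samples_where("HF"))

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1) transform (NaN preserved)."""
        return np.log2(self.values + 1.0)

    def __eq__(self, other) -> bool:  # used by round-trip tests
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (self.level == other.level
                and self.values.equals(other.values)
                and self.condition.equals(other.condition))


def read_samples_tsv(path) -> pd.DataFrame:
    """Read the sample annotation table (sample_id, condition, sex, age)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "condition" not in df.columns:
        raise ValueError(f"{path}: expected columns sample_id and condition")
    return df.set_index("sample_id")


def read_expression_tsv(path, level: str, samples: pd.DataFrame) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids).

    Gzipped files are handled transparently by pandas via the file suffix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return ExpressionMatrix(level, df, samples["condition"].copy())


def write_expression_tsv(mat: ExpressionMatrix, path) -> None:
    path = Path(path)
    out = mat.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
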