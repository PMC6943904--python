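"""Expression-matrix filters and PCA quality control.

Implements the pre-analysis filters: removal of mRNAs expressed below 1
FPKM in more than 80% of samples, the standard lncRNA candidate definition
(length >= 200 nt, at least two exons), removal of miRNAs with missing
measurements in more than 10% of samples, and a PCA of the log-transformed,
gene-standardised matrix used only for visual QC, never as a filter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclasses.dataclass(frozen=True)
class TranscriptMeta:
    """Minimal transcript annotation used by the lncRNA candidate filter."""

    transcript_id: str
    length: int      # nucleotides
    exon_count: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.exon_count < 1:
            raise ValueError("exon_count must be >= 1")


def filter_low_expression(mat: ExpressionMatrix, fpkm_min: float = 1.0,
                          frac: float = 0.8) -> ExpressionMatrix:
    """Drop genes with abundance below ``fpkm_min`` in more than ``frac`` of samples.

    The boundary is strict: a gene low in *exactly* ``frac`` of the samples
    is retained.  The denominator is all samples, both conditions pooled.
    Gene order of survivors is preserved.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    if mat.n_genes == 0 or mat.n_samples == 0:
        raise ValueError("empty expression matrix")
    low_frac = (mat.values < fpkm_min).sum(axis=1) / mat.n_samples
    keep = mat.values.index[low_frac <= frac]
    return mat.subset_genes(keep)


def filter_lncrna_candidates(meta: list[TranscriptMeta],
                             min_len: int = 200) -> list[TranscriptMeta]:
    """Keep transcripts of length >= ``min_len`` nt with at least two exons."""
    return [m for m in meta if m.length >= min_len and m.exon_count >= 2]


def filter_missing_mirna(mat: ExpressionMatrix,
                         max_missing: float = 0.1) -> ExpressionMatrix:
    """Drop miRNAs whose missing fraction exceeds ``max_missing``.

    Missing measurements are NaN entries; zero counts are data and do not
    count as missing.
    """
    if mat.level != "miRNA":
        raise ValueError("missing-value filter applies to miRNA matrices")
    miss_frac = mat.values.isna().sum(axis=1) / mat.n_samples
    keep = mat.values.index[miss_frac <= max_missing]
    return mat.subset_genes(keep)


def pca_qc(mat: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Sample scores from PCA of the gene-standardised log2(x+1) matrix.

    Returns a samples x components DataFrame (columns PC1, PC2, ...).
    Scores are computed by SVD; component variances are non-increasing.
    Constant genes carry no information and are dropped before
    standardisation.  Intended for QC plots of HF-vs-control separation.
    """
    if mat.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = mat.log2p1().to_numpy(dtype=float)
    sd = X.std(axis=1)
    X = X[sd > 0]
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    # samples are observations: SVD of the samples x genes matrix
    A = X.T - X.T.mean(axis=0, keepdims=True)
    max_rank = min(A.shape)
    if n_components > max_rank:
        raise ValueError(f"n_components {n_components} exceeds rank bound {max_rank}")
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    return pd.DataFrame(scores, index=mat.values.columns,
                        columns=[f"PC{i+1}" for i in range(n_components)])
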