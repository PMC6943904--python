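"""Differential expression calls and over-representation analysis.

A single, transparent engine is used at all three molecular levels: a
per-gene Welch two-sample t-test on log2(x+1) values with Benjamini-
Hochberg adjustment.  A gene is called differentially expressed when its
adjusted p-value is below ``alpha`` (default 0.05) and its absolute log2
fold change on pseudocounted group means strictly exceeds ``log2fc_min``
(default 1, i.e. more than twofold).  An alternative per-gene test can be
plugged in through ``test_fn``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .matrix import ExpressionMatrix
from .stats import benjamini_hochberg, welch_ttest

DE_COLUMNS = ["gene", "level", "log2fc", "p_raw", "p_adj", "is_de", "direction"]


def log2_fold_change(x_hf, x_ctl, pseudocount: float = 1.0) -> float:
    """log2 of the ratio of pseudocounted group means (HF over control)."""
    x_hf = np.asarray(x_hf, dtype=float)
    x_ctl = np.asarray(x_ctl, dtype=float)
    if x_hf.size == 0 or x_ctl.size == 0:
        raise ValueError("both groups must be non-empty")
    if (x_hf < 0).any() or (x_ctl < 0).any():
        raise ValueError("abundances must be non-negative")
    return float(np.log2((x_hf.mean() + pseudocount) /
                         (x_ctl.mean() + pseudocount)))


def de_test(mat: ExpressionMatrix, alpha: float = 0.05,
            log2fc_min: float = 1.0, pseudocount: float = 1.0,
            test_fn: Callable | None = None) -> pd.DataFrame:
    """Per-gene two-group differential expression table.

    Parameters
    ----------
    mat
        Expression matrix with HF and control samples (>= 2 each).
    test_fn
        Optional replacement for the default Welch test; called as
        ``test_fn(hf_log2, ctl_log2)`` on genes x samples arrays of
        log2(x+1) values and returning ``(stat, p)`` arrays.

    Returns
    -------
    DataFrame with columns gene, level, log2fc, p_raw, p_adj, is_de,
    direction — one row per gene, in input gene order.
    """
    hf = mat.samples_where("HF")
    ctl = mat.samples_where("control")
    if len(hf) < 2 or len(ctl) < 2:
        raise ValueError("each condition needs at least 2 samples")
    x_hf = mat.values[hf].to_numpy(dtype=float)
    x_ctl = mat.values[ctl].to_numpy(dtype=float)
    log2fc = np.log2((x_hf.mean(axis=1) + pseudocount) /
                     (x_ctl.mean(axis=1) + pseudocount))
    l_hf = np.log2(x_hf + 1.0)
    l_ctl = np.log2(x_ctl + 1.0)
    if test_fn is None:
        _, p_raw = welch_ttest(l_hf, l_ctl, axis=1)
    else:
        _, p_raw = test_fn(l_hf, l_ctl)
    p_adj = benjamini_hochberg(p_raw)
    is_de = (np.abs(log2fc) > log2fc_min) & (p_adj < alpha)
    return pd.DataFrame({
        "gene": mat.gene_ids,
        "level": mat.level,
        "log2fc": log2fc,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "is_de": is_de,
        "direction": np.where(log2fc >= 0, "up", "down"),
    })


def de_genes(table: pd.DataFrame) -> list[str]:
    """Gene ids called differentially expressed, in table order."""
    return list(table.loc[table["is_de"], "gene"])


def hypergeometric_ora(query: set, annotation: dict, universe: set,
                       warn: Callable[[str], None] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation analysis across annotation terms.

    For each term the upper-tail probability of observing at least the
    realised overlap between ``query`` and the term's gene set, drawing
    ``|query|`` genes from ``universe``; BH adjustment across terms.
    Term genes outside the universe are dropped (with a warning callback).
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    N, n = len(universe), len(query)
    for term in sorted(annotation):
        term_genes = set(annotation[term])
        outside = term_genes - universe
        if outside and warn is not None:
            warn(f"term {term!r}: {len(outside)} genes outside universe dropped")
        term_genes &= universe
        K = len(term_genes)
        k = len(term_genes & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term, K, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_raw"])
    out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy()) if len(out) else []
    return out
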