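"""Per-gene differential expression and gene ranking.

Expression differences between two cell groups are tested per gene with a
two-sided Wilcoxon rank-sum (Mann-Whitney) test under the tie-corrected
normal approximation; multiplicity is handled with Benjamini-Hochberg. The
log fold change is the difference of mean log-normalized expression
(natural log), matching the normalization upstream.

Genes are ranked for preranked GSEA by sign(logFC) * (-log10 p) with p
floored at 1e-300; ties break by |logFC| then gene id, so the ranking is a
strict total order.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from stromaniche.preprocess import LOGNORM_LAYER

P_FLOOR = 1e-300


@dataclass
class RankedList:
    genes: list[str]
    scores: np.ndarray  # descending

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")


def wilcoxon_de(
    adata: ad.AnnData, group1: np.ndarray, group2: np.ndarray
) -> pd.DataFrame:
    """Rank-sum DE of group1 vs group2 on the log-normalized layer.

    Returns a per-gene table with ``log_fc`` (mean lognorm group1 − group2),
    ``p_value`` and BH-adjusted ``q_value``.
    """
    g1 = np.asarray(group1)
    g2 = np.asarray(group2)
    if g1.dtype == bool:
        g1 = np.flatnonzero(g1)
    if g2.dtype == bool:
        g2 = np.flatnonzero(g2)
    if np.intersect1d(g1, g2).size:
        raise ValueError("groups overlap")
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 cells")
    norm = sp.csr_matrix(adata.layers[LOGNORM_LAYER])
    X1 = np.asarray(norm[g1].todense())
    X2 = np.asarray(norm[g2].todense())
    res = scipy.stats.mannwhitneyu(X1, X2, axis=0, alternative="two-sided",
                                   method="asymptotic")
    p = np.clip(res.pvalue, P_FLOOR, 1.0)
    log_fc = X1.mean(axis=0) - X2.mean(axis=0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log_fc": log_fc, "p_value": p, "q_value": np.maximum(q, p)},
        index=adata.var_names,
    )


def rank_genes(de_table: pd.DataFrame, by: str = "signed_logp") -> RankedList:
    """Build the descending ranked list; ``by`` is ``signed_logp`` (default)
    or ``logfc`` for a pure fold-change ranking."""
    p = np.clip(de_table["p_value"].to_numpy(), P_FLOOR, 1.0)
    lfc = de_table["log_fc"].to_numpy()
    if by == "signed_logp":
        score = np.sign(lfc) * (-np.log10(p))
    elif by == "logfc":
        score = lfc.astype(float)
    else:
        raise ValueError(f"unknown ranking metric {by!r}")
    order = sorted(
        range(len(de_table)),
        key=lambda i: (-score[i], -abs(lfc[i]), de_table.index[i]),
    )
    return RankedList([de_table.index[i] for i in order], score[order])
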