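"""Cell-level quality control.

A cell is removed when any of four predicates holds, all evaluated on the
pre-filter statistics of the combined dataset:

* fewer than ``min_genes`` detected genes (default 500),
* mitochondrial fraction above ``max_mito`` (default 5%),
* detected genes strictly above the top ``top_gene_quantile`` cutoff (2%),
* total transcripts strictly above the top ``top_count_quantile`` cutoff (5%).

Mitochondrial genes are recognized by a case-insensitive ``mt-`` symbol
prefix (mouse convention). The filter is applied exactly once: quantile
cutoffs would shift after removal, so a second pass is not a no-op and the
pipeline never takes one.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd


@dataclass
class QCThresholds:
    min_genes: int = 500
    max_mito: float = 0.05
    top_gene_quantile: float = 0.02
    top_count_quantile: float = 0.05

    def validate(self) -> None:
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        for q, name in [(self.top_gene_quantile, "top_gene_quantile"),
                        (self.top_count_quantile, "top_count_quantile")]:
            if not 0 < q < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def compute_qc(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell n_genes (detected), n_counts (total) and mito_frac."""
    if adata.n_vars == 0:
        raise ValueError("matrix has no genes")
    X = adata.X
    mito = np.array([g.lower().startswith("mt-") for g in adata.var_names])
    n_counts = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_counts > 0, mito_counts / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes.astype(int), "n_counts": n_counts, "mito_frac": mito_frac},
        index=adata.obs_names,
    )


def filter_cells(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, np.ndarray, dict]:
    """One-pass QC filter; returns (filtered matrix, keep flags, summary).

    Top-quantile removal uses a strictly-greater comparison against the
    linearly interpolated empirical quantile, so a fully tied dataset loses
    no cells to the quantile rules.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    stats = compute_qc(adata)
    gene_cut = np.quantile(stats["n_genes"], 1 - thresholds.top_gene_quantile)
    count_cut = np.quantile(stats["n_counts"], 1 - thresholds.top_count_quantile)

    low_genes = stats["n_genes"].to_numpy() < thresholds.min_genes
    high_mito = stats["mito_frac"].to_numpy() > thresholds.max_mito
    top_genes = stats["n_genes"].to_numpy() > gene_cut
    top_counts = stats["n_counts"].to_numpy() > count_cut
    remove = low_genes | high_mito | top_genes | top_counts
    keep = ~remove

    summary = {
        "n_input": int(adata.n_obs),
        "n_retained": int(keep.sum()),
        "removed_low_genes": int(low_genes.sum()),
        "removed_high_mito": int(high_mito.sum()),
        "removed_top_genes": int(top_genes.sum()),
        "removed_top_counts": int(top_counts.sum()),
        "gene_quantile_cutoff": float(gene_cut),
        "count_quantile_cutoff": float(count_cut),
        "all_removed_warning": bool(keep.sum() == 0),
    }
    return adata[keep].copy(), keep, summary
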