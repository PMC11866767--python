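"""Reading and writing 10x-style MTX triplet directories.

Layout produced by :func:`write_10x_dirs`::

    out/
      metadata.tsv              # barcode, library, condition[, true_label]
      <library-id>/
        matrix.mtx              # genes x cells, MatrixMarket integer
        features.tsv            # gene ids
        barcodes.tsv            # cell barcodes

All files are plain text so fixtures stay diffable.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_10x_dirs(adata: ad.AnnData, outdir: str) -> list[str]:
    """Write one MTX triplet per library plus a combined metadata table.

    Returns the list of files written (for pipeline manifests).
    """
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    if "library" not in adata.obs:
        raise ValueError("adata.obs must carry a 'library' column")
    meta_cols = [c for c in ("library", "condition", "true_label") if c in adata.obs]
    meta = adata.obs[meta_cols].copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta_path = os.path.join(outdir, "metadata.tsv")
    meta.to_csv(meta_path, sep="\t", index=False)
    written.append(meta_path)
    for lib in meta["library"].unique():
        sub = adata[adata.obs["library"] == lib]
        libdir = os.path.join(outdir, str(lib))
        os.makedirs(libdir, exist_ok=True)
        mat = sp.csr_matrix(sub.X).T.tocoo()  # genes x cells, 10x orientation
        mtx_path = os.path.join(libdir, "matrix.mtx")
        scipy.io.mmwrite(mtx_path, mat, field="integer")
        feat_path = os.path.join(libdir, "features.tsv")
        pd.Series(adata.var_names).to_csv(feat_path, sep="\t", index=False, header=False)
        bc_path = os.path.join(libdir, "barcodes.tsv")
        pd.Series(sub.obs_names).to_csv(bc_path, sep="\t", index=False, header=False)
        written.extend([mtx_path, feat_path, bc_path])
    return written


def read_10x_dirs(indir: str) -> ad.AnnData:
    """Read a directory written by :func:`write_10x_dirs` back into AnnData."""
    meta_path = os.path.join(indir, "metadata.tsv")
    if not os.path.exists(meta_path):
        raise FileNotFoundError(f"no metadata.tsv under {indir}")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    blocks = []
    var_names = None
    barcodes = []
    for lib in meta["library"].unique():
        libdir = os.path.join(indir, str(lib))
        mat = scipy.io.mmread(os.path.join(libdir, "matrix.mtx"))
        genes = pd.read_csv(
            os.path.join(libdir, "features.tsv"), sep="\t", header=None
        )[0].tolist()
        bcs = pd.read_csv(
            os.path.join(libdir, "barcodes.tsv"), sep="\t", header=None
        )[0].tolist()
        if var_names is None:
            var_names = genes
        elif genes != var_names:
            raise ValueError(f"feature list of library {lib} disagrees with the first")
        blocks.append(sp.csr_matrix(mat.T))  # back to cells x genes
        barcodes.extend(bcs)
    X = sp.vstack(blocks).tocsr()
    obs = meta.set_index("barcode").loc[barcodes]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=var_names))
    adata.obs_names = barcodes
    return adata
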