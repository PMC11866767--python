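"""Marker-panel cluster annotation and per-cell gates.

Clusters are scored against a named marker panel with a standardized
mean-difference: for each marker, (mean normalized expression in the
cluster − mean in all other cells) / pooled SD, averaged over the label's
markers. The argmax label wins; near-ties are flagged.

Per-cell gates use raw-count detection (count >= 1) — the least
parameterized positivity rule:

* tumor cells: Ighg2b detected;
* EndoMT: an endothelial marker (Cdh5 or Pecam1) AND a stromal marker
  (Prrx1 or Col1a1) both detected; abundance is reported relative to the
  Cdh5+ cells of each condition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from stromaniche.preprocess import LOGNORM_LAYER, ClusterAssignment

AMBIGUITY_MARGIN = 0.1

SEC_MARKERS = ["Flt4", "Il6st"]
AEC_MARKERS = ["Ly6a", "Cxcl12"]


@dataclass
class AnnotationResult:
    labels: dict[int, str]  # cluster id -> winning label
    scores: pd.DataFrame  # clusters x labels raw score table
    ambiguous: dict[int, bool]


def read_marker_panel(path) -> dict[str, list[str]]:
    with open(path) as fh:
        panel = json.load(fh)
    for label, markers in panel.items():
        if not markers:
            raise ValueError(f"panel label {label!r} has no markers")
    return panel


def default_marker_panel() -> dict[str, list[str]]:
    """The seven stromal population panels shipped with the package."""
    ref = resources.files("stromaniche") / "data" / "marker_panels.json"
    return read_marker_panel(ref)


def _dense_lognorm(adata: ad.AnnData, genes: list[str]) -> np.ndarray:
    idx = [adata.var_names.get_loc(g) for g in genes]
    return np.asarray(sp.csr_matrix(adata.layers[LOGNORM_LAYER])[:, idx].todense())


def score_clusters(
    adata: ad.AnnData, clusters: ClusterAssignment, panel: dict[str, list[str]]
) -> AnnotationResult:
    """Label clusters by standardized marker-score argmax; ties go to the
    lexicographically smaller label and are flagged as ambiguous."""
    present_panel: dict[str, list[str]] = {}
    for label, markers in panel.items():
        present = [g for g in markers if g in adata.var_names]
        if not present:
            raise ValueError(f"no markers of panel label {label!r} present in the gene universe")
        present_panel[label] = present

    labels = clusters.labels
    cluster_ids = sorted(set(labels.tolist()))
    all_genes = sorted({g for ms in present_panel.values() for g in ms})
    M = _dense_lognorm(adata, all_genes)
    col = {g: j for j, g in enumerate(all_genes)}

    rows = []
    for c in cluster_ids:
        inside = labels == c
        rest = ~inside
        row = {}
        for label, markers in present_panel.items():
            vals = []
            for g in markers:
                x_in, x_out = M[inside, col[g]], M[rest, col[g]]
                n1, n2 = x_in.size, x_out.size
                if n2 == 0:
                    vals.append(0.0)
                    continue
                pooled = np.sqrt(
                    ((n1 - 1) * x_in.var(ddof=1 if n1 > 1 else 0)
                     + (n2 - 1) * x_out.var(ddof=1 if n2 > 1 else 0))
                    / max(n1 + n2 - 2, 1)
                )
                vals.append(0.0 if pooled == 0 else (x_in.mean() - x_out.mean()) / pooled)
            row[label] = float(np.mean(vals))
        rows.append(row)

    scores = pd.DataFrame(rows, index=cluster_ids)
    winners, ambiguous = {}, {}
    for c in cluster_ids:
        s = scores.loc[c].sort_values(ascending=False, kind="stable")
        # ties broken lexicographically
        top_val = s.iloc[0]
        tied = sorted(s.index[np.isclose(s.values, top_val, rtol=0, atol=1e-12)])
        winners[c] = tied[0]
        runner = s.iloc[1] if len(s) > 1 else -np.inf
        ambiguous[c] = bool(top_val - runner < AMBIGUITY_MARGIN)
    return AnnotationResult(winners, scores, ambiguous)


def split_endothelial(
    adata: ad.AnnData, clusters: ClusterAssignment, ec_clusters: list[int]
) -> dict[int, dict]:
    """Assign each endothelial cluster AEC or SEC by the larger standardized
    subtype score; exact ties fall to AEC (fixed precedence) with a flag."""
    for g in SEC_MARKERS + AEC_MARKERS:
        if g not in adata.var_names:
            raise ValueError(f"endothelial subtype marker {g} absent")
    genes = SEC_MARKERS + AEC_MARKERS
    ec_cells = np.isin(clusters.labels, ec_clusters)
    M = _dense_lognorm(adata, genes)[ec_cells]
    mu, sd = M.mean(axis=0), M.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (M - mu) / sd
    labels_ec = clusters.labels[ec_cells]
    out = {}
    for c in ec_clusters:
        zc = Z[labels_ec == c]
        sec = float(zc[:, :2].mean())
        aec = float(zc[:, 2:].mean())
        if sec > aec:
            call = "SEC"
        else:
            call = "AEC"
        out[c] = {
            "label": call,
            "sec_score": sec,
            "aec_score": aec,
            "margin": abs(sec - aec),
            "ambiguous": bool(sec == aec),
        }
    return out


def _detected(adata: ad.AnnData, gene: str) -> np.ndarray:
    j = adata.var_names.get_loc(gene)
    return np.asarray(sp.csr_matrix(adata.X)[:, j].todense()).ravel() >= 1


def gate_tumor_cells(adata: ad.AnnData, gene: str = "Ighg2b") -> np.ndarray:
    """Flag cells with any detected Ighg2b transcript as tumor cells."""
    if gene not in adata.var_names:
        warnings.warn(f"{gene} absent from gene universe; no tumor cells flagged")
        return np.zeros(adata.n_obs, dtype=bool)
    return _detected(adata, gene)


def gate_endomt(adata: ad.AnnData) -> tuple[np.ndarray, pd.DataFrame]:
    """EndoMT flags plus per-condition abundance among Cdh5+ cells."""
    for g in ("Cdh5", "Pecam1", "Prrx1", "Col1a1"):
        if g not in adata.var_names:
            raise ValueError(f"EndoMT gate gene {g} absent from gene universe")
    endo = _detected(adata, "Cdh5") | _detected(adata, "Pecam1")
    stromal = _detected(adata, "Prrx1") | _detected(adata, "Col1a1")
    flag = endo & stromal
    denom = _detected(adata, "Cdh5")
    rows = []
    conds = adata.obs["condition"].unique() if "condition" in adata.obs else ["all"]
    for cond in conds:
        mask = (
            (adata.obs["condition"] == cond).to_numpy()
            if "condition" in adata.obs
            else np.ones(adata.n_obs, dtype=bool)
        )
        n_denom = int((denom & mask).sum())
        n_endomt = int((flag & denom & mask).sum())
        rows.append({
            "condition": cond,
            "n_cdh5_pos": n_denom,
            "n_endomt": n_endomt,
            "relative_abundance": n_endomt / n_denom if n_denom else np.nan,
        })
    return flag, pd.DataFrame(rows)
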