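"""End-to-end orchestration from a single JSON-able config.

Stages run in dependency order (simulate -> qc -> cluster -> annotate ->
abundance -> de -> gsea -> trajectory -> endomt -> ligands); each stage can
be toggled, every output file is recorded in a manifest together with its
SHA-256 hash and the stage parameters, and a rerun with the same config and
seed reproduces identical hashes for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from stromaniche import abundance as ab
from stromaniche import annotate as an
from stromaniche import de as de_mod
from stromaniche import gsea as gsea_mod
from stromaniche import io as io_mod
from stromaniche import ligands as lig_mod
from stromaniche import preprocess as pp
from stromaniche import qc as qc_mod
from stromaniche import synthetic as syn
from stromaniche import trajectory as tj

log = logging.getLogger("stromaniche.pipeline")

STAGES = ["simulate", "qc", "cluster", "annotate", "abundance", "de", "gsea",
          "trajectory", "endomt", "ligands"]

DEFAULT_CONFIG: dict = {
    "outdir": "pipeline_out",
    "seed": 0,
    "stages": {s: True for s in STAGES} | {"trajectory": False, "ligands": False},
    "simulate": {"n_genes": 1000, "n_cells_per_library": 2000,
                 "marker_fold": 8.0, "tumor_spike_fraction": 0.02},
    "qc": {"min_genes": 500, "max_mito": 0.05,
           "top_gene_quantile": 0.02, "top_count_quantile": 0.05},
    "cluster": {"n_hvgs": 2000, "n_components": 30, "k_neighbors": 20,
                "resolution": 0.2},
    "gsea": {"n_sets": 20, "set_size": 30, "n_perm": 200},
    "ligands": {"n_ligands": 10, "min_frac": 0.10},
}


def _validate_config(config: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in config.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(val, dict):
            unknown = set(val) - set(cfg[key])
            if unknown:
                raise ValueError(f"unknown keys under {key!r}: {sorted(unknown)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | None = None) -> dict:
    """Run the enabled stages; returns (and writes) the manifest."""
    cfg = _validate_config(config or {})
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed = cfg["seed"]
    manifest: dict = {"config": cfg, "stages": {}}

    def record(stage: str, files: list[str], params: dict) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {os.path.relpath(f, outdir): _sha256(f) for f in files},
        }

    def fail(stage: str, err: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    adata = None
    clusters = None
    embedding = None
    annotation = None

    if cfg["stages"]["simulate"]:
        log.info("stage simulate")
        try:
            sim_cfg = syn.default_config(seed=seed, **cfg["simulate"])
            dataset = syn.simulate_dataset(sim_cfg)
            adata = dataset.adata
            files = io_mod.write_10x_dirs(adata, os.path.join(outdir, "counts"))
        except Exception as err:  # noqa: BLE001
            fail("simulate", err)
        record("simulate", files, cfg["simulate"] | {"seed": seed})

    if cfg["stages"]["qc"] and adata is not None:
        log.info("stage qc")
        try:
            thresholds = qc_mod.QCThresholds(**cfg["qc"])
            adata, keep, summary = qc_mod.filter_cells(adata, thresholds)
            path = os.path.join(outdir, "qc_summary.json")
            with open(path, "w") as fh:
                json.dump(summary, fh, indent=2)
            flags = os.path.join(outdir, "qc_keep.tsv")
            pd.DataFrame({"keep": keep}).to_csv(flags, sep="\t")
        except Exception as err:  # noqa: BLE001
            fail("qc", err)
        record("qc", [path, flags], cfg["qc"])

    if cfg["stages"]["cluster"] and adata is not None:
        log.info("stage cluster")
        try:
            pp.log_normalize(adata)
            p = cfg["cluster"]
            hvgs = pp.select_hvgs(adata, p["n_hvgs"])
            embedding = pp.embed(adata, hvgs, p["n_components"])
            clusters = pp.cluster_graph(embedding, p["k_neighbors"], p["resolution"], seed)
            path = os.path.join(outdir, "clusters.tsv")
            pd.DataFrame({"cell": adata.obs_names, "cluster": clusters.labels}
                         ).to_csv(path, sep="\t", index=False)
        except Exception as err:  # noqa: BLE001
            fail("cluster", err)
        record("cluster", [path], cfg["cluster"])

    if cfg["stages"]["annotate"] and clusters is not None:
        log.info("stage annotate")
        try:
            annotation = an.score_clusters(adata, clusters, an.default_marker_panel())
            path = os.path.join(outdir, "annotation.tsv")
            tab = annotation.scores.copy()
            tab["label"] = [annotation.labels[c] for c in tab.index]
            tab["ambiguous"] = [annotation.ambiguous[c] for c in tab.index]
            tab.to_csv(path, sep="\t")
        except Exception as err:  # noqa: BLE001
            fail("annotate", err)
        record("annotate", [path], {})

    if cfg["stages"]["abundance"] and annotation is not None:
        log.info("stage abundance")
        try:
            labels = pd.Series([annotation.labels[c] for c in clusters.labels],
                               index=adata.obs_names)
            comp = ab.LabeledComposition.from_labels(labels, adata.obs["condition"])
            result = ab.bootstrap_abundance(comp, B=100, seed=seed)
            path = os.path.join(outdir, "abundance.tsv")
            result.table.to_csv(path, sep="\t")
        except Exception as err:  # noqa: BLE001
            fail("abundance", err)
        record("abundance", [path], {"B": 100, "seed": seed})

    de_table = None
    if cfg["stages"]["de"] and adata is not None:
        log.info("stage de")
        try:
            if pp.LOGNORM_LAYER not in adata.layers:
                pp.log_normalize(adata)
            cond = adata.obs["condition"].to_numpy()
            de_table = de_mod.wilcoxon_de(adata, cond == "tumor", cond == "control")
            path = os.path.join(outdir, "de.tsv")
            de_table.to_csv(path, sep="\t")
        except Exception as err:  # noqa: BLE001
            fail("de", err)
        record("de", [path], {})

    if cfg["stages"]["gsea"] and de_table is not None:
        log.info("stage gsea")
        try:
            ranked = de_mod.rank_genes(de_table)
            p = cfg["gsea"]
            sets = gsea_mod.make_synthetic_gene_sets(
                list(adata.var_names), p["n_sets"], p["set_size"], seed)
            res = gsea_mod.gsea_preranked(ranked, sets, p["n_perm"], seed)
            path = os.path.join(outdir, "gsea.tsv")
            res.table.to_csv(path, sep="\t")
        except Exception as err:  # noqa: BLE001
            fail("gsea", err)
        record("gsea", [path], p)

    if cfg["stages"]["trajectory"] and clusters is not None and embedding is not None:
        log.info("stage trajectory")
        try:
            root = 0  # largest cluster by the relabeling convention
            res = tj.fit_trajectory(embedding, clusters, root)
            path = os.path.join(outdir, "trajectory.tsv")
            tj.trajectory_table(res, clusters, adata.obs_names).to_csv(
                path, sep="\t", index=False)
        except Exception as err:  # noqa: BLE001
            fail("trajectory", err)
        record("trajectory", [path], {"root": 0})

    if cfg["stages"]["endomt"] and adata is not None:
        log.info("stage endomt")
        try:
            flag, rates = an.gate_endomt(adata)
            path = os.path.join(outdir, "endomt.tsv")
            rates.to_csv(path, sep="\t", index=False)
        except Exception as err:  # noqa: BLE001
            fail("endomt", err)
        record("endomt", [path], {})

    if cfg["stages"]["ligands"] and adata is not None and de_table is not None:
        log.info("stage ligands")
        try:
            p = cfg["ligands"]
            tumor_mask = an.gate_tumor_cells(adata)
            if tumor_mask.sum() == 0:
                raise ValueError("no tumor (sender) cells found")
            sender = lig_mod.expressed_genes(adata, tumor_mask, p["min_frac"])
            response = (de_table["q_value"] < 0.05).astype(int)
            prior = lig_mod.make_synthetic_prior(
                list(adata.var_names), p["n_ligands"],
                response_genes=list(response.index[response == 1]), seed=seed)
            sender = sender | {"Tgfb1"}  # ensure the named ligand is scoreable
            table = lig_mod.ligand_activity(prior, sender, response)
            path = os.path.join(outdir, "ligand_activity.tsv")
            table.to_csv(path, sep="\t")
        except Exception as err:  # noqa: BLE001
            fail("ligands", err)
        record("ligands", [path], p)

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
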