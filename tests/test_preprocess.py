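"""Normalization, HVG selection, embedding and clustering contracts."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score

from stromaniche import preprocess as pp
from stromaniche import synthetic as syn


def _adata(counts, genes=None, library=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    obs = pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])])
    if library is not None:
        obs["library"] = library
    return ad.AnnData(X=sp.csr_matrix(counts), var=pd.DataFrame(index=genes), obs=obs)


# --- log_normalize ----------------------------------------------------------


def test_lognorm_zero_count_is_zero_and_analytic_value():
    adata = _adata([[1, 9999, 0]])
    pp.log_normalize(adata, 1e4)
    vals = np.asarray(adata.layers["lognorm"].todense())[0]
    assert vals[2] == 0.0
    assert vals[0] == pytest.approx(np.log(2), abs=1e-12)  # 1 of 10,000 at sf 10,000


def test_lognorm_matches_dense_oracle(rng):
    counts = rng.integers(0, 20, size=(50, 20))
    counts[:, 0] += 1  # no zero-total cells
    adata = _adata(counts)
    pp.log_normalize(adata, 1e4)
    totals = counts.sum(1, keepdims=True)
    oracle = np.log1p(1e4 * counts / totals)
    assert np.allclose(np.asarray(adata.layers["lognorm"].todense()), oracle, atol=1e-12)


def test_lognorm_zero_total_cell_raises():
    adata = _adata([[1, 2], [0, 0]])
    with pytest.raises(ValueError, match="c1"):
        pp.log_normalize(adata)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.integers(0, 100), min_size=3, max_size=12))
def test_lognorm_monotone_within_cell(counts):
    counts = [c + 1 for c in counts]
    adata = _adata([counts])
    pp.log_normalize(adata)
    vals = np.asarray(adata.layers["lognorm"].todense())[0]
    order = np.argsort(counts, kind="stable")
    assert np.all(np.diff(vals[order]) >= -1e-12)


# --- HVG selection ----------------------------------------------------------


def test_constant_gene_never_selected_over_variable():
    # two cell patterns with equal totals: g0 constant, g1/g2 variable
    counts = np.array([[5, 1, 9], [5, 9, 1]] * 30)
    adata = _adata(counts)
    pp.log_normalize(adata)
    top = pp.select_hvgs(adata, 2)
    assert "g0" not in top


def test_hvg_tie_broken_lexicographically():
    counts = np.array([[1, 1, 5], [5, 5, 1], [1, 1, 5], [5, 5, 1]])
    adata = _adata(counts, genes=["zeta", "alpha", "other"])
    pp.log_normalize(adata)
    top = pp.select_hvgs(adata, 3)
    # zeta and alpha have identical variance: alpha must rank first
    assert top.index("alpha") < top.index("zeta")


def test_hvg_recovers_planted_markers(rng):
    """100 bimodal planted genes against steady filler: >= 95 recovered."""
    genes = [f"Planted{i:03d}" for i in range(100)] + [f"Filler{i:03d}" for i in range(200)]
    n = 600
    pop = rng.integers(0, 2, size=n).astype(bool)
    counts = rng.poisson(3.0, size=(n, 300))
    planted = rng.poisson(8.0, size=(pop.sum(), 100))
    counts[np.flatnonzero(pop)[:, None], np.arange(100)[None, :]] = planted
    counts[~pop, :100] = rng.poisson(0.1, size=((~pop).sum(), 100))
    adata = _adata(counts, genes=genes)
    pp.log_normalize(adata)
    top = set(pp.select_hvgs(adata, 100))
    assert sum(g.startswith("Planted") for g in top) >= 95


def test_hvg_invalid_n():
    adata = _adata([[1, 2], [3, 4]])
    pp.log_normalize(adata)
    with pytest.raises(ValueError):
        pp.select_hvgs(adata, 0)


# --- embedding --------------------------------------------------------------


def test_single_library_center_flag_is_noop(small_normalized):
    one_lib = small_normalized[small_normalized.obs["library"] == "PBS-1"].copy()
    hvgs = pp.select_hvgs(one_lib, 50)
    a = pp.embed(one_lib, hvgs, 10, center_per_library=True)
    b = pp.embed(one_lib, hvgs, 10, center_per_library=False)
    assert np.allclose(a.pcs, b.pcs, atol=1e-8)


def test_library_size_factor_not_separable_after_standardization():
    """Two libraries differing by a global size factor: a logistic probe on
    PC1-2 cannot tell them apart (accuracy <= 0.6)."""
    genes = syn.default_gene_universe(200)
    cfg = syn.SimulationConfig(
        genes=genes, populations=syn.default_stromal_profiles(genes),
        composition={"control": syn.table_composition("control")},
        libraries=[("A", "control"), ("B", "control")],
        n_cells_per_library=400, library_effect_sd=0.6, seed=13,
    )
    adata = syn.simulate_dataset(cfg).adata
    pp.log_normalize(adata)
    emb = pp.embed(adata, pp.select_hvgs(adata, 2000), 10, center_per_library=True)
    y = (adata.obs["library"] == "A").to_numpy()
    acc = LogisticRegression(max_iter=1000).fit(emb.pcs[:, :2], y).score(emb.pcs[:, :2], y)
    assert acc <= 0.6


def test_rank_limited_data_has_no_variance_beyond_rank():
    """Three exact expression patterns give a standardized matrix of rank 2."""
    patterns = np.array([[5, 1, 1, 3], [1, 5, 1, 3], [1, 1, 5, 3]])
    counts = np.repeat(patterns, 30, axis=0)
    adata = _adata(counts)
    pp.log_normalize(adata)
    emb = pp.embed(adata, list(adata.var_names), 4)
    assert np.all(emb.explained_variance_ratio[2:] < 1e-9)


def test_embed_reduces_components_beyond_rank():
    adata = _adata(np.tile([[2, 3, 4]], (10, 1)) + np.eye(10, 3, dtype=int))
    pp.log_normalize(adata)
    with pytest.warns(UserWarning):
        emb = pp.embed(adata, list(adata.var_names), 8)
    assert emb.n_components <= 3


def test_pca_reconstruction_error_nonincreasing(small_normalized):
    hvgs = pp.select_hvgs(small_normalized, 40)
    emb = pp.embed(small_normalized, hvgs, 20)
    # cumulative explained variance is non-decreasing <=> reconstruction
    # error non-increasing in the number of components
    assert np.all(np.diff(np.cumsum(emb.explained_variance_ratio)) >= 0)


# --- clustering -------------------------------------------------------------


def _blobs(rng, n=200, sep=20.0):
    a = rng.normal(size=(n, 5))
    b = rng.normal(size=(n, 5))
    b[:, 0] += sep
    return np.vstack([a, b])


def test_two_blobs_two_clusters(rng):
    pcs = _blobs(rng)
    emb = pp.EmbeddingResult(pcs, 5, [], np.array([]))
    cl = pp.cluster_graph(emb, 20, 0.2, seed=1)
    truth = np.repeat([0, 1], 200)
    assert cl.n_clusters == 2
    assert adjusted_rand_score(truth, cl.labels) == 1.0


def test_identical_coordinates_single_cluster():
    emb = pp.EmbeddingResult(np.zeros((50, 3)), 3, [], np.array([]))
    cl = pp.cluster_graph(emb, 10, 0.2, seed=1)
    assert cl.n_clusters == 1


def test_clustering_order_invariance_on_separable_data(rng):
    pcs = _blobs(rng)
    emb = pp.EmbeddingResult(pcs, 5, [], np.array([]))
    ref = pp.cluster_graph(emb, 15, 0.2, seed=3).labels
    perm = rng.permutation(pcs.shape[0])
    shuffled = pp.cluster_graph(pp.EmbeddingResult(pcs[perm], 5, [], np.array([])),
                                15, 0.2, seed=3).labels
    unshuffled = np.empty_like(shuffled)
    unshuffled[perm] = shuffled
    assert adjusted_rand_score(ref, unshuffled) == 1.0


def test_cluster_relabeling_by_size(rng):
    pcs = np.vstack([rng.normal(size=(300, 4)),
                     rng.normal(size=(100, 4)) + 30])
    cl = pp.cluster_graph(pp.EmbeddingResult(pcs, 4, [], np.array([])), 15, 0.2, seed=0)
    sizes = np.bincount(cl.labels)
    assert np.all(np.diff(sizes) <= 0)


def test_seven_populations_recovered(small_normalized, small_dataset):
    from stromaniche.annotate import gate_tumor_cells

    adata = small_normalized
    keep = ~gate_tumor_cells(adata)
    sub = adata[keep].copy()
    cl = pp.subcluster(sub, np.ones(sub.n_obs, bool), target_k=7, seed=7)
    truth = sub.obs["true_label"].to_numpy()
    assert adjusted_rand_score(truth, cl.labels) >= 0.9


# --- subcluster -------------------------------------------------------------


def test_subcluster_homogeneous_target_one(rng):
    genes = syn.default_gene_universe(150)
    cfg = syn.SimulationConfig(
        genes=genes, populations=[syn.make_profile("MSC", genes, ["Lepr"])],
        composition={"control": np.array([1.0])}, libraries=[("L", "control")],
        n_cells_per_library=200, seed=1,
    )
    adata = syn.simulate_dataset(cfg).adata
    cl = pp.subcluster(adata, np.ones(200, bool), target_k=1, seed=1)
    assert cl.n_clusters == 1 and not cl.mismatch


def test_subcluster_msc_lineage_six_profiles():
    genes = syn.default_gene_universe(250)
    cfg = syn.SimulationConfig(
        genes=genes, populations=syn.msc_lineage_profiles(genes),
        composition={"control": np.full(6, 1 / 6)},
        libraries=[("L", "control")], n_cells_per_library=1500, seed=17,
    )
    ds = syn.simulate_dataset(cfg)
    cl = pp.subcluster(ds.adata, np.ones(ds.adata.n_obs, bool), target_k=6, seed=17)
    assert cl.n_clusters == 6 and not cl.mismatch
    assert adjusted_rand_score(ds.true_labels.to_numpy(), cl.labels) >= 0.8


def test_subcluster_infeasible_target_sets_mismatch():
    genes = syn.default_gene_universe(150)
    cfg = syn.SimulationConfig(
        genes=genes, populations=[syn.make_profile("MSC", genes, ["Lepr"])],
        composition={"control": np.array([1.0])}, libraries=[("L", "control")],
        n_cells_per_library=60, seed=1,
    )
    adata = syn.simulate_dataset(cfg).adata
    cl = pp.subcluster(adata, np.ones(60, bool), target_k=50, seed=1, k_neighbors=10)
    assert cl.mismatch


def test_subcluster_rejects_tiny_subset(small_normalized):
    with pytest.raises(ValueError):
        pp.subcluster(small_normalized, np.arange(5), target_k=2)
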