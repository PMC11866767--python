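"""Differential expression, gene ranking, and the weighted-KS enrichment
statistic with its permutation null."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from stromaniche import de as de_mod
from stromaniche import gsea
from stromaniche import preprocess as pp
from stromaniche import synthetic as syn
from stromaniche.de import RankedList


def _adata(counts, genes=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    a = ad.AnnData(X=sp.csr_matrix(counts), var=pd.DataFrame(index=genes),
                   obs=pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])]))
    pp.log_normalize(a)
    return a


# --- wilcoxon_de ------------------------------------------------------------


def test_duplicated_cells_have_zero_logfc(rng):
    counts = rng.integers(1, 20, size=(10, 8))
    adata = _adata(np.vstack([counts, counts]))
    res = de_mod.wilcoxon_de(adata, np.arange(10), np.arange(10, 20))
    assert np.allclose(res["log_fc"], 0.0, atol=1e-12)
    assert (res["p_value"] > 0.9).all()


def test_overlapping_groups_raise(small_normalized):
    with pytest.raises(ValueError):
        de_mod.wilcoxon_de(small_normalized, np.arange(5), np.arange(3, 8))


def test_asymptotic_p_close_to_exact_enumeration(rng):
    """6-vs-6: the tie-corrected normal approximation tracks the exact
    permutation distribution (all 924 assignments) within 0.05."""
    from scipy.stats import rankdata

    for trial in range(5):
        vals = np.round(rng.normal(size=12), 1)  # rounding induces ties
        adata = _adata(np.maximum((vals[:, None] * 3 + 10).astype(int), 0))
        res = de_mod.wilcoxon_de(adata, np.arange(6), np.arange(6, 12))
        x = np.asarray(adata.layers["lognorm"].todense())[:, 0]
        # exact two-sided permutation p of the rank-sum statistic
        ranks = rankdata(x)
        obs = ranks[:6].sum()
        null = np.array([ranks[list(c)].sum() for c in itertools.combinations(range(12), 6)])
        exact = np.mean(np.abs(null - null.mean()) >= abs(obs - null.mean()) - 1e-12)
        assert abs(res["p_value"].iloc[0] - exact) < 0.05


def test_planted_twofold_genes_recovered():
    """Genes elevated 2x in one condition reach BH q < 0.05 at n=200/group."""
    genes = [f"up{i}" for i in range(50)] + [f"null{i}" for i in range(150)]
    rng = np.random.default_rng(31)
    a = rng.poisson(6.0, size=(200, 200))
    b = rng.poisson(6.0, size=(200, 200))
    a[:, :50] = rng.poisson(12.0, size=(200, 50))
    adata = _adata(np.vstack([a, b]), genes=genes)
    res = de_mod.wilcoxon_de(adata, np.arange(200), np.arange(200, 400))
    hits = (res["q_value"].iloc[:50] < 0.05).sum()
    assert hits >= 45
    assert res["log_fc"].iloc[:50].min() > 0


def test_bh_adjusted_p_not_below_p(small_normalized):
    cond = small_normalized.obs["condition"].to_numpy()
    res = de_mod.wilcoxon_de(small_normalized, cond == "tumor", cond == "control")
    assert (res["q_value"] >= res["p_value"] - 1e-15).all()
    assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()


# --- rank_genes -------------------------------------------------------------


def test_rank_score_arithmetic():
    table = pd.DataFrame({"log_fc": [0.5], "p_value": [0.01], "q_value": [0.02]},
                         index=["g"])
    ranked = de_mod.rank_genes(table)
    assert ranked.scores[0] == pytest.approx(2.0)


def test_rank_ties_broken_by_abs_logfc_then_id():
    table = pd.DataFrame(
        {"log_fc": [0.2, 0.8, -0.8], "p_value": [0.1, 0.1, 0.1],
         "q_value": [0.1, 0.1, 0.1]},
        index=["a", "b", "c"])
    ranked = de_mod.rank_genes(table)
    assert ranked.genes[0] == "b"  # larger |logFC| first among positive ties
    assert ranked.genes[-1] == "c"


def test_rank_matches_brute_force_sort(rng):
    n = 40
    table = pd.DataFrame({
        "log_fc": rng.normal(size=n),
        "p_value": rng.uniform(1e-6, 1, size=n),
    }, index=[f"g{i:02d}" for i in range(n)])
    table["q_value"] = table["p_value"]
    ranked = de_mod.rank_genes(table)
    score = np.sign(table["log_fc"]) * -np.log10(table["p_value"])
    oracle = sorted(table.index,
                    key=lambda g: (-score[g], -abs(table.loc[g, "log_fc"]), g))
    assert ranked.genes == oracle


# --- enrichment score -------------------------------------------------------


def oracle_es(scores, member_mask, weight=1.0):
    """Literal running-sum walk; earliest strictly-larger |deviation| wins
    (epsilon-guarded against float accumulation)."""
    n = len(scores)
    w = np.abs(np.asarray(scores, float)) ** weight
    tot = w[member_mask].sum()
    k = int(member_mask.sum())
    run, best = 0.0, 0.0
    for i in range(n):
        if member_mask[i]:
            run += w[i] / tot if tot > 0 else 0.0
        else:
            run -= 1.0 / (n - k)
        if abs(run) > abs(best) + 1e-12:
            best = run
    return best


def test_es_matches_exhaustive_oracle_all_small_lists(rng):
    """All proper non-empty subsets of ranked lists of length 2..8."""
    for n in range(2, 9):
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = RankedList(genes, scores)
        for r in range(1, n):
            for sub in itertools.combinations(range(n), r):
                mask = np.zeros(n, bool)
                mask[list(sub)] = True
                es, _, _ = gsea.enrichment_score(ranked, [genes[i] for i in sub])
                assert es == pytest.approx(oracle_es(scores, mask), abs=1e-12), (n, sub)


def test_singleton_at_top_is_exactly_one():
    ranked = RankedList(["a", "b", "c", "d", "e"], np.array([5.0, 4, 3, 2, 1]))
    es, _, leading = gsea.enrichment_score(ranked, ["a"])
    assert es == 1.0
    assert leading == ["a"]


def test_full_universe_set_defined_as_one_with_warning():
    ranked = RankedList(["a", "b"], np.array([2.0, 1.0]))
    with pytest.warns(UserWarning):
        es, _, _ = gsea.enrichment_score(ranked, ["a", "b"])
    assert es == 1.0


def test_no_overlap_raises():
    ranked = RankedList(["a", "b"], np.array([2.0, 1.0]))
    with pytest.raises(ValueError):
        gsea.enrichment_score(ranked, ["zzz"])


def _extreme_deviations(scores, member_mask, weight=1.0):
    """(max positive, max negative) running-sum deviation of the walk."""
    n = len(scores)
    w = np.abs(np.asarray(scores, float)) ** weight
    tot = w[member_mask].sum()
    k = int(member_mask.sum())
    run, hi, lo = 0.0, 0.0, 0.0
    for i in range(n):
        run += (w[i] / tot if tot > 0 else 0.0) if member_mask[i] else -1.0 / (n - k)
        hi, lo = max(hi, run), min(lo, run)
    return hi, lo


def test_es_magnitude_preserved_and_sign_flipped_under_reversal(rng):
    for _ in range(100):
        n = int(rng.integers(5, 40))
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        sub = rng.choice(n, size=int(rng.integers(1, n)), replace=False)
        members = [genes[i] for i in sub]
        es, _, _ = gsea.enrichment_score(RankedList(genes, scores), members)
        es_rev, _, _ = gsea.enrichment_score(
            RankedList(genes[::-1], -scores[::-1]), members)
        assert abs(abs(es) - abs(es_rev)) < 1e-9
        mask = np.zeros(n, bool)
        mask[sub] = True
        hi, lo = _extreme_deviations(scores, mask)
        if abs(hi + lo) > 1e-9:  # unique extremum sign: reversal must negate
            assert es_rev == pytest.approx(-es, abs=1e-9)


def test_es_invariant_to_relabeling_nonmembers(rng):
    n = 30
    scores = np.sort(rng.normal(size=n))[::-1]
    genes = [f"g{i}" for i in range(n)]
    sub = [2, 7, 19]
    es, _, _ = gsea.enrichment_score(RankedList(genes, scores), [genes[i] for i in sub])
    renamed = [g if i in sub else f"x{i}" for i, g in enumerate(genes)]
    es2, _, _ = gsea.enrichment_score(RankedList(renamed, scores),
                                      [renamed[i] for i in sub])
    assert es == es2


def test_moving_member_up_never_decreases_positive_es(rng):
    for _ in range(50):
        n = 20
        scores = np.sort(np.abs(rng.normal(size=n)))[::-1]
        genes = [f"g{i}" for i in range(n)]
        sub = sorted(rng.choice(n, size=4, replace=False))
        es, _, _ = gsea.enrichment_score(RankedList(genes, scores),
                                         [genes[i] for i in sub])
        if es <= 0 or sub[0] == 0:
            continue
        moved = [sub[0] - 1] + sub[1:]
        if len(set(moved)) < len(moved):
            continue
        es_up, _, _ = gsea.enrichment_score(RankedList(genes, scores),
                                            [genes[i] for i in moved])
        assert es_up >= es - 1e-12


def test_es_agrees_with_independent_gsea_implementation():
    """Cross-check against gseapy's preranked ES on a deterministic case."""
    gseapy = pytest.importorskip("gseapy")
    genes = [f"g{i}" for i in range(50)]
    scores = np.linspace(5, 0.1, 50)
    sets = {"S1": [genes[i] for i in (0, 3, 7, 20, 40)],
            "S2": [genes[i] for i in (45, 46, 47, 48, 49)]}
    res = gseapy.prerank(rnk=pd.DataFrame({"gene": genes, "score": scores}),
                         gene_sets=sets, permutation_num=20, seed=1,
                         outdir=None, min_size=2, no_plot=True, threads=1)
    ours = {name: gsea.enrichment_score(RankedList(genes, scores), m)[0]
            for name, m in sets.items()}
    for _, row in res.res2d.iterrows():
        assert ours[row["Term"]] == pytest.approx(float(row["ES"]), abs=1e-9)


# --- preranked procedure ----------------------------------------------------


def test_planted_top_set_is_significant():
    rng = np.random.default_rng(5)
    n = 1000
    genes = [f"g{i:04d}" for i in range(n)]
    scores = np.sort(rng.normal(size=n))[::-1] + np.linspace(1, 0, n)
    ranked = RankedList(genes, scores)
    sets = {"TOP": genes[:30],
            **gsea.make_synthetic_gene_sets(genes, n_sets=5, set_size=30, seed=1)}
    res = gsea.gsea_preranked(ranked, sets, n_perm=200, seed=2)
    row = res.table.loc["TOP"]
    assert row["nes"] > 0
    assert row["fdr_q"] < 0.25


def test_reversed_ranking_negates_every_es(rng):
    n = 200
    genes = [f"g{i}" for i in range(n)]
    scores = np.sort(rng.normal(size=n))[::-1]
    sets = gsea.make_synthetic_gene_sets(genes, n_sets=8, set_size=15, seed=3)
    fwd = gsea.gsea_preranked(RankedList(genes, scores), sets, n_perm=20, seed=0)
    rev = gsea.gsea_preranked(RankedList(genes[::-1], -scores[::-1]), sets,
                              n_perm=20, seed=0)
    assert np.allclose(np.abs(fwd.table["es"]), np.abs(rev.table.loc[fwd.table.index, "es"]),
                       atol=1e-9)


def test_fdr_q_monotone_in_abs_nes():
    rng = np.random.default_rng(11)
    n = 400
    genes = [f"g{i}" for i in range(n)]
    scores = np.sort(rng.normal(size=n))[::-1]
    sets = gsea.make_synthetic_gene_sets(genes, n_sets=15, set_size=20, seed=4)
    res = gsea.gsea_preranked(RankedList(genes, scores), sets, n_perm=100, seed=5)
    t = res.table.dropna(subset=["fdr_q"])
    for sign in (1, -1):
        side = t[np.sign(t["nes"]) == sign].sort_values("nes", key=np.abs, ascending=False)
        assert np.all(np.diff(side["fdr_q"]) >= -1e-12)


def test_too_few_permutations_raise():
    ranked = RankedList(["a", "b", "c"], np.array([3.0, 2, 1]))
    with pytest.raises(ValueError):
        gsea.gsea_preranked(ranked, {"s": ["a"]}, n_perm=5, seed=0)


def test_gmt_round_trip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("S1\tdesc\tg1\tg2\nS2\tdesc\tg3\n")
    sets = gsea.read_gmt(path)
    assert sets == {"S1": ["g1", "g2"], "S2": ["g3"]}
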