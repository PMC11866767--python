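"""Preranked gene-set enrichment with the weighted Kolmogorov-Smirnov
statistic, implemented from its definition.

Walking the ranked list, set members ("hits") increment a running sum by
|score|^weight / sum_hits |score|^weight and non-members decrement it by
1/(N − N_hits); the enrichment score (ES) is the signed maximum deviation
from zero and the leading edge contains the members encountered up to the
extremum. The null distribution is built by drawing, per set and
permutation, a random gene subset of the same size from the ranked universe
(the preranked convention — phenotype labels are unavailable). NES divides
each ES by the mean |null ES| of matching sign; nominal p comes from the
matching-sign null tail; FDR q uses the ratio-of-tails estimate over the
pooled null NES distribution followed by the usual monotonicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from stromaniche.de import RankedList


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per set: size, es, nes, p_value, fdr_q, leading_edge
    n_permutations: int
    seed: int


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def make_synthetic_gene_sets(
    universe: list[str],
    n_sets: int = 20,
    set_size: int = 30,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random stand-in gene-set collection (hallmark-style collections are
    external resources and are not redistributed)."""
    rng = np.random.default_rng(seed)
    return {
        f"SET_{i:03d}": sorted(rng.choice(universe, size=min(set_size, len(universe)),
                                          replace=False).tolist())
        for i in range(n_sets)
    }


def _es_from_positions(
    hit_pos: np.ndarray, weights: np.ndarray, n: int
) -> tuple[float, int]:
    """ES and extremum index given sorted hit positions (0-based) in a list
    of length n; weights are |score|^weight at every rank."""
    k = hit_pos.size
    if k == 0 or k == n:
        return 1.0, n - 1  # degenerate boundary convention
    w = weights[hit_pos]
    total = w.sum()
    if total == 0:
        # all hit scores zero: hits contribute nothing; maximal deficit
        w_norm = np.zeros(k)
    else:
        w_norm = w / total
    miss_step = 1.0 / (n - k)
    # The running sum changes slope only at hits, so its extrema lie right
    # before or right after a hit; evaluate those points in walk order and
    # take the earliest maximal |deviation| (the scan-statistic convention,
    # which also settles +/- ties deterministically).
    cum_hits = np.cumsum(w_norm)
    misses_before = hit_pos - np.arange(k)  # misses preceding each hit
    after = cum_hits - misses_before * miss_step
    before = after - w_norm
    candidates = np.empty(2 * k)
    candidates[0::2] = before
    candidates[1::2] = after
    mags = np.abs(candidates)
    # earliest candidate within float tolerance of the maximum wins, so
    # +/- ties resolve to the extremum reached first in the walk
    idx = int(np.argmax(mags > mags.max() - 1e-12))
    es = float(candidates[idx])
    j = idx // 2
    extremum = int(hit_pos[j]) if idx % 2 else int(hit_pos[j]) - 1
    return es, extremum


def enrichment_score(
    ranked: RankedList, gene_set: list[str], weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """(ES, full running sum, leading-edge members) for one gene set."""
    n = len(ranked.genes)
    pos_of = {g: i for i, g in enumerate(ranked.genes)}
    hit_pos = np.sort([pos_of[g] for g in gene_set if g in pos_of])
    if hit_pos.size == 0:
        raise ValueError("gene set has no overlap with the ranked universe")
    if hit_pos.size == n:
        warnings.warn("gene set covers the entire ranked universe; ES defined as 1.0")
        running = np.cumsum(np.abs(ranked.scores) ** weight)
        running = running / running[-1] if running[-1] else np.ones(n)
        return 1.0, running, list(ranked.genes)

    weights = np.abs(ranked.scores) ** weight
    es, extremum = _es_from_positions(hit_pos, weights, n)

    # dense running sum (for callers that plot it)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[hit_pos] = True
    w = weights[hit_pos]
    total = w.sum()
    steps = np.where(is_hit, 0.0, -1.0 / (n - hit_pos.size))
    if total > 0:
        steps[hit_pos] = w / total
    running = np.cumsum(steps)

    if es >= 0:
        leading = [ranked.genes[i] for i in hit_pos if i <= extremum]
    else:
        leading = [ranked.genes[i] for i in hit_pos if i > extremum]
    return es, running, leading


def _null_es(
    rng: np.random.Generator, weights: np.ndarray, size: int, n_perm: int
) -> np.ndarray:
    """ES of ``n_perm`` random same-size subsets of the universe."""
    n = weights.size
    out = np.empty(n_perm)
    for b in range(n_perm):
        pos = np.sort(rng.choice(n, size=size, replace=False))
        out[b], _ = _es_from_positions(pos, weights, n)
    return out


def gsea_preranked(
    ranked: RankedList,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Run the preranked procedure over a gene-set collection."""
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    rng = np.random.default_rng(seed)
    universe = set(ranked.genes)
    weights = np.abs(ranked.scores) ** weight

    rows = []
    null_nes_pool: list[np.ndarray] = []
    obs_nes: dict[str, float] = {}
    for name, members in sets.items():
        overlap = [g for g in members if g in universe]
        if not overlap:
            warnings.warn(f"set {name!r} has no overlap with the ranked universe; skipped")
            continue
        es, _, leading = enrichment_score(ranked, overlap, weight)
        null = _null_es(rng, weights, len(overlap), n_perm)
        pos_null, neg_null = null[null >= 0], null[null < 0]
        if es >= 0:
            denom = pos_null.mean() if pos_null.size else np.nan
            p = (np.sum(pos_null >= es) + 1) / (pos_null.size + 1) if pos_null.size else 1.0
        else:
            denom = np.abs(neg_null).mean() if neg_null.size else np.nan
            p = (np.sum(neg_null <= es) + 1) / (neg_null.size + 1) if neg_null.size else 1.0
        nes = es / denom if denom and not np.isnan(denom) else np.nan
        # normalize the whole null for this set the same way, for FDR pooling
        null_nes = np.empty_like(null)
        pmean = pos_null.mean() if pos_null.size else np.nan
        nmean = np.abs(neg_null).mean() if neg_null.size else np.nan
        null_nes[null >= 0] = null[null >= 0] / pmean if pos_null.size else np.nan
        null_nes[null < 0] = null[null < 0] / nmean if neg_null.size else np.nan
        null_nes_pool.append(null_nes[~np.isnan(null_nes)])
        obs_nes[name] = nes
        rows.append({
            "set": name,
            "size": len(overlap),
            "es": es,
            "nes": nes,
            "p_value": float(p),
            "leading_edge": ",".join(leading),
        })

    pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    nes_values = np.array([r["nes"] for r in rows])
    qs = []
    for r in rows:
        nes = r["nes"]
        if np.isnan(nes) or pooled.size == 0:
            qs.append(np.nan)
            continue
        if nes >= 0:
            null_frac = np.mean(pooled >= nes)
            obs_frac = np.mean(nes_values >= nes)
        else:
            null_frac = np.mean(pooled <= nes)
            obs_frac = np.mean(nes_values <= nes)
        qs.append(min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan)
    # monotonicity adjustment (step-up, as in BH): walking from the weakest
    # |NES| to the strongest within each sign, each set's q becomes the
    # minimum of its own raw q and all weaker sets' — so q is non-increasing
    # in |NES| without ever borrowing significance from stronger sets
    order = np.argsort(np.abs(nes_values))
    run_min = {1: np.inf, -1: np.inf}
    qs = np.asarray(qs, dtype=float)
    for i in order:
        if np.isnan(qs[i]):
            continue
        sign = 1 if nes_values[i] >= 0 else -1
        run_min[sign] = min(run_min[sign], qs[i])
        qs[i] = run_min[sign]
    for r, q in zip(rows, qs):
        r["fdr_q"] = float(q)

    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p_value", "leading_edge", "fdr_q"]
    )
    return EnrichmentResult(table=table, n_permutations=n_perm, seed=seed)
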