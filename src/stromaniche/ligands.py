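"""Sender-ligand activity inference over a pluggable prior network.

Given a ligand x target "regulatory potential" matrix (entries in [0, 1]),
the set of ligands expressed by a sender population, and a binary receiver
response over a stated gene universe (by default the condition-DE indicator
at BH q < 0.05), each expressed ligand is scored by the Pearson correlation
between its potential vector and the response indicator; ligands are ranked
by score. Receptor links are reported for ligands whose receptors the
receiver expresses.

Real ligand-target priors are external resources; the module ships a
synthetic prior generator with planted causal structure so the inference
can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class LigandPriorNetwork:
    potential: pd.DataFrame  # ligands x targets, entries in [0, 1]
    receptors: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.potential.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("potential entries must lie in [0, 1]")
        zero_rows = self.potential.index[(vals.sum(axis=1) == 0)]
        if len(zero_rows):
            raise ValueError(f"all-zero ligand rows: {zero_rows.tolist()}")

    @classmethod
    def from_tsv(cls, potential_path, receptor_path=None) -> "LigandPriorNetwork":
        long = pd.read_csv(potential_path, sep="\t")
        potential = long.pivot_table(index="ligand", columns="target",
                                     values="potential", fill_value=0.0)
        receptors: dict[str, list[str]] = {}
        if receptor_path is not None:
            rec = pd.read_csv(receptor_path, sep="\t")
            for lig, grp in rec.groupby("ligand"):
                receptors[lig] = grp["receptor"].tolist()
        return cls(potential, receptors)


def expressed_genes(
    adata: ad.AnnData, cells: np.ndarray, min_frac: float = 0.10
) -> set[str]:
    """Genes detected (count >= 1) in at least ``min_frac`` of the subset."""
    cells = np.asarray(cells)
    if cells.dtype == bool:
        cells = np.flatnonzero(cells)
    if cells.size == 0:
        raise ValueError("empty cell subset")
    X = sp.csr_matrix(adata.X)[cells]
    frac = np.asarray((X >= 1).sum(axis=0)).ravel() / cells.size
    return {g for g, f in zip(adata.var_names, frac) if f >= min_frac}


def ligand_activity(
    prior: LigandPriorNetwork,
    sender_expressed: set[str],
    response: pd.Series,
    receiver_expressed: set[str] | None = None,
    statistic: str = "pearson",
) -> pd.DataFrame:
    """Score sender-expressed ligands against the receiver response.

    ``response`` is a 0/1 indicator indexed by the gene universe; ``statistic``
    is ``pearson`` (default) or ``auroc``.
    """
    y = response.astype(float)
    universe = [g for g in y.index if g in prior.potential.columns]
    if not universe:
        raise ValueError("response universe does not overlap prior targets")
    y = y.loc[universe]
    if y.nunique() < 2:
        raise ValueError(
            "response indicator is constant over the universe; ligand activity "
            "needs a non-degenerate response (some responders and some not)"
        )
    ligs = [l for l in prior.potential.index if l in sender_expressed]
    rows = []
    yv = y.to_numpy()
    for lig in ligs:
        x = prior.potential.loc[lig, universe].to_numpy(dtype=float)
        if statistic == "pearson":
            sx = x.std()
            score = 0.0 if sx == 0 else float(np.corrcoef(x, yv)[0, 1])
            if abs(abs(score) - 1.0) < 1e-12:  # snap float rounding at the boundary
                score = float(np.sign(score))
        elif statistic == "auroc":
            from scipy.stats import rankdata

            r = rankdata(x)
            n1 = int(yv.sum())
            n0 = len(yv) - n1
            score = float((r[yv == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        receptors = prior.receptors.get(lig, [])
        matched = ([r for r in receptors if r in receiver_expressed]
                   if receiver_expressed is not None else receptors)
        rows.append({"ligand": lig, "activity": score,
                     "receptors_expressed": ",".join(matched)})
    table = pd.DataFrame(rows).set_index("ligand")
    table = table.sort_values("activity", ascending=False, kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def make_synthetic_prior(
    universe: list[str],
    n_ligands: int = 10,
    response_genes: list[str] | None = None,
    causal_ligand: str = "Tgfb1",
    targets_per_ligand: int = 50,
    seed: int = 0,
) -> LigandPriorNetwork:
    """A random prior with one planted causal ligand whose potential
    concentrates on ``response_genes``."""
    rng = np.random.default_rng(seed)
    names = [causal_ligand] + [f"Ligand{i:02d}" for i in range(1, n_ligands)]
    pot = np.zeros((n_ligands, len(universe)))
    idx = {g: j for j, g in enumerate(universe)}
    for i in range(n_ligands):
        targets = rng.choice(len(universe), size=min(targets_per_ligand, len(universe)),
                             replace=False)
        pot[i, targets] = rng.uniform(0.1, 1.0, size=targets.size)
    if response_genes:
        resp_idx = [idx[g] for g in response_genes if g in idx]
        pot[0] = rng.uniform(0.0, 0.05, size=len(universe))
        pot[0, resp_idx] = rng.uniform(0.7, 1.0, size=len(resp_idx))
    receptors = {causal_ligand: ["Tgfbr2", "Tgfbr3"]}
    return LigandPriorNetwork(pd.DataFrame(pot, index=names, columns=universe), receptors)
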