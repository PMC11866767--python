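"""Synthetic multi-library stromal count matrices with known ground truth.

The generator emulates the sorted bone-marrow stromal compartment of a
control-vs-myeloma mouse experiment: five 10x libraries (three control, two
tumor-engrafted), seven stromal populations (MSC, OLC, fibroblast,
chondrocyte, pericyte, arterial and sinusoidal endothelium) whose default
condition-specific composition follows the study's published abundance
table, per-cell mitochondrial content, rare Ighg2b+ tumor cells spiked into
tumor libraries, and a per-library log-normal size factor as the batch
effect.

Counts are negative-binomial with a single global dispersion theta
(variance = mu + mu^2/theta), sampled as a gamma-Poisson mixture. All
randomness flows from one seed; libraries consume independent child streams
in a fixed order, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

# ---------------------------------------------------------------------------
# gene universe and default population profiles

STROMAL_MARKERS: dict[str, list[str]] = {
    "MSC": ["Lepr", "Adipoq", "Cxcl12"],
    "OLC": ["Bglap", "Spp1", "Sp7"],
    "Fibroblast": ["S100a4", "Fn1", "Dcn"],
    "Chondrocyte": ["Col2a1", "Sox9", "Acan"],
    "Pericyte": ["Acta2", "Myh11", "Mcam"],
    "AEC": ["Cdh5", "Cd34", "Pecam1", "Ly6a", "Cxcl12"],
    "SEC": ["Cdh5", "Cd34", "Pecam1", "Flt4", "Il6st"],
}

# Genes used by detection (count >= 1) gates. They sit near zero outside
# the populations that express them so that presence/absence is informative.
GATE_GENES = {"Cdh5", "Pecam1", "Prrx1", "Col1a1", "Ighg2b"}
GATE_ON_MEAN = 4.0
GATE_BACKGROUND = 0.005

# Filler (housekeeping-like) genes are expressed at a steady moderate mean,
# so their log-normalized variance is detection noise only; marker genes sit
# at a moderate base and are elevated marker_fold-times in their population,
# which makes them bimodal across populations and hence the variable genes.
BASE_MARKER_MEAN = 1.0
FILLER_MEAN = 3.0

# extra named genes so lineage sub-profiles and gates have a home
_EXTRA_GENES = [
    "Prrx1", "Col1a1", "Ighg2b", "Snai2", "Twist1", "Zeb2",
    "Lpl", "Mgp", "Wif1", "Bglap2", "Car3", "Atf3", "Socs3", "Btg2",
    "Sparc", "Ppbp", "Tgfb1", "Pf4", "Calr", "Xbp1", "Sdc1",
]

_MITO_NAMES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb", "mt-Atp8",
]

# Control / tumor composition over the seven stromal populations, as
# observed-cell-count proportions in the study's abundance table
# (control total 5,848; tumor total 8,371).
TABLE_COUNTS_CONTROL: dict[str, int] = {
    "MSC": 990, "OLC": 603, "SEC": 499, "AEC": 1511,
    "Fibroblast": 1525, "Chondrocyte": 23, "Pericyte": 697,
}
TABLE_COUNTS_TUMOR: dict[str, int] = {
    "MSC": 2040, "OLC": 645, "SEC": 1382, "AEC": 1450,
    "Fibroblast": 1838, "Chondrocyte": 98, "Pericyte": 918,
}


@dataclass
class PopulationProfile:
    """A cell population: per-gene mean expression plus its marker genes.

    ``mean_expression`` is the fully resolved per-gene mean (markers already
    elevated); ``marker_genes``/``marker_fold`` record how it was built.
    """

    label: str
    mean_expression: np.ndarray
    marker_genes: list[str] = field(default_factory=list)
    marker_fold: float = 8.0

    def validate(self, genes: list[str]) -> None:
        if self.marker_fold <= 1:
            raise ValueError(f"profile {self.label}: marker_fold must be > 1")
        if np.any(self.mean_expression < 0):
            raise ValueError(f"profile {self.label}: negative mean expression")
        missing = set(self.marker_genes) - set(genes)
        if missing:
            raise ValueError(f"profile {self.label}: markers absent from universe: {missing}")


@dataclass
class SimulationConfig:
    genes: list[str]
    populations: list[PopulationProfile]
    composition: dict[str, np.ndarray]  # condition -> probabilities over populations
    libraries: list[tuple[str, str]]  # (library id, condition)
    n_cells_per_library: int = 2000
    nb_dispersion: float = 5.0
    library_effect_sd: float = 0.15
    mito_mean_fraction: float = 0.02
    tumor_spike_fraction: float = 0.0
    tumor_profile: PopulationProfile | None = None
    seed: int = 0

    def validate(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("empty gene universe")
        if len(self.populations) == 0:
            raise ValueError("no populations configured")
        if len(self.libraries) == 0:
            raise ValueError("no libraries configured")
        if self.n_cells_per_library <= 0:
            raise ValueError("n_cells_per_library must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.library_effect_sd < 0:
            raise ValueError("library_effect_sd must be non-negative")
        for prop, name in [
            (self.mito_mean_fraction, "mito_mean_fraction"),
            (self.tumor_spike_fraction, "tumor_spike_fraction"),
        ]:
            if not 0 <= prop <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for cond, probs in self.composition.items():
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (len(self.populations),):
                raise ValueError(f"composition[{cond}] length != number of populations")
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"composition[{cond}] must be a probability vector")
        for _, cond in self.libraries:
            if cond not in self.composition:
                raise ValueError(f"library condition {cond!r} has no composition vector")
        if self.tumor_spike_fraction > 0 and self.tumor_profile is None:
            raise ValueError("tumor_spike_fraction > 0 requires a tumor_profile")
        for prof in self.populations:
            prof.validate(self.genes)
        if self.tumor_profile is not None:
            self.tumor_profile.validate(self.genes)


@dataclass
class SyntheticDataset:
    """Counts plus ground truth; counts live in ``adata`` (cells x genes CSR)."""

    adata: ad.AnnData

    @property
    def true_labels(self) -> pd.Series:
        return self.adata.obs["true_label"]

    @property
    def true_pseudotime(self) -> pd.Series | None:
        if "true_pseudotime" in self.adata.obs:
            return self.adata.obs["true_pseudotime"]
        return None


# ---------------------------------------------------------------------------
# universe / profile construction


def default_gene_universe(n_genes: int = 1000, mito_gene_fraction: float = 0.01) -> list[str]:
    """Named marker genes, a block of ``mt-`` genes, then numbered filler."""
    named: list[str] = []
    for markers in STROMAL_MARKERS.values():
        for g in markers:
            if g not in named:
                named.append(g)
    for g in _EXTRA_GENES:
        if g not in named:
            named.append(g)
    n_mito = max(1, round(mito_gene_fraction * n_genes))
    mito = [_MITO_NAMES[i % len(_MITO_NAMES)] + ("" if i < len(_MITO_NAMES) else f".{i}")
            for i in range(n_mito)]
    n_filler = n_genes - len(named) - n_mito
    if n_filler < 0:
        raise ValueError(f"n_genes={n_genes} too small for {len(named)} named + {n_mito} mito genes")
    filler = [f"Gene{i:04d}" for i in range(n_filler)]
    return named + mito + filler


def _mito_mask(genes: list[str]) -> np.ndarray:
    return np.array([g.lower().startswith("mt-") for g in genes])


def _base_mean_vector(genes: list[str]) -> np.ndarray:
    all_markers = {g for ms in STROMAL_MARKERS.values() for g in ms} | set(_EXTRA_GENES)
    means = np.full(len(genes), FILLER_MEAN)
    for i, g in enumerate(genes):
        if g in GATE_GENES:
            means[i] = GATE_BACKGROUND
        elif g in all_markers:
            means[i] = BASE_MARKER_MEAN
    means[_mito_mask(genes)] = 0.0  # set by _apply_mito
    return means


def _apply_mito(means: np.ndarray, genes: list[str], mito_mean_fraction: float) -> np.ndarray:
    """Scale mt- gene means so the expected mitochondrial fraction is as asked."""
    mito = _mito_mask(genes)
    out = means.copy()
    out[mito] = 0.0
    if mito.any() and mito_mean_fraction > 0:
        total = out[~mito].sum()
        out[mito] = mito_mean_fraction / (1 - mito_mean_fraction) * total / mito.sum()
    return out


def make_profile(
    label: str,
    genes: list[str],
    marker_genes: list[str],
    marker_fold: float = 8.0,
    extra_means: dict[str, float] | None = None,
) -> PopulationProfile:
    """Build a profile: base means, markers elevated by ``marker_fold``.

    Detection-gate genes among the markers jump to a fixed high mean instead
    of a fold over their near-zero background; ``extra_means`` pins
    individual genes explicitly (used for gates and sub-lineage profiles).
    """
    idx = {g: i for i, g in enumerate(genes)}
    means = _base_mean_vector(genes)
    for g in marker_genes:
        if g not in idx:
            raise ValueError(f"marker {g} not in gene universe")
        means[idx[g]] = GATE_ON_MEAN if g in GATE_GENES else means[idx[g]] * marker_fold
    for g, m in (extra_means or {}).items():
        means[idx[g]] = m
    return PopulationProfile(label, means, list(marker_genes), marker_fold)


PROGRAM_FOLD = 3.0
PROGRAM_FRACTION = 0.06


def _assign_program(profile: PopulationProfile, genes: list[str], block: int) -> PopulationProfile:
    """Give a profile a broader expression program: a deterministic block of
    filler genes elevated a modest fold. Real populations differ across
    dozens of genes, not only their handful of canonical markers; without
    this the NB noise at the log scale swamps a 3-gene signature."""
    filler_idx = [i for i, g in enumerate(genes) if g.startswith("Gene")]
    size = max(5, int(PROGRAM_FRACTION * len(filler_idx)))
    chosen = [filler_idx[(block * size + j) % len(filler_idx)] for j in range(size)]
    means = profile.mean_expression.copy()
    means[chosen] *= PROGRAM_FOLD
    return replace(profile, mean_expression=means)


def default_stromal_profiles(genes: list[str], marker_fold: float = 8.0) -> list[PopulationProfile]:
    """The seven stromal populations with their published marker structure,
    each riding on its own broader expression program."""
    profs = [make_profile(lab, genes, mk, marker_fold) for lab, mk in STROMAL_MARKERS.items()]
    return [_assign_program(p, genes, i) for i, p in enumerate(profs)]


def tumor_profile(genes: list[str], marker_fold: float = 8.0) -> PopulationProfile:
    """Myeloma (5TGM1-like) plasma cells: Ighg2b+ with a plasma-cell flavor."""
    prof = make_profile("tumor", genes, ["Ighg2b", "Xbp1", "Sdc1"], marker_fold,
                        extra_means={"Ighg2b": 6.0})
    return _assign_program(prof, genes, 7)


def endomt_profile(genes: list[str], marker_fold: float = 8.0) -> PopulationProfile:
    """Endothelial-to-mesenchymal transition cells: EC and stromal co-expression."""
    prof = make_profile(
        "EndoMT", genes,
        ["Cdh5", "Pecam1", "Cd34", "Prrx1", "Col1a1", "Snai2", "Twist1", "Zeb2", "Cxcl12"],
        marker_fold,
    )
    return _assign_program(prof, genes, 8)


def msc_lineage_profiles(genes: list[str], marker_fold: float = 8.0) -> list[PopulationProfile]:
    """Six MSC-lineage sub-populations spanning the adipo/osteo axis."""
    spec = {
        "Adipo-MSC1": ["Lepr", "Lpl", "Mgp"],
        "MSC-0": ["Lepr", "Lpl", "Mgp", "Wif1"],
        "OLC-1": ["Wif1", "Spp1", "Sparc", "Col1a1"],
        "OLC-2": ["Bglap", "Bglap2", "Car3"],
        "Adipo-MSC2": ["Lepr", "Mgp", "Adipoq", "Atf3", "Socs3", "Btg2"],
        "MM-OLC3": ["Bglap", "Col1a1", "Lepr", "Mgp", "Adipoq", "Ppbp", "Cxcl12", "Tgfb1"],
    }
    profs = [make_profile(lab, genes, mk, marker_fold) for lab, mk in spec.items()]
    return [_assign_program(p, genes, i) for i, p in enumerate(profs)]


def table_composition(condition: str) -> np.ndarray:
    """Published per-condition cell-count proportions over the seven populations."""
    counts = TABLE_COUNTS_CONTROL if condition == "control" else TABLE_COUNTS_TUMOR
    order = list(STROMAL_MARKERS)
    v = np.array([counts[p] for p in order], dtype=float)
    return v / v.sum()


def default_config(
    n_genes: int = 1000,
    n_cells_per_library: int = 2000,
    marker_fold: float = 8.0,
    tumor_spike_fraction: float = 0.02,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Study-condition defaults: 5 libraries (3 control, 2 tumor), published
    per-condition composition, Ighg2b+ tumor cells spiked into tumor libraries."""
    genes = default_gene_universe(n_genes)
    cfg = SimulationConfig(
        genes=genes,
        populations=default_stromal_profiles(genes, marker_fold),
        composition={
            "control": table_composition("control"),
            "tumor": table_composition("tumor"),
        },
        libraries=[
            ("PBS-1", "control"), ("PBS-2", "control"), ("PBS-3", "control"),
            ("5TGM1-1", "tumor"), ("5TGM1-2", "tumor"),
        ],
        n_cells_per_library=n_cells_per_library,
        tumor_spike_fraction=tumor_spike_fraction,
        tumor_profile=tumor_profile(genes, marker_fold) if tumor_spike_fraction > 0 else None,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# sampling


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + mu^2/theta; Poisson at theta=inf."""
    if np.isinf(theta):
        return rng.poisson(mu)
    lam = rng.gamma(shape=theta, scale=np.asarray(mu) / theta)
    return rng.poisson(lam)


def _resolve_means(profile: PopulationProfile, genes: list[str], mito_mean_fraction: float) -> np.ndarray:
    return _apply_mito(profile.mean_expression, genes, mito_mean_fraction)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a multi-library dataset: per-library multinomial composition,
    NB counts, log-normal library size factors, deterministic given the seed."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.libraries))
    genes = config.genes
    profiles = list(config.populations)
    means = np.stack([_resolve_means(p, genes, config.mito_mean_fraction) for p in profiles])
    labels = [p.label for p in profiles]
    if config.tumor_profile is not None:
        means = np.vstack([means, _resolve_means(config.tumor_profile, genes, config.mito_mean_fraction)])
        labels = labels + [config.tumor_profile.label]

    blocks, obs_rows = [], []
    for (lib, cond), ss in zip(config.libraries, seeds):
        rng = np.random.default_rng(ss)
        size_factor = rng.lognormal(0.0, config.library_effect_sd) if config.library_effect_sd > 0 else 1.0
        probs = np.asarray(config.composition[cond], dtype=float)
        if cond == "tumor" and config.tumor_spike_fraction > 0:
            probs = np.concatenate([(1 - config.tumor_spike_fraction) * probs,
                                    [config.tumor_spike_fraction]])
        else:
            probs = np.concatenate([probs, [0.0]]) if config.tumor_profile is not None else probs
        n = config.n_cells_per_library
        assignment = rng.choice(len(probs), size=n, p=probs / probs.sum())
        counts = np.zeros((n, len(genes)), dtype=np.int32)
        for k in range(len(probs)):
            cells_k = np.flatnonzero(assignment == k)
            if cells_k.size == 0:
                continue
            mu = means[k] * size_factor
            counts[cells_k] = _nb_sample(rng, np.broadcast_to(mu, (cells_k.size, len(genes))),
                                         config.nb_dispersion)
        blocks.append(sp.csr_matrix(counts))
        for i in range(n):
            obs_rows.append((f"{lib}-{i:05d}", lib, cond, labels[assignment[i]]))

    X = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows, columns=["barcode", "library", "condition", "true_label"])
    obs = obs.set_index("barcode")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.var["mito"] = _mito_mask(genes)
    return SyntheticDataset(adata)


def gradient_means(
    config: SimulationConfig, path: list[str], latent: np.ndarray
) -> np.ndarray:
    """Expected expression at latent positions in [0,1] along a profile path.

    Piecewise-linear interpolation between successive profiles; latent 0 is
    the first profile exactly, latent 1 the last.
    """
    by_label = {p.label: p for p in config.populations}
    prof_means = np.stack([
        _resolve_means(by_label[lab], config.genes, config.mito_mean_fraction) for lab in path
    ])
    n_seg = len(path) - 1
    pos = np.clip(np.asarray(latent, dtype=float), 0.0, 1.0) * n_seg
    seg = np.minimum(pos.astype(int), n_seg - 1)
    t = (pos - seg)[:, None]
    return (1 - t) * prof_means[seg] + t * prof_means[seg + 1]


def simulate_gradient(config: SimulationConfig, path: list[str]) -> SyntheticDataset:
    """A continuous differentiation axis: cells at uniform latent positions
    with expression interpolating linearly along ``path``."""
    config.validate()
    if len(path) < 2:
        raise ValueError("gradient path must name at least 2 populations")
    known = {p.label for p in config.populations}
    missing = set(path) - known
    if missing:
        raise ValueError(f"gradient path labels not in config: {missing}")

    seeds = np.random.SeedSequence(config.seed).spawn(len(config.libraries))
    blocks, obs_rows = [], []
    for (lib, cond), ss in zip(config.libraries, seeds):
        rng = np.random.default_rng(ss)
        size_factor = rng.lognormal(0.0, config.library_effect_sd) if config.library_effect_sd > 0 else 1.0
        n = config.n_cells_per_library
        u = rng.uniform(size=n)
        mu = gradient_means(config, path, u) * size_factor
        counts = _nb_sample(rng, mu, config.nb_dispersion).astype(np.int32)
        blocks.append(sp.csr_matrix(counts))
        nearest = np.rint(u * (len(path) - 1)).astype(int)
        for i in range(n):
            obs_rows.append((f"{lib}-{i:05d}", lib, cond, path[nearest[i]], u[i]))

    X = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(
        obs_rows, columns=["barcode", "library", "condition", "true_label", "true_pseudotime"]
    ).set_index("barcode")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(config.genes, name="gene")))
    adata.var["mito"] = _mito_mask(config.genes)
    return SyntheticDataset(adata)
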