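"""Synthetic single-cell count data with known ground truth.

Emulates the statistical structure of a dissociated early-postnatal brainstem
sample: a few hundred cells of five types (two neuronal groups, astrocytes,
oligodendrocytes, vascular-associated cells), strongly type-specific marker
genes, a highly expressed reporter transcript restricted to neurons,
mitochondrial genes, log-normal per-cell depth variation, and optionally a
minority of low-quality libraries and doublet captures.

Counts are negative binomial with mean ``libsize_c * rate[g]`` (marker genes
multiplied by the profile's enrichment) and variance ``mu + alpha * mu**2``.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import CountMatrix

__all__ = [
    "CellTypeProfile",
    "SimulationConfig",
    "SyntheticDataset",
    "ConfigurationError",
    "generate_dataset",
    "inject_artifacts",
    "write_dataset",
    "default_config",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class CellTypeProfile:
    """One cell type: a per-gene rate vector plus marker enrichment.

    ``mean_expression`` is a nonnegative relative rate vector over the gene
    universe (internally normalized to sum 1, so the expected library size of a
    cell equals its drawn depth). ``marker_genes`` are multiplied by
    ``marker_fold`` (>= 1) before normalization. ``neuron`` marks profiles that
    express the reporter transcript.
    """

    name: str
    n_cells: int
    mean_expression: np.ndarray
    marker_genes: frozenset = frozenset()
    marker_fold: float = 1.0
    neuron: bool = False

    def __post_init__(self):
        self.mean_expression = np.asarray(self.mean_expression, dtype=float)
        self.marker_genes = frozenset(self.marker_genes)
        if self.n_cells < 0:
            raise ConfigurationError(f"profile {self.name!r}: n_cells < 0")
        if self.marker_fold < 1:
            raise ConfigurationError(f"profile {self.name!r}: marker_fold < 1")
        if (self.mean_expression < 0).any():
            raise ConfigurationError(f"profile {self.name!r}: negative rates")


@dataclass
class SimulationConfig:
    profiles: list
    gene_ids: list
    mito_genes: frozenset = frozenset()
    reporter_gene: str | None = None
    reporter_rate: float = 0.02          # fraction of a neuron's rate mass
    reporter_leakage: float = 0.0        # fraction of reporter_rate in non-neurons
    library_size_lognormal: tuple = (np.log(50_000.0), 0.3)
    nb_dispersion: float = 0.1
    frac_low_quality: float = 0.0
    frac_doublets: float = 0.0
    low_quality_keep_frac: float = 0.2   # thinning target for low-quality cells
    low_quality_mito_frac: float = 0.5   # mito fraction forced into low-quality cells
    seed: int = 0

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.mito_genes = frozenset(self.mito_genes)
        if not self.profiles:
            raise ConfigurationError("at least one profile required")
        universe = set(self.gene_ids)
        if len(universe) != len(self.gene_ids):
            raise ConfigurationError("duplicate gene ids")
        if not self.mito_genes <= universe:
            raise ConfigurationError("mito_genes outside gene universe")
        if len(self.mito_genes) >= len(self.gene_ids):
            raise ConfigurationError("n_mito_genes must be < n_genes")
        if self.reporter_gene is not None and self.reporter_gene not in universe:
            raise ConfigurationError("reporter_gene outside gene universe")
        for frac in (self.frac_low_quality, self.frac_doublets,
                     self.reporter_leakage, self.low_quality_keep_frac,
                     self.low_quality_mito_frac):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("proportions must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        for p in self.profiles:
            if p.mean_expression.shape != (len(self.gene_ids),):
                raise ConfigurationError(
                    f"profile {p.name!r}: rate vector length mismatch"
                )
            if not p.marker_genes <= universe:
                raise ConfigurationError(
                    f"profile {p.name!r}: marker genes outside gene universe"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class SyntheticDataset:
    """A CountMatrix plus ground truth for recovery tests."""

    counts: CountMatrix
    true_type: pd.Series
    is_doublet: pd.Series
    is_low_quality: pd.Series
    marker_map: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


def _profile_rates(config: SimulationConfig, profile: CellTypeProfile) -> np.ndarray:
    """Absolute rate vector normalized to sum 1, markers and reporter applied."""
    gene_pos = {g: i for i, g in enumerate(config.gene_ids)}
    rates = profile.mean_expression.astype(float).copy()
    for g in profile.marker_genes:
        rates[gene_pos[g]] *= profile.marker_fold
    if config.reporter_gene is not None:
        i = gene_pos[config.reporter_gene]
        base = rates.sum() - rates[i]
        level = config.reporter_rate if profile.neuron else (
            config.reporter_rate * config.reporter_leakage
        )
        # reporter_rate is the reporter's share of the cell's total rate mass
        rates[i] = base * level / (1.0 - level) if level < 1 else base
    total = rates.sum()
    if total <= 0:
        raise ConfigurationError(f"profile {profile.name!r}: all-zero rates")
    return rates / total


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Sample a count matrix from the configured cell-type profiles.

    Deterministic under a fixed ``config.seed``; artifact fractions from the
    config are applied through :func:`inject_artifacts`.
    """
    if len(config.profiles) < 1:
        raise ConfigurationError("at least one profile required")
    rng = np.random.default_rng(config.seed)
    logmean, logsd = config.library_size_lognormal

    blocks, types = [], []
    for profile in config.profiles:
        rates = _profile_rates(config, profile)
        lib = rng.lognormal(mean=logmean, sigma=logsd, size=profile.n_cells)
        mu = np.outer(rates, lib)  # genes x cells
        blocks.append(_nb_sample(rng, mu, config.nb_dispersion))
        types.extend([profile.name] * profile.n_cells)

    counts = np.concatenate(blocks, axis=1) if blocks else np.zeros((config.n_genes, 0))
    n_cells = counts.shape[1]
    cell_ids = pd.Index([f"cell{i:04d}" for i in range(n_cells)])
    gene_flags = pd.DataFrame(
        {
            "mito": [g in config.mito_genes for g in config.gene_ids],
            "reporter": [g == config.reporter_gene for g in config.gene_ids],
        },
        index=pd.Index(config.gene_ids, name="gene"),
    )
    cm = CountMatrix(
        sp.csr_matrix(counts),
        gene_ids=config.gene_ids,
        cell_ids=cell_ids,
        gene_flags=gene_flags,
        cell_meta=pd.DataFrame({"excluded_manually": False}, index=cell_ids),
    )
    ds = SyntheticDataset(
        counts=cm,
        true_type=pd.Series(types, index=cell_ids, name="true_type"),
        is_doublet=pd.Series(False, index=cell_ids, name="is_doublet"),
        is_low_quality=pd.Series(False, index=cell_ids, name="is_low_quality"),
        marker_map={p.name: set(p.marker_genes) for p in config.profiles},
        config=config,
    )
    if config.frac_low_quality > 0 or config.frac_doublets > 0:
        # child seed keeps artifact injection reproducible but independent
        ds = inject_artifacts(
            ds,
            config.frac_low_quality,
            config.frac_doublets,
            seed=np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0]
            % (2**31),
        )
    return ds


def inject_artifacts(
    ds: SyntheticDataset,
    frac_low_quality: float,
    frac_doublets: float,
    seed: int,
    keep_frac: float | None = None,
    mito_frac: float | None = None,
) -> SyntheticDataset:
    """Degrade a clean dataset with low-quality libraries and doublets.

    Low-quality cells are existing cells binomially thinned to ``keep_frac`` of
    their original total with counts re-allocated so the mitochondrial fraction
    reaches at least ``mito_frac``. Doublets are appended cells equal to the
    element-wise sum of two distinct randomly paired parents.
    """
    if not (0.0 <= frac_low_quality <= 1.0 and 0.0 <= frac_doublets <= 1.0):
        raise ConfigurationError("fractions must lie in [0, 1]")
    cfg = ds.config
    keep_frac = (cfg.low_quality_keep_frac if cfg else 0.2) if keep_frac is None else keep_frac
    mito_frac = (cfg.low_quality_mito_frac if cfg else 0.5) if mito_frac is None else mito_frac
    if frac_low_quality == 0 and frac_doublets == 0:
        return ds

    rng = np.random.default_rng(seed)
    counts = ds.counts.dense().astype(np.int64)
    n_genes, n_cells = counts.shape
    mito_mask = ds.counts.gene_flags["mito"].to_numpy()

    is_lq = ds.is_low_quality.to_numpy().copy()
    n_lq = int(round(frac_low_quality * n_cells))
    lq_idx = rng.choice(n_cells, size=n_lq, replace=False) if n_lq else np.array([], int)
    for c in lq_idx:
        x = counts[:, c]
        total = x.sum()
        if total == 0:
            is_lq[c] = True
            continue
        thinned = rng.binomial(x, keep_frac)
        t = int(thinned.sum())
        if t == 0:
            thinned = x.copy()
            t = int(total)
        # multinomial redraw: force ceil(mito_frac * t) counts onto mito genes
        n_mito = int(np.ceil(mito_frac * t))
        mito_w = np.where(mito_mask, thinned + 1.0, 0.0)
        rest_w = np.where(~mito_mask, thinned.astype(float), 0.0)
        new = np.zeros(n_genes, dtype=np.int64)
        if mito_w.sum() > 0:
            new += rng.multinomial(n_mito, mito_w / mito_w.sum())
        if rest_w.sum() > 0:
            new += rng.multinomial(t - n_mito, rest_w / rest_w.sum())
        counts[:, c] = new
        is_lq[c] = True

    true_type = ds.true_type.copy()
    is_doublet = ds.is_doublet.copy()
    cell_ids = list(ds.counts.cell_ids)
    n_db = int(round(frac_doublets * n_cells))
    doublet_cols, doublet_ids, doublet_types = [], [], []
    clean = np.setdiff1d(np.arange(n_cells), lq_idx)
    pool = clean if clean.size >= 2 else np.arange(n_cells)
    for k in range(n_db):
        a, b = rng.choice(pool, size=2, replace=False)
        doublet_cols.append(counts[:, a] + counts[:, b])
        doublet_ids.append(f"doublet{k:03d}")
        doublet_types.append(f"{true_type.iloc[a]}+{true_type.iloc[b]}")

    if doublet_cols:
        counts = np.concatenate([counts, np.stack(doublet_cols, axis=1)], axis=1)
        cell_ids = cell_ids + doublet_ids
        true_type = pd.concat(
            [true_type, pd.Series(doublet_types, index=doublet_ids)]
        )
        is_doublet = pd.concat(
            [is_doublet, pd.Series(True, index=doublet_ids)]
        )
        is_lq = np.concatenate([is_lq, np.zeros(n_db, dtype=bool)])

    cell_index = pd.Index(cell_ids)
    true_type.index = cell_index
    is_doublet.index = cell_index
    cm = CountMatrix(
        sp.csr_matrix(counts),
        gene_ids=ds.counts.gene_ids,
        cell_ids=cell_index,
        gene_flags=ds.counts.gene_flags,
        cell_meta=pd.DataFrame({"excluded_manually": False}, index=cell_index),
    )
    return SyntheticDataset(
        counts=cm,
        true_type=true_type.rename("true_type"),
        is_doublet=is_doublet.rename("is_doublet"),
        is_low_quality=pd.Series(is_lq, index=cell_index, name="is_low_quality"),
        marker_map=ds.marker_map,
        config=ds.config,
    )


def write_dataset(ds: SyntheticDataset, directory) -> dict:
    """Write MTX counts + TSV sidecars; round-trips through ``scmntb.io``."""
    from . import io as _io

    return _io.write_dataset(ds, directory)


# ---------------------------------------------------------------------------
# Default study conditions: five brainstem cell types, ~240 cells.
# ---------------------------------------------------------------------------

# Marker panels use the field's standard symbols so annotation and the
# ligand/receptor fixtures read naturally. Both neuronal profiles share the
# pan-neuronal panel and additionally carry a small private panel, mirroring
# the near-homogeneous principal-neuron population that still splits in two.
PAN_NEURON_MARKERS = ("Calb1", "Gabra5", "Grin2a", "Snap25", "Syt1", "Stmn2",
                      "Rbfox3", "Fgf9", "Hapln1", "Acan")
N1_MARKERS = ("Ass1", "Akap5", "Vsnl1", "Rab3b", "Nrxn1", "Cask")
N2_MARKERS = ("Tbrg1", "Tln2", "Atp1a2", "Gstm1", "Dbi", "Ednrb")
ASTRO_MARKERS = ("Aldh1l1", "Slc1a2", "Slc1a3", "Fgfr3", "Aqp4", "Tnc",
                 "Slc6a11", "Agt", "Hepacam", "Ncan", "Vcan", "Bcan")
OLIGO_MARKERS = ("Cnp", "Mbp", "Sox10", "Plp1", "Bcas1", "Ugt8a", "Tnr",
                 "Olig2", "Sox6", "Scrg1")
VAC_MARKERS = ("Cldn5", "Flt1", "Pdgfrb", "Acvrl1", "Tgfbr2", "Eng", "Kdr",
               "Icam2", "Robo4", "Tek")
REPORTER_GENE = "tdTomato"
N_MITO_DEFAULT = 13  # the mouse mitochondrial protein-coding genes


def default_config(
    seed: int = 0,
    n_genes: int = 2000,
    cells_per_type: dict | None = None,
    marker_fold: float = 8.0,
    nb_dispersion: float = 0.1,
    frac_low_quality: float = 0.0,
    frac_doublets: float = 0.0,
) -> SimulationConfig:
    """Five-type configuration emulating the P3 brainstem sample.

    Defaults: 240 cells (60/45/50/45/40 across N1/N2/astro/oligo/VAC), 2000
    genes with a shared log-normal baseline, 8-fold marker enrichment,
    scalar NB dispersion 0.1, log-normal depths (log-sd 0.3), reporter
    restricted to the neuronal profiles with zero leakage.
    """
    if cells_per_type is None:
        cells_per_type = {"N1": 60, "N2": 45, "astrocyte": 50,
                         "oligodendrocyte": 45, "VAC": 40}
    named = sorted(
        set(PAN_NEURON_MARKERS) | set(N1_MARKERS) | set(N2_MARKERS)
        | set(ASTRO_MARKERS) | set(OLIGO_MARKERS) | set(VAC_MARKERS)
    )
    mito = [f"mt-Gene{i}" for i in range(N_MITO_DEFAULT)]
    n_filler = n_genes - len(named) - len(mito) - 1
    if n_filler < 0:
        raise ConfigurationError("n_genes too small for the default marker panels")
    filler = [f"g{i:04d}" for i in range(n_filler)]
    gene_ids = named + mito + filler + [REPORTER_GENE]

    # shared baseline so types differ only through their marker panels
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA5E]))
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(gene_ids))
    base[gene_ids.index(REPORTER_GENE)] = 0.0
    mito_pos = [gene_ids.index(g) for g in mito]
    # mitochondrial reads ~4% of a healthy library
    base[mito_pos] = 0.04 * (base.sum() - base[mito_pos].sum()) / (0.96 * len(mito))

    def prof(name, markers, neuron=False):
        return CellTypeProfile(
            name=name,
            n_cells=cells_per_type[name],
            mean_expression=base,
            marker_genes=frozenset(markers),
            marker_fold=marker_fold,
            neuron=neuron,
        )

    profiles = [
        prof("N1", set(PAN_NEURON_MARKERS) | set(N1_MARKERS), neuron=True),
        prof("N2", set(PAN_NEURON_MARKERS) | set(N2_MARKERS), neuron=True),
        prof("astrocyte", ASTRO_MARKERS),
        prof("oligodendrocyte", OLIGO_MARKERS),
        prof("VAC", VAC_MARKERS),
    ]
    return SimulationConfig(
        profiles=profiles,
        gene_ids=gene_ids,
        mito_genes=frozenset(mito),
        reporter_gene=REPORTER_GENE,
        nb_dispersion=nb_dispersion,
        frac_low_quality=frac_low_quality,
        frac_doublets=frac_doublets,
        seed=seed,
    )
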