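"""Synthetic layered skin-tissue data generator with recorded ground truth.

Emulates the statistical structure of a psoriasis-style single-cell /
spatial transcriptomics study: negative-binomial counts per cell, a small
panel of cell types with marker programs, three disease conditions
(NS = healthy, PN = perilesional, PP = lesional) with condition-skewed
sub-clusters, a layered tissue (basal / spinous / supraspinous epidermal
bands above a mixed dermis), graded cytokine-response programs peaking in
the supraspinous band, and planted condition-specific ligand-receptor
interactions.

Every generator is a pure function of ``(config, seed)``: the master seed
splits into independent per-stage streams, so adding a stage never
perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

CONDITIONS = ("NS", "PN", "PP")
EPIDERMAL_LAYERS = ("basal", "spinous", "supraspinous")

# fixed stream order; append-only so earlier draws never shift
_STREAMS = ("base", "assign", "mito", "cells", "spots", "pixels")


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class CellTypeSpec:
    """One simulated cell type.

    ``layer`` names the epidermal differentiation layer for keratinocyte
    types (one of basal/spinous/supraspinous) and is None for dermal and
    immune types.
    """

    name: str
    n_markers: int = 25
    marker_fold: float = 5.0
    layer: str | None = None


@dataclass
class ProgramSpec:
    """A cytokine-response gene program with per-layer effect sizes.

    ``layer_effects`` are multiplicative expression effects at the centers
    of the basal, spinous and supraspinous layers; effects at intermediate
    pseudotime are linearly interpolated, so a monotone triple yields a
    program that rises continuously along differentiation.
    """

    name: str
    n_genes: int = 30
    layer_effects: tuple[float, float, float] = (1.0, 2.0, 4.0)


@dataclass
class PlantedLR:
    """A planted ligand-receptor interaction.

    The ligand gene is upregulated ``fold``-fold in cells of ``source``
    type, the receptor gene in cells of ``target`` type, restricted to
    ``condition`` (None = all conditions).  The default fold emulates the
    strong induction of inflammatory mediators in lesional skin, where
    cytokine transcripts undetectable at baseline become abundant.
    """

    ligand: str
    receptor: str
    source: str
    target: str
    condition: str | None = "PP"
    fold: float = 50.0


def _default_cell_types() -> list[CellTypeSpec]:
    return [
        CellTypeSpec("KC_basal", layer="basal"),
        CellTypeSpec("KC_spinous", layer="spinous"),
        CellTypeSpec("KC_supraspinous", layer="supraspinous"),
        CellTypeSpec("Fibroblast"),
        CellTypeSpec("T_cell"),
        CellTypeSpec("Myeloid"),
        CellTypeSpec("Endothelial"),
        CellTypeSpec("Melanocyte"),
    ]


def _default_programs() -> list[ProgramSpec]:
    return [
        ProgramSpec("IL17_response", layer_effects=(1.0, 2.0, 4.0)),
        ProgramSpec("IL36_response", layer_effects=(1.0, 1.5, 3.0)),
        ProgramSpec("IFN_response", layer_effects=(2.0, 1.5, 1.0)),
    ]


def _default_strata_mixtures() -> dict[str, dict[str, float]]:
    return {
        "supraspinous": {"KC_supraspinous": 0.8, "KC_spinous": 0.2},
        "spinous": {"KC_spinous": 0.7, "KC_supraspinous": 0.15, "KC_basal": 0.15},
        "basal": {"KC_basal": 0.7, "KC_spinous": 0.15, "Melanocyte": 0.15},
        "dermis": {
            "Fibroblast": 0.45,
            "T_cell": 0.2,
            "Myeloid": 0.15,
            "Endothelial": 0.2,
        },
    }


def _default_strata_rows() -> dict[str, tuple[int, int]]:
    # half-open row ranges on a 16-row lattice, outermost band first
    return {
        "supraspinous": (0, 3),
        "spinous": (3, 6),
        "basal": (6, 9),
        "dermis": (9, 16),
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic tissue.

    Defaults describe a small desk-scale skin biopsy: 8 cell types at
    ~5,000 expected transcripts per cell with NB dispersion theta = 10
    (variance mu + mu^2/theta), three conditions, three sub-clusters per
    type (one NS-skewed, one mixed, one PP-skewed), three graded cytokine
    programs, and a 16 x 30 hexagonal spot lattice split into the three
    epidermal bands plus dermis.
    """

    n_genes: int = 2000
    n_cells: int = 3000
    cell_types: list[CellTypeSpec] = field(default_factory=_default_cell_types)
    type_weights: dict[str, float] | None = None
    condition_weights: dict[str, float] = field(
        default_factory=lambda: {"NS": 1 / 3, "PN": 1 / 3, "PP": 1 / 3}
    )
    # P(sub-cluster | condition): rows NS/PN/PP, columns sub-cluster 0..2
    n_subclusters: int = 3
    subcluster_mix: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "NS": (0.8, 0.2, 0.0),
            "PN": (0.1, 0.8, 0.1),
            "PP": (0.0, 0.2, 0.8),
        }
    )
    samples_per_condition: int = 3
    nb_dispersion: float = 10.0
    depth_per_cell: float = 5000.0
    base_lognorm_sigma: float = 1.0
    # mitochondrial content: Beta-distributed share with an outlier component
    n_mito: int = 13
    mito_beta: tuple[float, float] = (3.0, 57.0)
    mito_outlier_frac: float = 0.05
    mito_outlier_beta: tuple[float, float] = (10.0, 30.0)
    # planted QC violations: cells with crippled library depth
    low_depth_frac: float = 0.0
    low_depth_scale: float = 0.05
    # signaling block: lowly expressed ligand/receptor-like genes
    n_signaling: int = 450
    signaling_scale: float = 0.012
    program_specs: list[ProgramSpec] = field(default_factory=_default_programs)
    planted_lr: list[PlantedLR] = field(default_factory=list)
    # spatial lattice
    lattice: str = "hex6"
    lattice_rows: int = 16
    lattice_cols: int = 30
    strata_rows: dict[str, tuple[int, int]] = field(default_factory=_default_strata_rows)
    strata_mixtures: dict[str, dict[str, float]] = field(
        default_factory=_default_strata_mixtures
    )
    spot_depth: float = 10000.0
    spot_dirichlet_conc: float = 60.0
    spot_condition: str = "PP"
    # sub-cellular pixel field (micrometres)
    pixel_field_um: tuple[float, float] = (120.0, 120.0)
    pixel_density_per_um2: float = 1.5
    seed: int = 0

    # ------------------------------------------------------------------
    def type_names(self) -> list[str]:
        return [t.name for t in self.cell_types]

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ConfigError("n_genes and n_cells must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.depth_per_cell < 0:
            raise ConfigError("depth_per_cell must be non-negative")
        names = self.type_names()
        if len(set(names)) != len(names):
            raise ConfigError("cell type names must be unique")
        w = np.array(list(self.condition_weights.values()), dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ConfigError("condition weights must be a simplex")
        for cond, mix in self.subcluster_mix.items():
            m = np.asarray(mix, dtype=float)
            if len(m) != self.n_subclusters or (m < 0).any() or not np.isclose(m.sum(), 1.0):
                raise ConfigError(f"subcluster mix for {cond} must be a simplex "
                                  f"of length {self.n_subclusters}")
        if self.type_weights is not None:
            tw = np.array([self.type_weights[n] for n in names], dtype=float)
            if (tw < 0).any() or not np.isclose(tw.sum(), 1.0):
                raise ConfigError("type weights must be a simplex")
        n_reserved = (
            self.n_mito
            + sum(t.n_markers for t in self.cell_types)
            + sum(p.n_genes for p in self.program_specs)
            + self.n_signaling
        )
        if n_reserved >= self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {n_reserved} reserved genes"
            )
        if self.lattice not in ("square4", "square8", "hex6"):
            raise ConfigError(f"unknown lattice {self.lattice!r}")
        if self.lattice_rows <= 0 or self.lattice_cols <= 0:
            raise ConfigError("lattice dimensions must be positive")
        covered: list[int] = []
        for lo, hi in self.strata_rows.values():
            covered.extend(range(lo, hi))
        if sorted(covered) != list(range(self.lattice_rows)):
            raise ConfigError("strata_rows must cover every lattice row exactly once")
        for stratum, mix in self.strata_mixtures.items():
            vals = np.array(list(mix.values()), dtype=float)
            if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
                raise ConfigError(f"stratum mixture {stratum!r} must be a simplex")
            unknown = set(mix) - set(names)
            if unknown:
                raise ConfigError(f"stratum {stratum!r} names unknown types {unknown}")
        if min(self.pixel_field_um) < 0:
            raise ConfigError("pixel field dimensions must be non-negative")


@dataclass
class SyntheticTruth:
    """Generator-side record of everything that was planted."""

    cell_type_of_cell: pd.Series | None = None
    subcluster_of_cell: pd.Series | None = None
    condition_of_cell: pd.Series | None = None
    pseudotime_true: pd.Series | None = None
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    program_gene_sets: dict[str, list[str]] = field(default_factory=dict)
    signaling_genes: list[str] = field(default_factory=list)
    planted_lr: list[PlantedLR] = field(default_factory=list)
    true_spot_fractions: pd.DataFrame | None = None
    stratum_of_spot: pd.Series | None = None
    stratum_of_pixel: pd.Series | None = None

    def to_json_dict(self) -> dict:
        def ser(x):
            if isinstance(x, pd.Series):
                return {str(k): (None if pd.isna(v) else v) for k, v in x.items()}
            return x

        return {
            "cell_type_of_cell": ser(self.cell_type_of_cell),
            "subcluster_of_cell": ser(self.subcluster_of_cell),
            "condition_of_cell": ser(self.condition_of_cell),
            "pseudotime_true": ser(self.pseudotime_true),
            "marker_genes": self.marker_genes,
            "program_gene_sets": self.program_gene_sets,
            "signaling_genes": self.signaling_genes,
            "planted_lr": [dataclasses.asdict(p) for p in self.planted_lr],
            "true_spot_fractions": None
            if self.true_spot_fractions is None
            else self.true_spot_fractions.to_dict(orient="index"),
            "stratum_of_spot": ser(self.stratum_of_spot),
        }


# ----------------------------------------------------------------------
# internal machinery
# ----------------------------------------------------------------------


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


class _GeneLayout:
    """Deterministic partition of gene indices into functional blocks."""

    def __init__(self, config: SimConfig):
        i = 0
        self.mito = np.arange(i, i + config.n_mito)
        i += config.n_mito
        self.markers: dict[str, np.ndarray] = {}
        for t in config.cell_types:
            self.markers[t.name] = np.arange(i, i + t.n_markers)
            i += t.n_markers
        self.programs: dict[str, np.ndarray] = {}
        for p in config.program_specs:
            self.programs[p.name] = np.arange(i, i + p.n_genes)
            i += p.n_genes
        self.signaling = np.arange(i, i + config.n_signaling)
        i += config.n_signaling
        self.background = np.arange(i, config.n_genes)

        names = np.array([f"gene_{j:05d}" for j in range(config.n_genes)], dtype=object)
        for k, j in enumerate(self.mito):
            names[j] = f"MT-{k:02d}"
        self.gene_names = names


def _base_profile(config: SimConfig, layout: _GeneLayout, rng: np.random.Generator) -> np.ndarray:
    """Relative expression of the non-mito transcriptome, summing to one."""
    base = rng.lognormal(mean=0.0, sigma=config.base_lognorm_sigma, size=config.n_genes)
    # signaling genes sit near the detection floor with a tight spread,
    # as baseline cytokine/receptor transcripts do in resting tissue
    base[layout.signaling] = config.signaling_scale * rng.lognormal(
        mean=0.0, sigma=0.25, size=len(layout.signaling)
    )
    base[layout.mito] = 0.0
    return base / base.sum()


def _gene_index(layout: _GeneLayout, gene: str) -> int:
    idx = np.flatnonzero(layout.gene_names == gene)
    if idx.size != 1:
        raise ConfigError(f"unknown or ambiguous gene name {gene!r}")
    return int(idx[0])


def _layer_multiplier(spec: ProgramSpec, t: float) -> float:
    """Program effect at pseudotime t in [0,1] (layer centers at 1/6, 1/2, 5/6)."""
    centers = np.array([1 / 6, 1 / 2, 5 / 6])
    return float(np.interp(t, centers, np.asarray(spec.layer_effects, dtype=float)))


def _type_rates(
    config: SimConfig,
    layout: _GeneLayout,
    base: np.ndarray,
    type_name: str,
    condition: str | None,
    pseudotime: float | None,
) -> np.ndarray:
    """Expected relative expression for one (type, condition, pseudotime)."""
    spec = next(t for t in config.cell_types if t.name == type_name)
    rate = base.copy()
    rate[layout.markers[type_name]] *= spec.marker_fold
    if spec.layer is not None:
        t = pseudotime
        if t is None:
            t = (EPIDERMAL_LAYERS.index(spec.layer) + 0.5) / 3.0
        for p in config.program_specs:
            rate[layout.programs[p.name]] *= _layer_multiplier(p, t)
    for planted in config.planted_lr:
        if planted.condition is not None and condition != planted.condition:
            continue
        if type_name == planted.source:
            rate[_gene_index(layout, planted.ligand)] *= planted.fold
        if type_name == planted.target:
            rate[_gene_index(layout, planted.receptor)] *= planted.fold
    return rate


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB draw with mean mu and variance mu + mu^2/theta; Poisson as theta -> inf."""
    mu = np.asarray(mu, dtype=float)
    if not np.isfinite(theta):
        return rng.poisson(mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = theta / (theta + mu[pos])
    out[pos] = rng.negative_binomial(theta, p)
    return out


# ----------------------------------------------------------------------
# public generators
# ----------------------------------------------------------------------


def simulate_cells(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate a single-cell count matrix with per-cell sample/condition labels.

    Returns an AnnData (cells x genes, integer counts in ``.X``, sample and
    condition in ``.obs``) and the :class:`SyntheticTruth` holding the
    planted type, sub-cluster and pseudotime labels.
    """
    config.validate()
    streams = _streams(config.seed)
    layout = _GeneLayout(config)
    base = _base_profile(config, layout, streams["base"])

    n = config.n_cells
    rng_a = streams["assign"]
    conds = list(config.condition_weights)
    cond_of_cell = rng_a.choice(conds, size=n, p=list(config.condition_weights.values()))
    names = config.type_names()
    tw = (
        np.full(len(names), 1.0 / len(names))
        if config.type_weights is None
        else np.array([config.type_weights[t] for t in names])
    )
    type_of_cell = rng_a.choice(names, size=n, p=tw)
    sub_of_cell = np.empty(n, dtype=np.int64)
    for cond, mix in config.subcluster_mix.items():
        m = cond_of_cell == cond
        sub_of_cell[m] = rng_a.choice(config.n_subclusters, size=m.sum(), p=mix)
    sample_of_cell = np.array(
        [
            f"{c}{rng_a.integers(1, config.samples_per_condition + 1)}"
            for c in cond_of_cell
        ],
        dtype=object,
    )

    # layer-graded pseudotime for epidermal cells, uniform for the rest
    layer_of_type = {t.name: t.layer for t in config.cell_types}
    pt = rng_a.uniform(0.0, 1.0, size=n)
    for i in range(n):
        layer = layer_of_type[type_of_cell[i]]
        if layer is not None:
            k = EPIDERMAL_LAYERS.index(layer)
            pt[i] = (k + pt[i]) / 3.0

    # mitochondrial share per cell (Beta with an outlier component)
    rng_m = streams["mito"]
    a, b = config.mito_beta
    mito_share = rng_m.beta(a, b, size=n)
    out = rng_m.uniform(size=n) < config.mito_outlier_frac
    ao, bo = config.mito_outlier_beta
    mito_share[out] = rng_m.beta(ao, bo, size=int(out.sum()))

    depth = np.full(n, config.depth_per_cell)
    if config.low_depth_frac > 0:
        low = rng_m.uniform(size=n) < config.low_depth_frac
        depth[low] *= config.low_depth_scale

    # mito relative profile (uniform-ish, drawn once)
    mito_profile = rng_m.dirichlet(np.full(config.n_mito, 5.0)) if config.n_mito else None

    rate_cache: dict[tuple, np.ndarray] = {}
    rng_c = streams["cells"]
    lam = np.zeros((n, config.n_genes))
    for i in range(n):
        tname, cond = type_of_cell[i], cond_of_cell[i]
        is_epi = layer_of_type[tname] is not None
        # epidermal rates depend continuously on pseudotime; quantize for caching
        tq = round(float(pt[i]), 2) if is_epi else None
        key = (tname, cond, tq)
        if key not in rate_cache:
            rate_cache[key] = _type_rates(config, layout, base, tname, cond, tq)
        rate = rate_cache[key]
        lam[i] = depth[i] * (1.0 - mito_share[i]) * rate
        if config.n_mito:
            lam[i, layout.mito] = depth[i] * mito_share[i] * mito_profile

    counts = _nb_sample(rng_c, lam, config.nb_dispersion)

    cell_ids = [f"cell_{i:05d}" for i in range(n)]
    obs = pd.DataFrame(
        {"sample_id": sample_of_cell, "condition": cond_of_cell}, index=cell_ids
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int32)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(layout.gene_names, name="gene")),
    )

    truth = SyntheticTruth(
        cell_type_of_cell=pd.Series(type_of_cell, index=cell_ids, name="cell_type"),
        subcluster_of_cell=pd.Series(
            [f"{t}_{s}" for t, s in zip(type_of_cell, sub_of_cell)],
            index=cell_ids,
            name="subcluster",
        ),
        condition_of_cell=pd.Series(cond_of_cell, index=cell_ids, name="condition"),
        pseudotime_true=pd.Series(pt, index=cell_ids, name="pseudotime"),
        marker_genes={
            t: list(layout.gene_names[idx]) for t, idx in layout.markers.items()
        },
        program_gene_sets={
            p: list(layout.gene_names[idx]) for p, idx in layout.programs.items()
        },
        signaling_genes=list(layout.gene_names[layout.signaling]),
        planted_lr=list(config.planted_lr),
    )
    return adata, truth


def true_type_profiles(config: SimConfig) -> pd.DataFrame:
    """Expected relative expression per cell type (genes x types), mito excluded.

    These are the count-space profiles the spot simulator mixes; they can
    also serve as an idealized signature for deconvolution tests.
    """
    config.validate()
    streams = _streams(config.seed)
    layout = _GeneLayout(config)
    base = _base_profile(config, layout, streams["base"])
    cols = {}
    for t in config.cell_types:
        cols[t.name] = _type_rates(
            config, layout, base, t.name, config.spot_condition, None
        )
    return pd.DataFrame(cols, index=layout.gene_names)


def _lattice_coords(config: SimConfig) -> pd.DataFrame:
    rows, cols = config.lattice_rows, config.lattice_cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    ids = [f"spot_{r:03d}_{c:03d}" for r, c in zip(rr.ravel(), cc.ravel())]
    return pd.DataFrame(
        {"array_row": rr.ravel(), "array_col": cc.ravel()}, index=ids
    )


def simulate_spots(
    config: SimConfig, profiles: pd.DataFrame | None = None
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate a lattice of capture spots as NB-noised cell-type mixtures.

    Each spot's expected expression is ``spot_depth x (fractions . profiles)``
    where the true fraction vector is Dirichlet-jittered around its
    stratum's mixture.  ``profiles`` defaults to the config's own
    count-space type profiles (:func:`true_type_profiles`).
    """
    config.validate()
    if profiles is None:
        profiles = true_type_profiles(config)
    missing = set().union(*(m.keys() for m in config.strata_mixtures.values())) - set(
        profiles.columns
    )
    if missing:
        raise ConfigError(f"profiles missing types used in strata mixtures: {missing}")

    streams = _streams(config.seed)
    rng = streams["spots"]
    coords = _lattice_coords(config)
    n_spots = len(coords)
    types = list(profiles.columns)

    stratum_of_row = {}
    for stratum, (lo, hi) in config.strata_rows.items():
        for r in range(lo, hi):
            stratum_of_row[r] = stratum
    stratum = coords["array_row"].map(stratum_of_row)

    fractions = np.zeros((n_spots, len(types)))
    for i, (sid, row) in enumerate(coords.iterrows()):
        mix = config.strata_mixtures[stratum.iloc[i]]
        support = [t for t, w in mix.items() if w > 0]
        if len(support) == 1:
            fractions[i, types.index(support[0])] = 1.0
            continue
        alpha = np.array([mix[t] for t in support]) * config.spot_dirichlet_conc
        draw = rng.dirichlet(alpha)
        for t, f in zip(support, draw):
            fractions[i, types.index(t)] = f

    # transcript-fraction convention: each type profile renormalized to a
    # simplex so spot_depth is the expected total regardless of markers
    P = profiles.to_numpy(dtype=float)
    P = P / P.sum(axis=0, keepdims=True)  # genes x types
    lam = config.spot_depth * (fractions @ P.T)
    counts = _nb_sample(rng, lam, config.nb_dispersion)

    obs = coords.copy()
    obs["condition"] = config.spot_condition
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int32)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(profiles.index, name="gene")),
    )
    adata.uns["lattice"] = config.lattice

    truth = SyntheticTruth(
        true_spot_fractions=pd.DataFrame(fractions, index=coords.index, columns=types),
        stratum_of_spot=pd.Series(stratum.to_numpy(), index=coords.index, name="stratum"),
        planted_lr=list(config.planted_lr),
    )
    return adata, truth


def simulate_pixels(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a sub-cellular pixel table (x_um, y_um, gene, count).

    Pixels are uniform in a rectangular field; the gene of each pixel is
    drawn from the expression profile of the tissue band at its y
    coordinate (bands ordered as the lattice strata, outermost at y = 0).
    """
    config.validate()
    streams = _streams(config.seed)
    rng = streams["pixels"]
    width, height = config.pixel_field_um
    n_pixels = int(round(config.pixel_density_per_um2 * width * height))
    if n_pixels == 0 or width == 0 or height == 0:
        empty = pd.DataFrame(columns=["x_um", "y_um", "gene", "count"])
        return empty, SyntheticTruth()

    profiles = true_type_profiles(config)
    types = list(profiles.columns)
    P = profiles.to_numpy(dtype=float)

    # band boundaries proportional to the lattice row allocation
    strata = list(config.strata_rows)
    rows_per = np.array([hi - lo for lo, hi in config.strata_rows.values()], dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(rows_per / rows_per.sum()) * height])

    x = rng.uniform(0.0, width, size=n_pixels)
    y = rng.uniform(0.0, height, size=n_pixels)
    band = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, len(strata) - 1)

    gene_idx = np.zeros(n_pixels, dtype=np.int64)
    gene_names = profiles.index.to_numpy()
    for b, stratum in enumerate(strata):
        m = band == b
        if not m.any():
            continue
        mix = config.strata_mixtures[stratum]
        w = np.zeros(len(types))
        for t, f in mix.items():
            w[types.index(t)] = f
        probs = P @ w
        probs = probs / probs.sum()
        gene_idx[m] = rng.choice(len(gene_names), size=int(m.sum()), p=probs)

    px = pd.DataFrame(
        {
            "x_um": x,
            "y_um": y,
            "gene": gene_names[gene_idx],
            "count": np.ones(n_pixels, dtype=np.int64),
        }
    )
    truth = SyntheticTruth(
        stratum_of_pixel=pd.Series(np.array(strata, dtype=object)[band], name="stratum")
    )
    return px, truth


# ----------------------------------------------------------------------
# preset configurations and benchmarks
# ----------------------------------------------------------------------


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard layered-skin configuration used across the pipeline."""
    cfg = SimConfig(seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def atlas_config(seed: int = 0, n_cells: int = 3000, n_types: int = 6) -> SimConfig:
    """A compact atlas with ``n_types`` well-separated cell types.

    Used for clustering-recovery benchmarks: marker fold-change 5 at
    depth 5,000 makes types separable while keeping within-type cells
    exchangeable.
    """
    types = _default_cell_types()[:n_types]
    names = {t.name for t in types}
    mixtures = {}
    for stratum, mix in _default_strata_mixtures().items():
        kept = {t: w for t, w in mix.items() if t in names}
        total = sum(kept.values())
        if total == 0:
            kept = {t.name: 1.0 for t in types}
            total = float(len(types))
        mixtures[stratum] = {t: w / total for t, w in kept.items()}
    return default_config(
        seed=seed, n_cells=n_cells, cell_types=types, strata_mixtures=mixtures
    )


def qc_benchmark_config(seed: int = 0, n_cells: int = 1000) -> SimConfig:
    """Atlas with planted QC violations (shallow libraries, mito outliers)."""
    return default_config(
        seed=seed,
        n_cells=n_cells,
        low_depth_frac=0.15,
        low_depth_scale=0.05,
        mito_outlier_frac=0.15,
    )


def lr_benchmark_config(
    seed: int = 0,
    n_cells: int = 2400,
    n_pairs: int = 200,
    n_planted: int = 20,
    fold: float = 50.0,
) -> tuple[SimConfig, pd.DataFrame]:
    """Interaction benchmark: ``n_pairs`` ligand-receptor pairs, of which
    ``n_planted`` are planted PP-specific between four major cell types.

    Returns the config plus the ligand-receptor database table
    (pair_id, ligand_members, receptor_members).  Database genes come from
    the low-expression signaling block, so unplanted pairs sit at the
    detection floor, as baseline cytokine transcripts do in real skin.
    """
    types = [
        CellTypeSpec("KC_supraspinous", layer="supraspinous"),
        CellTypeSpec("Fibroblast"),
        CellTypeSpec("T_cell"),
        CellTypeSpec("Myeloid"),
    ]
    cfg = default_config(
        seed=seed,
        n_cells=n_cells,
        cell_types=types,
        n_signaling=max(450, 2 * n_pairs + 10),
        strata_rows={"supraspinous": (0, 4), "dermis": (4, 16)},
        strata_mixtures={
            "supraspinous": {"KC_supraspinous": 1.0},
            "dermis": {"Fibroblast": 0.5, "T_cell": 0.25, "Myeloid": 0.25},
        },
    )
    layout = _GeneLayout(cfg)
    sig_genes = list(layout.gene_names[layout.signaling])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]).generate_state(1)[0])
    picked = rng.choice(len(sig_genes), size=2 * n_pairs, replace=False)
    ligands = [sig_genes[i] for i in picked[:n_pairs]]
    receptors = [sig_genes[i] for i in picked[n_pairs:]]
    tnames = cfg.type_names()
    planted = []
    for j in range(n_planted):
        src = tnames[int(rng.integers(len(tnames)))]
        dst = tnames[int(rng.integers(len(tnames)))]
        planted.append(
            PlantedLR(
                ligand=ligands[j],
                receptor=receptors[j],
                source=src,
                target=dst,
                condition="PP",
                fold=fold,
            )
        )
    cfg.planted_lr = planted
    db = pd.DataFrame(
        {
            "pair_id": [f"pair_{j:04d}" for j in range(n_pairs)],
            "ligand_members": ligands,
            "receptor_members": receptors,
        }
    )
    return cfg, db


def null_lr_database(config: SimConfig, n_pairs: int = 500) -> pd.DataFrame:
    """A database of pairs built from well-expressed background genes.

    Background genes have identical expected expression in every cell type
    and condition, so cluster labels are exchangeable and permutation
    p-values for these pairs are uniform: the calibration null.
    """
    layout = _GeneLayout(config)
    bg = list(layout.gene_names[layout.background])
    if len(bg) < 2 * n_pairs:
        raise ConfigError("not enough background genes for the null database")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]).generate_state(1)[0])
    picked = rng.choice(len(bg), size=2 * n_pairs, replace=False)
    return pd.DataFrame(
        {
            "pair_id": [f"null_{j:04d}" for j in range(n_pairs)],
            "ligand_members": [bg[i] for i in picked[:n_pairs]],
            "receptor_members": [bg[i] for i in picked[n_pairs:]],
        }
    )
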