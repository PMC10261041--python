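"""Spot deconvolution against single-cell reference signatures and
tissue-domain clustering.

Each capture spot collects transcripts from a mixture of cells, so a
spot's depth-normalized expression is (up to noise) a non-negative linear
combination of per-type expression profiles.  Composition is estimated by
non-negative least squares on the linear CP10K scale -- the scale on which
mixing is actually additive -- against per-type mean CP10K signatures,
with the coefficients renormalized to a simplex.  Domains are k-means
clusters of the composition vectors, annotated by their dominant cell
type.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.cluster import KMeans

from . import sc_core


def build_signature_matrix(
    nm: ad.AnnData, labels: pd.Series, panel: list[str], scale: str = "cp10k"
) -> pd.DataFrame:
    """Per-type mean expression over a gene panel (genes x types).

    ``scale='cp10k'`` (default) averages the expm1 of the log-normalized
    values, i.e. each column is the type's mean depth-normalized
    expression on the linear scale where spot mixtures are additive;
    ``scale='lognorm'`` averages the log1p values directly (for display
    and marker inspection).
    """
    if scale not in ("cp10k", "lognorm"):
        raise ValueError(f"unknown scale {scale!r}")
    lab = labels.loc[nm.obs_names]
    panel = [g for g in panel if g in nm.var_names]
    if not panel:
        raise ValueError("no panel gene present in the matrix")
    cols = {}
    for t in sorted(lab.unique()):
        mask = (lab == t).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"cell type {t!r} has zero cells")
        if mask.sum() < 20:
            warnings.warn(f"cell type {t!r} has only {mask.sum()} cells")
        vals = np.asarray(sc_core._dense(nm[mask, panel].X))
        if scale == "cp10k":
            vals = np.expm1(vals)
        cols[t] = vals.mean(axis=0)
    sig = pd.DataFrame(cols, index=panel)
    if (sig.sum(axis=0) == 0).any():
        raise ValueError("signature matrix has an all-zero column")
    return sig


def marker_hvg_panel(
    nm: ad.AnnData,
    labels: pd.Series,
    n_markers: int = 50,
    hvg: list[str] | None = None,
) -> list[str]:
    """Deconvolution panel: union of per-type top markers and (optionally) HVGs."""
    markers = sc_core.rank_markers(nm, labels, n_top=n_markers)
    panel: set[str] = set()
    for genes in markers.values():
        panel.update(genes)
    if hvg:
        panel.update(g for g in hvg if g in nm.var_names)
    return sorted(panel)


def deconvolve_spots(
    spots: ad.AnnData,
    sig: pd.DataFrame,
    min_shared: int = 50,
    nb_dispersion: float = 10.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Variance-weighted NNLS composition estimate per spot.

    Spots are CP10K depth-normalized (linear scale, where the mixture of
    cell-type profiles is additive), restricted to the genes shared with
    the signature, and each spot's vector is regressed on the signature
    columns with non-negativity.  Genes are inverse-standard-deviation
    weighted under an NB noise model (sd ~ sqrt(m + m^2/theta) at the
    signature's mean expression m), so highly expressed genes with
    multiplicative noise do not dominate the fit.  Coefficients are
    divided by their sum.  Spots with zero panel counts get an all-NaN
    row (flagged, not normalized).  Returns (fractions spots x types,
    residual norm).
    """
    shared = [g for g in sig.index if g in spots.var_names]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} genes shared between spots and signature "
            f"(need >= {min_shared})"
        )
    S = sig.loc[shared].to_numpy(dtype=float)
    m = S.mean(axis=1)
    w = np.sqrt(m + m * m / nb_dispersion + 1e-3)
    Sw = S / w[:, None]
    counts = sc_core._dense(spots[:, shared].X).astype(float)
    totals = np.asarray(spots.X.sum(axis=1)).ravel()

    frac = np.full((spots.n_obs, sig.shape[1]), np.nan)
    resid = np.full(spots.n_obs, np.nan)
    for i in range(spots.n_obs):
        if totals[i] <= 0 or counts[i].sum() <= 0:
            continue
        y = 1e4 * counts[i] / totals[i]
        coef, r = optimize.nnls(Sw, y / w)
        s = coef.sum()
        if s <= 0:
            continue
        frac[i] = coef / s
        resid[i] = r
    fractions = pd.DataFrame(frac, index=spots.obs_names, columns=sig.columns)
    return fractions, pd.Series(resid, index=spots.obs_names, name="residual")


def cluster_domains(
    comp: pd.DataFrame, k: int = 6, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means tissue domains on composition rows.

    Flagged (all-NaN) spots are excluded and labeled -1.  Domain ids are
    ordered by decreasing size; also returns each domain's mean
    composition.
    """
    valid = comp.dropna()
    if k > len(valid):
        raise ValueError("k exceeds the number of valid spots")
    if len(valid.drop_duplicates()) < k:
        warnings.warn("fewer distinct composition rows than k; clusters degenerate")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(valid.to_numpy())
    raw = pd.Series(km.labels_, index=valid.index)
    sizes = raw.value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = pd.Series(-1, index=comp.index, name="domain", dtype=int)
    labels.loc[valid.index] = raw.map(remap)
    means = valid.groupby(labels.loc[valid.index]).mean()
    means.index.name = "domain"
    return labels, means


def annotate_domains(labels: pd.Series, comp: pd.DataFrame) -> pd.Series:
    """Name each domain by the cell type(s) with highest mean fraction.

    Exact ties yield a compound name joining the tied types in
    lexicographic order with '+'.
    """
    if not labels.index.equals(comp.index):
        raise ValueError("labels and composition must cover the same spots")
    names = {}
    valid = comp.dropna()
    for dom, block in valid.groupby(labels.loc[valid.index]):
        if dom == -1:
            continue
        mean = block.mean()
        top = mean.max()
        winners = sorted(mean.index[mean == top])
        names[dom] = "+".join(winners)
    return pd.Series(names, name="annotation").sort_index()
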