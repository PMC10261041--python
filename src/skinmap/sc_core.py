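"""Single-cell preprocessing, composition, differential expression and
gene-module scoring.

All operations take an AnnData (cells x genes).  Raw integer counts live in
``.X`` of the input matrix; :func:`normalize_cp10k_log` produces the
log1p-CP10K matrix every downstream statistic works on.
"""

from __future__ import annotations

import warnings

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


# ----------------------------------------------------------------------
# quality control
# ----------------------------------------------------------------------


def qc_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell transcript total, detected-gene count and mito fraction."""
    X = adata.X
    if sparse.issparse(X):
        total = np.asarray(X.sum(axis=1)).ravel()
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        total = X.sum(axis=1)
        n_genes = (X > 0).sum(axis=1)
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    if not mito_mask.any():
        warnings.warn(
            f"no genes match mito prefix {mito_prefix!r}; mito filter is vacuous"
        )
        mito = np.zeros(adata.n_obs)
    else:
        sub = X[:, np.flatnonzero(mito_mask)]
        mito = np.asarray(sub.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "n_transcripts": total.astype(np.int64),
            "n_genes": n_genes.astype(np.int64),
            "mito_frac": mito_frac,
        },
        index=adata.obs_names,
    )


def qc_filter(
    adata: ad.AnnData,
    min_transcripts: int = 500,
    min_genes: int = 100,
    max_mito_frac: float = 0.10,
    mito_prefix: str = "MT-",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-quality cells.

    A cell is retained iff transcripts >= ``min_transcripts`` AND detected
    genes >= ``min_genes`` AND mito fraction <= ``max_mito_frac`` (the
    low-side inequalities are strict on removal, and a cell at exactly the
    mito ceiling is retained).  The gene set is unchanged.  Returns the
    filtered matrix and a per-cell report with the metrics and a
    ``retained`` flag.
    """
    report = qc_metrics(adata, mito_prefix=mito_prefix)
    keep = (
        (report["n_transcripts"] >= min_transcripts)
        & (report["n_genes"] >= min_genes)
        & (report["mito_frac"] <= max_mito_frac)
    )
    report = report.assign(retained=keep)
    if not keep.any():
        warnings.warn("qc_filter removed every cell")
    return adata[keep.to_numpy()].copy(), report


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------


def normalize_cp10k_log(adata: ad.AnnData) -> ad.AnnData:
    """log1p counts-per-10k: value(c, g) = ln(1 + 1e4 * count / total(c)).

    Zero counts map to exactly 0 and the transform is invariant to
    per-cell depth scaling.  Cells with zero total are rejected (run
    :func:`qc_filter` first).
    """
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    if (total <= 0).any():
        raise ValueError(
            "cells with zero total counts present; apply qc_filter before "
            "normalization"
        )
    out = adata.copy()
    if sparse.issparse(X):
        Xn = X.astype(np.float64).tocsr(copy=True)
        scale = 1e4 / total
        Xn = sparse.diags(scale) @ Xn
        Xn.data = np.log1p(Xn.data)
        out.X = Xn.tocsr()
    else:
        out.X = np.log1p(1e4 * np.asarray(X, dtype=float) / total[:, None])
    out.uns["normalization"] = "log1p-CP10K"
    return out


# ----------------------------------------------------------------------
# variable genes
# ----------------------------------------------------------------------


def select_variable_genes(nm: ad.AnnData, n_top: int = 2000) -> list[str]:
    """Top ``n_top`` genes by standardized variance (vst-style).

    Works on the CP10K scale (expm1 of the normalized values): a lowess
    trend of log10 variance on log10 mean predicts each gene's expected
    standard deviation; values standardized by the trend are clipped at
    sqrt(n_cells) and the genes with the largest clipped variance win.
    """
    if n_top > nm.n_vars:
        raise ValueError("n_top exceeds the number of genes")
    X = _dense(nm.X)
    cp10k = np.expm1(X)
    mu = cp10k.mean(axis=0)
    var = cp10k.var(axis=0, ddof=1)
    varying = (var > 0) & (mu > 0)
    if not varying.any():
        warnings.warn("matrix is constant; returning genes in stored order")
        return list(nm.var_names[:n_top])
    logmu = np.log10(mu[varying])
    logvar = np.log10(var[varying])
    fit = lowess(logvar, logmu, frac=0.3, return_sorted=False)
    sd_hat = np.sqrt(10.0**fit)
    clip = np.sqrt(nm.n_obs)
    Z = (cp10k[:, varying] - mu[varying]) / sd_hat
    np.clip(Z, -clip, clip, out=Z)
    std_var = np.zeros(nm.n_vars)
    std_var[varying] = Z.var(axis=0, ddof=1)
    order = np.argsort(-std_var, kind="stable")
    return list(nm.var_names[order[:n_top]])


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------


def cluster_cells(
    nm: ad.AnnData,
    hvg: list[str],
    n_pcs: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
    n_neighbors: int = 15,
) -> pd.Series:
    """Leiden community detection on a PCA/KNN graph of the HVG submatrix.

    Genes are z-scored (clipped at 10) before PCA; the KNN graph is the
    symmetrized k-nearest-neighbour relation in PC space; communities are
    found by modularity (RB configuration) at the given resolution.
    Cluster ids are integers ordered by decreasing size.  Deterministic
    given the seed.
    """
    if not hvg:
        raise ValueError("hvg must be non-empty")
    X = _dense(nm[:, hvg].X)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -10, 10)
    n_pcs_eff = min(n_pcs, Z.shape[0] - 1, Z.shape[1])
    if n_pcs_eff < n_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {n_pcs_eff}")
    pcs = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed).fit_transform(Z)

    knn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, len(pcs))).fit(pcs)
    _, idx = knn.kneighbors(pcs)
    edges = {
        (min(i, j), max(i, j))
        for i, row in enumerate(idx)
        for j in row[1:]
    }
    g = igraph.Graph(n=len(pcs), edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel by decreasing cluster size (ties broken by old label)
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    return pd.Series(
        [remap[v] for v in labels], index=nm.obs_names, name="cluster", dtype=int
    )


# ----------------------------------------------------------------------
# composition
# ----------------------------------------------------------------------


def composition_table(labels: pd.Series, conditions: pd.Series) -> pd.DataFrame:
    """Condition composition per label, scaled to 100 percent per row.

    entry(type, cond) = 100 * f(type, cond) / sum_cond' f(type, cond')
    with f(type, cond) = n(type, cond) / N(cond): the within-condition
    frequencies are compared so that unequal condition sizes do not bias
    the shares.
    """
    conditions = conditions.loc[labels.index]
    n_cond = conditions.value_counts()
    empty = n_cond[n_cond == 0]
    if len(empty):
        warnings.warn(f"conditions with zero cells excluded: {list(empty.index)}")
    counts = pd.crosstab(labels, conditions)
    f = counts.div(n_cond[counts.columns], axis=1)
    share = f.div(f.sum(axis=1), axis=0) * 100.0
    share.index.name = "label"
    share.columns.name = "condition"
    return share


# ----------------------------------------------------------------------
# differential expression
# ----------------------------------------------------------------------


def _exact_rank_p(xa: np.ndarray, xb: np.ndarray) -> float | None:
    """Two-sided exact rank-sum p via the null distribution of U.

    Only valid without ties (scipy's exact method assumes continuity);
    returns None when ties are present so the caller keeps the
    tie-corrected normal approximation.
    """
    combined = np.concatenate([xa, xb])
    if len(np.unique(combined)) != len(combined):
        return None
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="exact")
    return float(res.pvalue)


def wilcoxon_de(
    nm: ad.AnnData,
    group_a,
    group_b,
    exact_limit: int = 400,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum differential expression per gene.

    ``group_a`` / ``group_b`` are disjoint boolean masks or index arrays
    over cells.  P-values use the tie-corrected normal approximation with
    continuity correction, replaced by the exact null distribution of U
    when nA * nB <= ``exact_limit`` and the gene has no ties.  Log
    fold-changes are natural-log ratios of mean expm1-normalized
    expression (pseudocount 1e-9); BH adjustment across genes.
    """
    a_idx = np.flatnonzero(group_a) if np.asarray(group_a).dtype == bool else np.asarray(group_a)
    b_idx = np.flatnonzero(group_b) if np.asarray(group_b).dtype == bool else np.asarray(group_b)
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(a_idx, b_idx).size:
        raise ValueError("groups overlap")
    Xa = _dense(nm.X[a_idx])
    Xb = _dense(nm.X[b_idx])
    na, nb = len(a_idx), len(b_idx)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(
            Xa, Xb, alternative="two-sided", method="asymptotic", axis=0
        )
    p = np.asarray(res.pvalue, dtype=float)
    # fully tied genes (zero rank variance) yield NaN; no evidence => p = 1
    constant = (np.ptp(Xa, axis=0) == 0) & (np.ptp(Xb, axis=0) == 0) & (Xa[0] == Xb[0])
    p[constant] = 1.0
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)

    if na * nb <= exact_limit:
        for g in range(nm.n_vars):
            if constant[g]:
                continue
            pe = _exact_rank_p(Xa[:, g], Xb[:, g])
            if pe is not None:
                p[g] = pe

    eps = 1e-9
    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    lfc = np.log(mean_a + eps) - np.log(mean_b + eps)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log_fc": lfc,
            "p": p,
            "fdr": fdr,
            "pct_a": (Xa > 0).mean(axis=0),
            "pct_b": (Xb > 0).mean(axis=0),
        },
        index=nm.var_names,
    )


def rank_markers(
    nm: ad.AnnData, labels: pd.Series, n_top: int = 50
) -> dict[str, list[str]]:
    """Top one-vs-rest markers per label (by p, then descending log FC)."""
    out = {}
    lab = labels.loc[nm.obs_names]
    for group in sorted(lab.unique()):
        mask = (lab == group).to_numpy()
        de = wilcoxon_de(nm, mask, ~mask)
        de = de[de["log_fc"] > 0].sort_values(["p", "log_fc"], ascending=[True, False])
        out[group] = list(de.index[:n_top])
    return out


# ----------------------------------------------------------------------
# module scoring
# ----------------------------------------------------------------------


def module_score(
    nm: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control gene-module score per cell.

    Genes are ordered by their dataset-average expression and split into
    ``n_bins`` near-equal bins; for each target gene, ``n_ctrl`` control
    genes are sampled from the target's bin (without replacement when the
    bin is large enough); the score is the per-cell mean of the target
    genes minus the mean of the pooled control draws (with multiplicity).
    Centered by construction: a random gene set scores ~0.
    """
    present = [g for g in gene_set if g in nm.var_names]
    missing = set(gene_set) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} gene-set genes absent from the matrix")
    if not present:
        raise ValueError("no gene of the set is present in the matrix")

    X = _dense(nm.X)
    data_avg = X.mean(axis=0)
    order = np.argsort(data_avg, kind="mergesort")
    bin_of_gene = np.empty(nm.n_vars, dtype=np.int64)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of_gene[chunk] = b

    gene_pos = {g: i for i, g in enumerate(nm.var_names)}
    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    target_idx = []
    for g in present:
        gi = gene_pos[g]
        target_idx.append(gi)
        members = np.flatnonzero(bin_of_gene == bin_of_gene[gi])
        replace = len(members) < n_ctrl
        ctrl_idx.append(rng.choice(members, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_idx)
    return X[:, target_idx].mean(axis=1) - X[:, ctrl].mean(axis=1)


# ----------------------------------------------------------------------
# grouped means
# ----------------------------------------------------------------------


def group_mean_expression(
    nm: ad.AnnData,
    labels: pd.Series,
    genes: list[str] | None = None,
    min_avg: float = 0.01,
) -> pd.DataFrame:
    """Mean normalized expression per (gene, label).

    Genes whose maximum group average is below ``min_avg`` are dropped as
    lowly expressed (the strict-< reading: a gene reaching ``min_avg`` in
    any group is retained).
    """
    lab = labels.loc[nm.obs_names]
    sub = nm if genes is None else nm[:, [g for g in genes if g in nm.var_names]]
    X = _dense(sub.X)
    groups = sorted(lab.unique())
    means = pd.DataFrame(
        {g: X[(lab == g).to_numpy()].mean(axis=0) for g in groups},
        index=sub.var_names,
    )
    return means[means.max(axis=1) >= min_avg]
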