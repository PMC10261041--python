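"""Hypergeometric upstream-regulator enrichment with BH FDR, and
correlation of regulator target-set module scores with pseudotime.

A regulator's target set is tested for over-representation in a query
gene list (e.g. differentially expressed genes) against a universe of
detected genes: p = P(X >= k) for X hypergeometric with population
``n_universe``, successes ``n_set`` and draws ``n_query``.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import sc_core, spatial_stats


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    query: list[str],
    regulator_sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each regulator target set.

    ``query`` and each regulator set are intersected with the universe
    before testing; BH adjustment across regulators.  Sorted by FDR.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    q = set(query) & uni
    rows = []
    for name, genes in regulator_sets.items():
        s = set(genes) & uni
        k = len(s & q)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(s), len(q)))
        rows.append((name, len(uni), len(s), len(q), k, p))
    res = pd.DataFrame(
        rows, columns=["regulator", "n_universe", "n_set", "n_query", "overlap", "p"]
    ).set_index("regulator")
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    return res.sort_values(["fdr", "p"])


def detected_universe(nm: ad.AnnData) -> list[str]:
    """Genes expressed in at least one cell of the matrix."""
    X = nm.X
    detected = np.asarray((X > 0).sum(axis=0)).ravel() > 0
    return list(nm.var_names[detected])


def regulator_score_correlation(
    nm: ad.AnnData,
    regulator_sets: dict[str, list[str]],
    pseudotime: pd.Series,
    seed: int = 0,
    method: str = "pearson",
    n_bins: int = 24,
    n_ctrl: int = 100,
) -> pd.Series:
    """Correlation of each regulator's target-set module score with pseudotime.

    Scores are binned-control module scores (see
    :func:`skinmap.sc_core.module_score`); regulators whose score vector
    is constant get NaN with a warning.
    """
    pt = pseudotime.loc[nm.obs_names].to_numpy(dtype=float)
    if np.isnan(pt).any():
        raise ValueError("pseudotime must be defined for every cell scored")
    out = {}
    for name, genes in regulator_sets.items():
        score = sc_core.module_score(nm, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        if np.ptp(score) == 0:
            warnings.warn(f"regulator {name!r} has a constant score vector")
            out[name] = float("nan")
        else:
            out[name] = spatial_stats.score_correlation(score, pt, method=method)
    return pd.Series(out, name="r")
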