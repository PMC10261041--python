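"""Spot-adjacency statistics, sub-cellular grid binning, and module-score
correlation.

The adjacency statistic counts, for every unordered pair of neighboring
lattice spots, the cell-type pairs the two spots carry; the neighbor set
is defined by the lattice (rook, queen, or the six hexagonal offsets a
Visium array uses, which depend on row parity).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

LATTICES = ("square4", "square8", "hex6")


def neighbor_offsets(lattice: str, row: int) -> list[tuple[int, int]]:
    """(dr, dc) neighbor offsets for a spot in ``row`` of the lattice."""
    if lattice == "square4":
        return [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if lattice == "square8":
        return [
            (dr, dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        ]
    if lattice == "hex6":
        # odd-r horizontal hex layout: odd rows shift right by half a spot
        if row % 2 == 0:
            return [(0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)]
        return [(0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)]
    raise ValueError(f"unknown lattice {lattice!r}")


def lattice_edges(coords: pd.DataFrame, lattice: str) -> list[tuple[str, str]]:
    """Unordered neighbor edges between spots; each edge listed once.

    ``coords`` has columns array_row / array_col indexed by spot id;
    coordinates must be unique.
    """
    pos = {}
    for sid, row in coords.iterrows():
        key = (int(row["array_row"]), int(row["array_col"]))
        if key in pos:
            raise ValueError(f"duplicate lattice coordinate {key}")
        pos[key] = sid
    edges = []
    for (r, c), sid in pos.items():
        for dr, dc in neighbor_offsets(lattice, r):
            other = pos.get((r + dr, c + dc))
            if other is not None and sid < other:
                edges.append((sid, other))
    return sorted(edges)


def spot_memberships(
    comp: pd.DataFrame, rule: str = "threshold", tau: float = 0.1
) -> dict[str, list[str]]:
    """Which cell types each spot 'contains'.

    ``threshold``: every type with fraction >= tau (the slices visible in
    a scatter-pie plot); ``dominant``: the argmax type only.  Flagged
    (NaN) spots contain nothing.
    """
    if rule not in ("threshold", "dominant"):
        raise ValueError(f"unknown membership rule {rule!r}")
    out = {}
    for sid, row in comp.iterrows():
        if row.isna().any():
            out[sid] = []
        elif rule == "dominant":
            out[sid] = [row.idxmax()]
        else:
            out[sid] = list(row.index[row >= tau])
    return out


def adjacency_counts(
    comp: pd.DataFrame,
    coords: pd.DataFrame,
    lattice: str,
    rule: str = "threshold",
    tau: float = 0.1,
) -> pd.DataFrame:
    """Neighboring-spot counts per cell-type pair.

    For each unordered lattice edge (s, s') and each ordered type pair
    (a in s, b in s'), one count is accumulated; the ordered matrix is
    then symmetrized with the diagonal kept as-is, so the diagonal counts
    each unordered adjacent same-type pair once.
    """
    types = list(comp.columns)
    members = spot_memberships(comp, rule=rule, tau=tau)
    pos = {t: i for i, t in enumerate(types)}
    O = np.zeros((len(types), len(types)), dtype=np.int64)
    for s, s2 in lattice_edges(coords.loc[comp.index], lattice):
        for a in members[s]:
            for b in members[s2]:
                O[pos[a], pos[b]] += 1
    S = O + O.T
    np.fill_diagonal(S, np.diag(O))
    return pd.DataFrame(S, index=types, columns=types)


def bin_pixels_to_grid(
    px: pd.DataFrame, grid_um: float = 10.0, min_genes_per_grid: int = 30
) -> pd.DataFrame:
    """Aggregate a pixel table into square grids (genes x grids).

    Grid cells are half-open [i*g, (i+1)*g) in both axes so each pixel
    maps to exactly one grid; counts are summed per (gene, grid) and
    grids detecting fewer than ``min_genes_per_grid`` distinct genes are
    removed.  Columns are (i, j) grid-index tuples.
    """
    if grid_um <= 0:
        raise ValueError("grid_um must be positive")
    if px.empty:
        return pd.DataFrame()
    gi = np.floor(px["x_um"].to_numpy() / grid_um).astype(np.int64)
    gj = np.floor(px["y_um"].to_numpy() / grid_um).astype(np.int64)
    df = pd.DataFrame({"gene": px["gene"].to_numpy(), "count": px["count"].to_numpy(),
                       "gi": gi, "gj": gj})
    grouped = df.groupby(["gene", "gi", "gj"], sort=True)["count"].sum()
    mat = grouped.unstack(["gi", "gj"], fill_value=0).sort_index(axis=1)
    n_genes = (mat > 0).sum(axis=0)
    return mat.loc[:, n_genes >= min_genes_per_grid]


def score_correlation(
    a: np.ndarray, b: np.ndarray, method: str = "pearson"
) -> float:
    """Correlation between two paired module-score vectors.

    Pearson by default (``method='spearman'`` available).  Returns NaN
    with a warning when either vector is constant or too short.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be paired")
    if len(a) < 3:
        raise ValueError("need at least 3 paired scores")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant score vector: correlation undefined")
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")
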