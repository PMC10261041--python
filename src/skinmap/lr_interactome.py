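"""Permutation-scored ligand-receptor interaction inference and
condition-specific differential network extraction.

The interaction statistic follows the published CellPhoneDB definition:
for a (ligand, receptor) pair between a source and a target cluster, the
score is the arithmetic mean of the ligand unit's average normalized
expression in the source cluster and the receptor unit's average in the
target cluster, where a protein complex takes the minimum over its
members; a unit counts as expressed only if more than
``min_expressed_frac`` of the cluster's cells detect every member.  The
null is a joint shuffle of cluster labels across cells; the p-value uses
the +1 correction, p = (1 + #{permuted >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import anndata as ad
import numpy as np
import pandas as pd

from . import sc_core


def _as_members(val) -> tuple[str, ...]:
    if isinstance(val, str):
        return tuple(v.strip() for v in val.split("|") if v.strip())
    return tuple(val)


def parse_lr_database(db: pd.DataFrame) -> pd.DataFrame:
    """Normalize a ligand-receptor table.

    Expects columns pair_id / ligand_members / receptor_members, complex
    members pipe-delimited; returns tuples of member genes.
    """
    out = pd.DataFrame(
        {
            "pair_id": db["pair_id"].astype(str),
            "ligand_members": db["ligand_members"].map(_as_members),
            "receptor_members": db["receptor_members"].map(_as_members),
        }
    )
    if out["pair_id"].duplicated().any():
        raise ValueError("pair_ids must be unique")
    if (out["ligand_members"].map(len) == 0).any() or (
        out["receptor_members"].map(len) == 0
    ).any():
        raise ValueError("complex member sets must be non-empty")
    return out


def classify_condition_specific(
    labels: pd.Series, conditions: pd.Series, cutoff: float = 0.70
) -> pd.DataFrame:
    """Classify sub-clusters as NS-specific / PP-specific / mixed.

    Composition is computed over NS and PP cells only (PN cells do not
    enter the condition-specific runs); a sub-cluster is specific to a
    condition iff that condition's share strictly exceeds ``cutoff``.
    """
    cond = conditions.loc[labels.index]
    use = cond.isin(["NS", "PP"])
    rows = []
    for sub in sorted(labels.unique()):
        m = (labels == sub) & use
        n = int(m.sum())
        ns = float((cond[m] == "NS").mean()) if n else np.nan
        pp = float((cond[m] == "PP").mean()) if n else np.nan
        if n and ns > cutoff:
            cls = "NS-specific"
        elif n and pp > cutoff:
            cls = "PP-specific"
        else:
            cls = "mixed"
        rows.append((sub, n, ns, pp, cls))
    return pd.DataFrame(
        rows, columns=["subcluster", "n_ns_pp", "ns_frac", "pp_frac", "class"]
    ).set_index("subcluster")


def _unit_stats(
    means: np.ndarray, detect: np.ndarray | None, member_idx: list[np.ndarray],
    min_frac: float,
):
    """Min-over-members cluster means and (optionally) expressed flags."""
    unit_mean = np.stack([means[idx].min(axis=0) for idx in member_idx])
    if detect is None:
        return unit_mean, None
    expressed = np.stack([(detect[idx] > min_frac).all(axis=0) for idx in member_idx])
    return unit_mean, expressed


def score_interactions(
    nm: ad.AnnData,
    labels: pd.Series,
    db: pd.DataFrame,
    min_expressed_frac: float = 0.10,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every (pair, source cluster, target cluster) combination.

    Returns a long table (pair_id, source, target, score, p, n_perm).
    Pairs whose genes are absent from the matrix are dropped with a
    warning.  Unexpressed combinations score 0 with p = 1.  Deterministic
    given the seed.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")
    db = parse_lr_database(db)
    have = set(nm.var_names)
    usable = db[
        db["ligand_members"].map(lambda m: set(m) <= have)
        & db["receptor_members"].map(lambda m: set(m) <= have)
    ]
    if len(usable) < len(db):
        warnings.warn(f"dropped {len(db) - len(usable)} pairs with unmapped genes")
    if usable.empty:
        return pd.DataFrame(
            columns=["pair_id", "source", "target", "score", "p", "n_perm"]
        )

    genes = sorted({g for ms in usable["ligand_members"] for g in ms}
                   | {g for ms in usable["receptor_members"] for g in ms})
    gene_pos = {g: i for i, g in enumerate(genes)}
    X = sc_core._dense(nm[:, genes].X)

    lab = labels.loc[nm.obs_names]
    clusters = sorted(lab.unique())
    codes = pd.Categorical(lab, categories=clusters).codes
    K = len(clusters)
    onehot = np.zeros((len(codes), K))
    onehot[np.arange(len(codes)), codes] = 1.0
    n_k = onehot.sum(axis=0)
    if (n_k == 0).any():
        raise ValueError("empty cluster in labels")

    means = (X.T @ onehot) / n_k  # genes x clusters
    detect = ((X > 0).T.astype(float) @ onehot) / n_k

    lig_idx = [np.array([gene_pos[g] for g in ms]) for ms in usable["ligand_members"]]
    rec_idx = [np.array([gene_pos[g] for g in ms]) for ms in usable["receptor_members"]]
    L, expr_l = _unit_stats(means, detect, lig_idx, min_expressed_frac)
    R, expr_r = _unit_stats(means, detect, rec_idx, min_expressed_frac)

    # observed scores: pairs x src x dst
    S = 0.5 * (L[:, :, None] + R[:, None, :])
    valid = expr_l[:, :, None] & expr_r[:, None, :]
    S = np.where(valid, S, 0.0)

    rng = np.random.default_rng(seed)
    ge = np.zeros_like(S, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        P = np.zeros((len(codes), K))
        P[np.arange(len(codes)), perm] = 1.0
        means_p = (X.T @ P) / n_k
        Lp, _ = _unit_stats(means_p, None, lig_idx, min_expressed_frac)
        Rp, _ = _unit_stats(means_p, None, rec_idx, min_expressed_frac)
        Sp = 0.5 * (Lp[:, :, None] + Rp[:, None, :])
        ge += Sp >= S
    p = (1.0 + ge) / (1.0 + n_perm)
    p = np.where(valid, p, 1.0)

    n_pairs = len(usable)
    src_idx, dst_idx = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
    records = pd.DataFrame(
        {
            "pair_id": np.repeat(usable["pair_id"].to_numpy(), K * K),
            "source": np.tile(np.asarray(clusters, dtype=object)[src_idx.ravel()], n_pairs),
            "target": np.tile(np.asarray(clusters, dtype=object)[dst_idx.ravel()], n_pairs),
            "score": S.reshape(-1),
            "p": p.reshape(-1),
            "n_perm": n_perm,
        }
    )
    return records


def filter_significant(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Drop records with p > alpha (and zero-score unexpressed records)."""
    return table[(table["p"] <= alpha) & (table["score"] > 0)].reset_index(drop=True)


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def run_condition_specific(
    nm: ad.AnnData,
    labels: pd.Series,
    conditions: pd.Series,
    db: pd.DataFrame,
    cutoff: float = 0.70,
    min_expressed_frac: float = 0.10,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Separate scoring runs on the condition-specific sub-clusters.

    The NS run uses NS cells from NS-specific sub-clusters; the PP run
    uses PP cells from PP-specific sub-clusters; mixed sub-clusters enter
    neither.  Records with p > alpha are removed from each table.
    Returns (ns_table, pp_table, classification).
    """
    lab = labels.loc[nm.obs_names]
    cond = conditions.loc[nm.obs_names]
    spec = classify_condition_specific(lab, cond, cutoff=cutoff)
    out = {}
    for i, (condition, cls) in enumerate([("NS", "NS-specific"), ("PP", "PP-specific")]):
        subs = spec.index[spec["class"] == cls]
        mask = (cond == condition) & lab.isin(subs)
        if not mask.any():
            warnings.warn(f"no {cls} sub-clusters: empty {condition} table")
            out[condition] = pd.DataFrame(
                columns=["pair_id", "source", "target", "score", "p", "n_perm"]
            )
            continue
        sub_nm = nm[mask.to_numpy()]
        table = score_interactions(
            sub_nm,
            lab[mask],
            db,
            min_expressed_frac=min_expressed_frac,
            n_perm=n_perm,
            seed=_subseed(seed, i),
        )
        out[condition] = filter_significant(table, alpha=alpha)
    return out["NS"], out["PP"], spec


def merge_to_celltype_pairs(
    table: pd.DataFrame, subcluster_to_type: Mapping
) -> pd.DataFrame:
    """Collapse sub-cluster records to major cell-type records.

    Records sharing (pair_id, source type, target type) merge to the one
    with the maximum score; the winning sub-cluster pair is retained as
    provenance.  Max is order-independent, so merging preserves the
    strongest sub-cluster signal.
    """
    if table.empty:
        return pd.DataFrame(
            columns=[
                "pair_id", "source", "target", "score", "p",
                "source_subcluster", "target_subcluster",
            ]
        )
    unmapped = (set(table["source"]) | set(table["target"])) - set(subcluster_to_type)
    if unmapped:
        raise KeyError(f"sub-clusters missing from the type map: {sorted(unmapped)}")
    t = table.copy()
    t["source_subcluster"] = t["source"]
    t["target_subcluster"] = t["target"]
    t["source"] = t["source_subcluster"].map(subcluster_to_type)
    t["target"] = t["target_subcluster"].map(subcluster_to_type)
    t = t.sort_values(
        ["pair_id", "source", "target", "score", "source_subcluster", "target_subcluster"],
        ascending=[True, True, True, False, True, True],
    )
    merged = t.groupby(["pair_id", "source", "target"], as_index=False).first()
    cols = ["pair_id", "source", "target", "score", "p",
            "source_subcluster", "target_subcluster"]
    return merged[[c for c in cols if c in merged.columns]]


def differential_network(
    pp: pd.DataFrame, ns: pd.DataFrame, require_both: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairs whose interaction score is strictly higher in PP than in NS.

    A pair absent from the NS table contributes score_NS = 0 (set
    ``require_both`` to demand presence in both runs).  Also returns the
    source x target matrix counting retained records, the summary heatmap
    of the differential network.
    """
    key = ["pair_id", "source", "target"]
    ns_scores = (
        ns[key + ["score"]].rename(columns={"score": "score_ns"})
        if not ns.empty
        else pd.DataFrame(columns=key + ["score_ns"])
    )
    if pp.empty:
        records = pd.DataFrame(columns=key + ["score_pp", "score_ns", "delta"])
    else:
        records = pp[key + ["score"]].rename(columns={"score": "score_pp"})
        records = records.merge(ns_scores, on=key, how="inner" if require_both else "left")
        records["score_ns"] = records["score_ns"].fillna(0.0)
        records = records[records["score_pp"] > records["score_ns"]].copy()
        records["delta"] = records["score_pp"] - records["score_ns"]
        records = records.reset_index(drop=True)
    if records.empty:
        matrix = pd.DataFrame(dtype=np.int64)
    else:
        matrix = pd.crosstab(records["source"], records["target"])
    return records, matrix
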