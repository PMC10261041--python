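"""Interaction scoring, permutation null, condition splitting and the
differential network."""

import itertools

import numpy as np
import pandas as pd
import pytest

from skinmap import lr_interactome, sc_core, synthgen

from conftest import make_adata


def _nm_from_values(values, gene_names):
    """AnnData whose .X is taken as already-normalized expression."""
    adata = make_adata(np.zeros_like(values), gene_names=gene_names)
    adata.X = np.asarray(values, dtype=float)
    return adata


def _db(pairs):
    return pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(len(pairs))],
            "ligand_members": [p[0] for p in pairs],
            "receptor_members": [p[1] for p in pairs],
        }
    )


# ----------------------------------------------------------------------
# condition specificity
# ----------------------------------------------------------------------


def test_classify_condition_specific_boundaries():
    idx = [f"c{i}" for i in range(30)]
    labels = pd.Series(["s1"] * 10 + ["s2"] * 10 + ["s3"] * 10, index=idx)
    cond = pd.Series(
        ["PP"] * 8 + ["NS"] * 2          # s1: 80% PP
        + ["PP"] * 7 + ["NS"] * 3        # s2: exactly 70% PP
        + ["NS"] * 10,                   # s3: all NS
        index=idx,
    )
    spec = lr_interactome.classify_condition_specific(labels, cond)
    assert spec.loc["s1", "class"] == "PP-specific"
    assert spec.loc["s2", "class"] == "mixed"  # strict inequality
    assert spec.loc["s3", "class"] == "NS-specific"


def test_classify_ignores_pn_cells():
    idx = [f"c{i}" for i in range(10)]
    labels = pd.Series(["s"] * 10, index=idx)
    cond = pd.Series(["NS"] * 4 + ["PN"] * 6, index=idx)
    spec = lr_interactome.classify_condition_specific(labels, cond)
    assert spec.loc["s", "class"] == "NS-specific"  # 4/4 of NS+PP cells


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------


def test_score_is_mean_of_cluster_means():
    # ligand mean 2.0 in source, receptor mean 4.0 in target, all detected
    vals = np.array(
        [[2.0, 0.5], [2.0, 0.5], [0.5, 4.0], [0.5, 4.0]]
    )
    nm = _nm_from_values(vals, ["L", "R"])
    labels = pd.Series(["src", "src", "dst", "dst"], index=nm.obs_names)
    tbl = lr_interactome.score_interactions(
        nm, labels, _db([("L", "R")]), n_perm=100, seed=0
    )
    rec = tbl[(tbl.source == "src") & (tbl.target == "dst")].iloc[0]
    assert rec["score"] == pytest.approx(3.0)


def test_constant_gene_permutation_p_is_one():
    vals = np.full((6, 2), 1.5)
    nm = _nm_from_values(vals, ["L", "R"])
    labels = pd.Series(["a"] * 3 + ["b"] * 3, index=nm.obs_names)
    tbl = lr_interactome.score_interactions(nm, labels, _db([("L", "R")]),
                                            n_perm=199, seed=0)
    assert (tbl["p"] == 1.0).all()


def test_complex_minimum_rule():
    vals = np.array([[3.0, 1.0, 5.0]] * 4)
    nm = _nm_from_values(vals, ["La", "Lb", "R"])
    labels = pd.Series(["a", "a", "b", "b"], index=nm.obs_names)
    tbl = lr_interactome.score_interactions(
        nm, labels, _db([("La|Lb", "R")]), n_perm=100, seed=0
    )
    # ligand unit = min(3, 1) = 1; score = (1 + 5)/2
    assert tbl["score"].iloc[0] == pytest.approx(3.0)


def test_score_symmetry_under_unit_and_cluster_swap():
    rng = np.random.default_rng(3)
    vals = rng.uniform(0.5, 3.0, size=(10, 2))
    nm = _nm_from_values(vals, ["L", "R"])
    labels = pd.Series(["a"] * 5 + ["b"] * 5, index=nm.obs_names)
    fwd = lr_interactome.score_interactions(nm, labels, _db([("L", "R")]),
                                            n_perm=50, seed=0)
    rev = lr_interactome.score_interactions(nm, labels, _db([("R", "L")]),
                                            n_perm=50, seed=0)
    s1 = fwd[(fwd.source == "a") & (fwd.target == "b")]["score"].iloc[0]
    s2 = rev[(rev.source == "b") & (rev.target == "a")]["score"].iloc[0]
    assert s1 == pytest.approx(s2)


def test_permutation_p_matches_exhaustive_enumeration():
    """6-cell toy: sampled permutation p ~ exact p over the 20 relabelings."""
    vals = np.array([[5.0], [4.0], [3.5], [0.5], [0.2], [0.1]])
    vals = np.hstack([vals, vals[::-1]])
    nm = _nm_from_values(vals, ["L", "R"])
    labels = pd.Series(["a", "a", "a", "b", "b", "b"], index=nm.obs_names)

    # exact: enumerate every assignment of 3 cells to cluster a
    lmean = vals[:, 0]
    rmean = vals[:, 1]
    obs = 0.5 * (lmean[:3].mean() + rmean[3:].mean())  # a -> b score
    cnt = 0
    combos = list(itertools.combinations(range(6), 3))
    for a_idx in combos:
        b_idx = [i for i in range(6) if i not in a_idx]
        s = 0.5 * (lmean[list(a_idx)].mean() + rmean[b_idx].mean())
        if s >= obs - 1e-12:
            cnt += 1
    exact_p = cnt / len(combos)

    tbl = lr_interactome.score_interactions(nm, labels, _db([("L", "R")]),
                                            n_perm=4000, seed=1)
    rec = tbl[(tbl.source == "a") & (tbl.target == "b")].iloc[0]
    assert rec["p"] == pytest.approx(exact_p, abs=0.02)


def test_raising_expression_threshold_never_adds_records():
    cfg, db = synthgen.lr_benchmark_config(seed=2, n_cells=600, n_pairs=40,
                                           n_planted=8)
    cells, truth = synthgen.simulate_cells(cfg)
    nm = sc_core.normalize_cp10k_log(cells)
    types = truth.cell_type_of_cell.loc[nm.obs_names]
    counts = []
    for frac in (0.05, 0.10, 0.25):
        tbl = lr_interactome.score_interactions(
            nm, types, db, min_expressed_frac=frac, n_perm=20, seed=0
        )
        counts.append(int((tbl["score"] > 0).sum()))
    assert counts[0] >= counts[1] >= counts[2]


def test_unmapped_genes_dropped_with_warning(toy_adata):
    labels = pd.Series(["a"] * 3 + ["b"] * 3, index=toy_adata.obs_names)
    with pytest.warns(UserWarning, match="unmapped"):
        tbl = lr_interactome.score_interactions(
            toy_adata, labels, _db([("g0", "nope"), ("g1", "g2")]),
            n_perm=100, seed=0,
        )
    assert set(tbl["pair_id"]) == {"p1"}


# ----------------------------------------------------------------------
# filtering / merging / differential
# ----------------------------------------------------------------------


def test_filter_drops_p_above_cutoff():
    tbl = pd.DataFrame(
        {"pair_id": ["p", "q", "r"], "source": "a", "target": "b",
         "score": [1.0, 1.0, 1.0], "p": [0.04, 0.05, 0.06], "n_perm": 100}
    )
    kept = lr_interactome.filter_significant(tbl)
    assert set(kept["pair_id"]) == {"p", "q"}  # 0.06 filtered, 0.05 kept


def test_merge_identity_and_max_rule():
    tbl = pd.DataFrame(
        {
            "pair_id": ["p", "p", "q"],
            "source": ["KC_0", "KC_1", "KC_0"],
            "target": ["FB_0", "FB_0", "FB_1"],
            "score": [1.2, 2.5, 0.7],
            "p": [0.01, 0.02, 0.03],
            "n_perm": 100,
        }
    )
    mapping = {"KC_0": "KC", "KC_1": "KC", "FB_0": "FB", "FB_1": "FB"}
    merged = lr_interactome.merge_to_celltype_pairs(tbl, mapping)
    rec = merged[merged.pair_id == "p"].iloc[0]
    assert rec["score"] == 2.5
    assert rec["source_subcluster"] == "KC_1"  # provenance of the winner
    # distinct keys equal the brute-force key set
    brute = {(r.pair_id, mapping[r.source], mapping[r.target]) for r in tbl.itertuples()}
    assert set(zip(merged.pair_id, merged.source, merged.target)) == brute


def test_merge_unmapped_cluster_errors():
    tbl = pd.DataFrame(
        {"pair_id": ["p"], "source": ["X_0"], "target": ["Y_0"],
         "score": [1.0], "p": [0.01], "n_perm": 100}
    )
    with pytest.raises(KeyError):
        lr_interactome.merge_to_celltype_pairs(tbl, {"X_0": "X"})


def test_differential_network_rules():
    pp = pd.DataFrame(
        {"pair_id": ["p", "q", "r"], "source": "KC", "target": "FB",
         "score": [3.0, 2.0, 1.5]}
    )
    ns = pd.DataFrame(
        {"pair_id": ["p", "q"], "source": "KC", "target": "FB",
         "score": [1.0, 2.0]}
    )
    diff, matrix = lr_interactome.differential_network(pp, ns)
    by_pair = diff.set_index("pair_id")
    assert by_pair.loc["p", "delta"] == pytest.approx(2.0)  # higher in PP
    assert "q" not in by_pair.index                         # equal: excluded
    assert by_pair.loc["r", "score_ns"] == 0.0              # absent-as-zero
    assert matrix.loc["KC", "FB"] == 2


def test_mixed_subclusters_enter_neither_run(atlas6_nm):
    nm, truth = atlas6_nm
    sub = truth.subcluster_of_cell.loc[nm.obs_names]
    cond = nm.obs["condition"]
    db = synthgen.null_lr_database(synthgen.atlas_config(seed=3, n_cells=2000),
                                   n_pairs=5)
    ns_tbl, pp_tbl, spec = lr_interactome.run_condition_specific(
        nm, sub, cond, db, n_perm=20, seed=0
    )
    mixed = set(spec.index[spec["class"] == "mixed"])
    used = set(ns_tbl.get("source", [])) | set(ns_tbl.get("target", [])) \
        | set(pp_tbl.get("source", [])) | set(pp_tbl.get("target", []))
    assert not (mixed & used)


def test_planted_pp_interaction_found_only_in_pp_table():
    cfg, db = synthgen.lr_benchmark_config(seed=4, n_cells=1200, n_pairs=30,
                                           n_planted=3)
    cells, truth = synthgen.simulate_cells(cfg)
    nm = sc_core.normalize_cp10k_log(cells)
    sub = truth.subcluster_of_cell.loc[nm.obs_names]
    ns_tbl, pp_tbl, _ = lr_interactome.run_condition_specific(
        nm, sub, nm.obs["condition"], db, n_perm=200, seed=0
    )
    dbi = db.set_index("pair_id")
    planted_ids = {
        dbi.index[dbi["ligand_members"] == p.ligand][0] for p in truth.planted_lr
    }
    assert planted_ids <= set(pp_tbl["pair_id"])
    assert not (planted_ids & set(ns_tbl["pair_id"]))
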