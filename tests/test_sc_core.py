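"""Preprocessing, composition, rank-sum DE and module-score contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from skinmap import sc_core, synthgen

from conftest import make_adata


# ----------------------------------------------------------------------
# QC
# ----------------------------------------------------------------------


def _qc_case_matrix():
    """Hand-built cells probing each QC boundary (200 genes, 10 mito)."""
    n_genes = 200
    genes = [f"MT-{i}" for i in range(10)] + [f"g{i}" for i in range(n_genes - 10)]
    rows = []

    def cell(total, n_expressed, mito_frac):
        x = np.zeros(n_genes)
        mito = int(round(total * mito_frac))
        x[0] = mito
        body = total - mito
        n_body = n_expressed - (1 if mito else 0)
        per = body // n_body
        x[10 : 10 + n_body] = per
        x[10] += body - per * n_body
        return x

    rows.append(cell(499, 150, 0.05))   # too few transcripts
    rows.append(cell(600, 150, 0.105))  # mito above the ceiling
    rows.append(cell(600, 150, 0.10))   # exactly at the ceiling: retained
    rows.append(cell(500, 150, 0.05))   # exactly at the floor: retained
    rows.append(cell(2000, 99, 0.0))    # too few genes
    rows.append(cell(2000, 100, 0.0))   # exactly enough genes
    return make_adata(np.array(rows), gene_names=genes)


def test_qc_filter_boundary_readings():
    adata = _qc_case_matrix()
    filtered, report = sc_core.qc_filter(adata)
    assert list(report["retained"]) == [False, False, True, True, False, True]
    assert filtered.n_vars == adata.n_vars  # gene set unchanged


def test_qc_filter_is_idempotent():
    cfg = synthgen.qc_benchmark_config(seed=5, n_cells=300)
    adata, _ = synthgen.simulate_cells(cfg)
    once, rep1 = sc_core.qc_filter(adata)
    twice, rep2 = sc_core.qc_filter(once)
    assert once.n_obs == twice.n_obs
    assert rep2["retained"].all()


def test_qc_unknown_mito_prefix_warns():
    adata = make_adata(np.full((3, 120), 10))
    with pytest.warns(UserWarning, match="mito"):
        _, report = sc_core.qc_filter(adata, mito_prefix="ZZ-")
    assert report["retained"].all()


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------


def test_normalize_closed_form_and_zero_preservation():
    x = np.zeros((1, 100))
    x[0, 0] = 10
    x[0, 1:] = (10000 - 10) / 99
    adata = make_adata(x)
    nm = sc_core.normalize_cp10k_log(adata)
    val = nm.X.toarray()
    assert val[0, 0] == pytest.approx(np.log(11), abs=1e-12)
    zeros = make_adata(np.array([[0, 5], [3, 0]]))
    nz = sc_core.normalize_cp10k_log(zeros).X.toarray()
    assert nz[0, 0] == 0.0 and nz[1, 1] == 0.0


def test_normalize_depth_invariance():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 30, size=(4, 50))
    counts[counts.sum(axis=1) == 0, 0] = 1
    a = sc_core.normalize_cp10k_log(make_adata(counts)).X.toarray()
    b = sc_core.normalize_cp10k_log(make_adata(2 * counts)).X.toarray()
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_normalize_rejects_zero_total_cells():
    with pytest.raises(ValueError, match="qc_filter"):
        sc_core.normalize_cp10k_log(make_adata(np.zeros((2, 5))))


# ----------------------------------------------------------------------
# variable genes
# ----------------------------------------------------------------------


def test_variable_genes_pick_only_varying_genes():
    rng = np.random.default_rng(2)
    values = np.full((40, 50), np.log1p(5.0))  # already-normalized scale
    varying = rng.choice(50, 10, replace=False)
    values[:, varying] = np.log1p(rng.integers(0, 60, size=(40, 10)))
    nm = make_adata(np.zeros_like(values))
    nm.X = values
    top = sc_core.select_variable_genes(nm, n_top=10)
    assert set(top) == {f"g{i}" for i in varying}
    assert len(sc_core.select_variable_genes(nm, n_top=50)) == 50


def test_variable_genes_enrich_planted_markers(atlas6_nm):
    nm, truth = atlas6_nm
    hvg = set(sc_core.select_variable_genes(nm, n_top=500))
    markers = {g for gs in truth.marker_genes.values() for g in gs}
    k = len(hvg & markers)
    p = stats.hypergeom.sf(k - 1, nm.n_vars, len(markers), 500)
    assert p < 0.01


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------


def test_cluster_cells_separates_two_types_and_is_deterministic():
    from sklearn.metrics import adjusted_rand_score

    cfg = synthgen.atlas_config(seed=8, n_cells=400, n_types=2)
    adata, truth = synthgen.simulate_cells(cfg)
    nm = sc_core.normalize_cp10k_log(adata)
    hvg = sc_core.select_variable_genes(nm, n_top=300)
    lab1 = sc_core.cluster_cells(nm, hvg, seed=0)
    lab2 = sc_core.cluster_cells(nm, hvg, seed=0)
    assert lab1.equals(lab2)
    assert adjusted_rand_score(truth.cell_type_of_cell.loc[nm.obs_names], lab1) == 1.0


# ----------------------------------------------------------------------
# composition
# ----------------------------------------------------------------------


def test_composition_hand_arithmetic():
    labels = pd.Series(["X", "X", "Y", "Y", "X", "Y"], index=list("abcdef"))
    cond = pd.Series(["NS", "NS", "NS", "NS", "PP", "PP"], index=list("abcdef"))
    tbl = sc_core.composition_table(labels, cond)
    # X: 2/4 NS vs 1/2 PP -> equal shares
    assert tbl.loc["X", "NS"] == pytest.approx(50.0)
    assert tbl.loc["X", "PP"] == pytest.approx(50.0)


def test_composition_exclusive_type():
    labels = pd.Series(["A", "B", "B", "B"], index=list("abcd"))
    cond = pd.Series(["PP", "NS", "PN", "PP"], index=list("abcd"))
    tbl = sc_core.composition_table(labels, cond)
    assert tbl.loc["A", "PP"] == pytest.approx(100.0)
    assert tbl.loc["A", ["NS", "PN"]].sum() == pytest.approx(0.0)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.sampled_from(["T", "B", "K"]), min_size=6, max_size=40),
       st.randoms(use_true_random=False))
def test_composition_rows_sum_to_100(labs, rnd):
    conds = [rnd.choice(["NS", "PN", "PP"]) for _ in labs]
    idx = [f"c{i}" for i in range(len(labs))]
    tbl = sc_core.composition_table(pd.Series(labs, index=idx), pd.Series(conds, index=idx))
    np.testing.assert_allclose(tbl.sum(axis=1), 100.0, atol=1e-6)


# ----------------------------------------------------------------------
# Wilcoxon DE
# ----------------------------------------------------------------------


def test_wilcoxon_exact_small_sample_and_symmetry():
    adata = make_adata(np.array([[1], [2], [3], [4], [5], [6]], dtype=float))
    adata.X = adata.X.toarray()  # treat values as already normalized
    de_ab = sc_core.wilcoxon_de(adata, [0, 1, 2], [3, 4, 5])
    assert de_ab["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)
    de_ba = sc_core.wilcoxon_de(adata, [3, 4, 5], [0, 1, 2])
    assert de_ba["p"].iloc[0] == pytest.approx(de_ab["p"].iloc[0])
    assert de_ba["log_fc"].iloc[0] == pytest.approx(-de_ab["log_fc"].iloc[0])


def test_wilcoxon_constant_gene_p_one(toy_adata):
    X = toy_adata.X.toarray()
    X[:, 0] = 7.0
    adata = make_adata(X)
    de = sc_core.wilcoxon_de(adata, [0, 1, 2], [3, 4, 5])
    assert de["p"].iloc[0] == 1.0


def test_wilcoxon_rejects_overlapping_groups(toy_adata):
    with pytest.raises(ValueError, match="overlap"):
        sc_core.wilcoxon_de(toy_adata, [0, 1], [1, 2])


def test_wilcoxon_null_pvalues_uniform(atlas6_nm):
    """Permuted labels give uniform p-values (KS check at 2,000 genes)."""
    nm, _ = atlas6_nm
    rng = np.random.default_rng(0)
    idx = rng.permutation(nm.n_obs)
    de = sc_core.wilcoxon_de(nm, idx[:400], idx[400:800])
    assert stats.kstest(de["p"], "uniform").pvalue > 0.01


# ----------------------------------------------------------------------
# module score
# ----------------------------------------------------------------------


def brute_force_module_score(nm, gene_set, n_bins, n_ctrl, seed):
    """Independent loop-based coding of the bin/sample/subtract recipe."""
    X = nm.X.toarray() if hasattr(nm.X, "toarray") else np.asarray(nm.X)
    genes = list(nm.var_names)
    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="mergesort")
    bin_of = {}
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        for gi in chunk:
            bin_of[gi] = b
    rng = np.random.default_rng(seed)
    targets, ctrl = [], []
    for g in gene_set:
        if g not in genes:
            continue
        gi = genes.index(g)
        targets.append(gi)
        members = [j for j in range(len(genes)) if bin_of[j] == bin_of[gi]]
        ctrl.extend(rng.choice(members, size=n_ctrl, replace=len(members) < n_ctrl))
    scores = []
    for c in range(X.shape[0]):
        t = np.mean([X[c, gi] for gi in targets])
        k = np.mean([X[c, gi] for gi in ctrl])
        scores.append(t - k)
    return np.array(scores)


def test_module_score_matches_brute_force_oracle():
    rng = np.random.default_rng(4)
    counts = rng.integers(0, 25, size=(50, 30))
    counts[counts.sum(axis=1) == 0, 0] = 1
    nm = sc_core.normalize_cp10k_log(make_adata(counts))
    gs = ["g2", "g7", "g11", "g25"]
    mine = sc_core.module_score(nm, gs, n_bins=5, n_ctrl=10, seed=9)
    oracle = brute_force_module_score(nm, gs, n_bins=5, n_ctrl=10, seed=9)
    np.testing.assert_allclose(mine, oracle, atol=1e-12)


def test_module_score_constant_matrix_is_zero():
    nm = make_adata(np.full((10, 40), 3.0))
    scores = sc_core.module_score(nm, ["g0", "g5"], n_bins=4, n_ctrl=5, seed=0)
    np.testing.assert_allclose(scores, 0.0, atol=1e-12)


def test_module_score_separates_expressing_cells():
    X = np.zeros((20, 60))
    X[:10, :5] = 5.0  # gene-set genes on only in the first 10 cells
    nm = make_adata(X)
    scores = sc_core.module_score(nm, [f"g{i}" for i in range(5)], seed=0)
    assert scores[:10].min() > scores[10:].max()


def test_module_score_random_set_centered(atlas6_nm):
    nm, _ = atlas6_nm
    rng = np.random.default_rng(12)
    means = []
    for s in range(3):
        gs = list(rng.choice(nm.var_names, 50, replace=False))
        means.append(sc_core.module_score(nm, gs, seed=s).mean())
    assert np.all(np.abs(means) < 0.05)


def test_module_score_missing_genes():
    nm = make_adata(np.ones((5, 30)))
    with pytest.warns(UserWarning, match="absent"):
        sc_core.module_score(nm, ["g1", "nope"], seed=0)
    with pytest.raises(ValueError):
        sc_core.module_score(nm, ["nope"], seed=0)


# ----------------------------------------------------------------------
# group means
# ----------------------------------------------------------------------


def test_group_mean_expression_low_expression_filter():
    X = np.zeros((4, 3))
    X[0, 1] = 0.08  # mean 0.02 in group A only -> retained
    nm = make_adata(X)
    nm.X = X
    labels = pd.Series(["A", "A", "A", "A"], index=nm.obs_names)
    means = sc_core.group_mean_expression(nm, labels)
    assert "g0" not in means.index  # all-zero gene dropped
    assert means.loc["g1", "A"] == pytest.approx(0.02)


def test_group_mean_expression_single_group_identity():
    rng = np.random.default_rng(3)
    X = rng.uniform(0.5, 2.0, size=(6, 4))
    nm = make_adata(X)
    nm.X = X
    labels = pd.Series(["only"] * 6, index=nm.obs_names)
    means = sc_core.group_mean_expression(nm, labels)
    np.testing.assert_allclose(means["only"].to_numpy(), X.mean(axis=0))
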