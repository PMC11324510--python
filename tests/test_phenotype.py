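import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st
from scipy.stats import ranksums

from editscope.phenotype import (
    CLASS_SIGNIFICANT,
    CLASS_WT_LIKE,
    EmptyMatrixError,
    ExpressionMatrix,
    IntegrateParams,
    JoinError,
    bh_adjust,
    classify_variants,
    cluster_cells,
    cluster_proportions,
    dge_rank_sum,
    integrate,
    module_score,
    normalize,
    qc_filter,
    score_test,
)


def make_matrix(counts, genes=None, barcodes=None):
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"BC{i:04d}" for i in range(counts.shape[1])]
    return ExpressionMatrix(
        np.array(genes, dtype=object),
        np.array(barcodes, dtype=object),
        sp.csr_matrix(counts),
    )


# ------------------------------------------------------------------ QC


def rich_matrix(rng, n_genes=150, n_cells=30):
    return make_matrix(rng.poisson(5, size=(n_genes, n_cells)))


def test_qc_removes_cell_with_99_genes():
    rng = np.random.default_rng(0)
    m = rich_matrix(rng)
    counts = np.asarray(m.X.todense())
    counts[:, 0] = 0
    counts[:99, 0] = 1  # exactly 99 detected genes -> removed
    m = make_matrix(counts, genes=list(m.genes), barcodes=list(m.barcodes))
    filtered, report = qc_filter(m, min_cells_per_gene=1)
    assert "BC0000" not in filtered.barcodes
    assert report["cells_removed_low_genes"] == 1


def test_qc_cell_with_100_genes_kept():
    rng = np.random.default_rng(0)
    m = rich_matrix(rng)
    counts = np.asarray(m.X.todense())
    counts[:, 0] = 0
    counts[:100, 0] = 1
    m = make_matrix(counts, genes=list(m.genes), barcodes=list(m.barcodes))
    filtered, _ = qc_filter(m, min_cells_per_gene=1)
    assert "BC0000" in filtered.barcodes


def test_qc_gene_in_three_cells_removed():
    rng = np.random.default_rng(1)
    m = rich_matrix(rng)
    counts = np.asarray(m.X.todense())
    counts[0, :] = 0
    counts[0, :3] = 7  # present in exactly 3 cells -> removed at default 4
    m2 = make_matrix(counts, genes=list(m.genes), barcodes=list(m.barcodes))
    filtered, report = qc_filter(m2)
    assert "G0" not in filtered.genes
    assert report["genes_removed_low_cells"] >= 1


def test_qc_mito_fraction():
    rng = np.random.default_rng(2)
    counts = rng.poisson(5, size=(150, 10))
    genes = [f"MT-{i}" if i < 5 else f"G{i}" for i in range(150)]
    counts[:5, 0] = 1000  # cell 0 dominated by mitochondrial counts
    m = make_matrix(counts, genes=genes)
    filtered, report = qc_filter(m, min_cells_per_gene=1)
    assert "BC0000" not in filtered.barcodes
    assert report["cells_removed_mito"] == 1


def test_qc_all_pass_unchanged():
    rng = np.random.default_rng(3)
    m = rich_matrix(rng)
    filtered, _ = qc_filter(m, min_cells_per_gene=1)
    assert filtered.n_cells == m.n_cells and filtered.n_genes == m.n_genes


def test_qc_empty_result_raises():
    m = make_matrix(np.ones((5, 3)))
    with pytest.raises(EmptyMatrixError):
        qc_filter(m)  # every cell has only 5 detected genes


# ------------------------------------------------------------------ normalize


def test_normalize_zero_cell_stays_zero():
    m = make_matrix(np.array([[0, 5], [0, 5]]))
    n = normalize(m)
    assert np.asarray(n.X.todense())[:, 0].sum() == 0


def test_normalize_scale_invariance():
    base = np.array([[1, 2], [3, 6], [0, 0], [4, 8]], dtype=float)
    n = normalize(make_matrix(base))
    X = np.asarray(n.X.todense())
    assert np.allclose(X[:, 0], X[:, 1])


def test_normalize_closed_form():
    c = np.array([[1.0, 3.0], [4.0, 2.0]])
    n = normalize(make_matrix(c))
    X = np.asarray(n.X.todense())
    expected = np.log1p(1e4 * c / c.sum(axis=0, keepdims=True))
    assert np.allclose(X, expected)


# ------------------------------------------------------------------ clustering


def two_blob_matrix(rng, n_per=40, n_genes=60):
    a = rng.poisson(2, size=(n_genes, n_per))
    b = rng.poisson(2, size=(n_genes, n_per))
    b[:20] += rng.poisson(20, size=(20, n_per))  # strong shift in 20 genes
    return make_matrix(np.hstack([a, b])), np.array([0] * n_per + [1] * n_per)


def test_cluster_two_blobs_ari_one():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(5)
    m, truth = two_blob_matrix(rng)
    labels = cluster_cells(normalize(m), k=2, seed=0)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_cluster_k1_and_determinism():
    rng = np.random.default_rng(6)
    m, _ = two_blob_matrix(rng)
    n = normalize(m)
    assert set(cluster_cells(n, k=1, seed=0)) == {0}
    l1 = cluster_cells(n, k=4, seed=3)
    l2 = cluster_cells(n, k=4, seed=3)
    assert np.array_equal(l1, l2)


def test_cluster_k_exceeds_cells():
    m = make_matrix(np.ones((10, 4)))
    with pytest.raises(ValueError):
        cluster_cells(normalize(m), k=5)


# ------------------------------------------------------------------ module score


def test_module_score_self_control_near_zero():
    rng = np.random.default_rng(7)
    m = normalize(make_matrix(rng.poisson(5, size=(400, 300))))
    scores, report = module_score(m, [f"G{i}" for i in range(0, 40)], seed=0)
    se = scores.std(ddof=1) / np.sqrt(len(scores))
    assert abs(scores.mean()) < 3 * se + 1e-9


def test_module_score_detects_planted_shift():
    rng = np.random.default_rng(8)
    counts = rng.poisson(5, size=(400, 500))
    counts[:40, 250:] += rng.poisson(6, size=(40, 250))
    m = normalize(make_matrix(counts))
    scores, _ = module_score(m, [f"G{i}" for i in range(40)], seed=0)
    p = ranksums(scores[250:], scores[:250]).pvalue
    assert scores[250:].mean() > scores[:250].mean()
    assert p < 1e-6


def test_module_score_deterministic_and_reports_missing():
    rng = np.random.default_rng(9)
    m = normalize(make_matrix(rng.poisson(5, size=(200, 50))))
    gene_set = ["G0", "G1", "NOT_A_GENE"]
    s1, rep1 = module_score(m, gene_set, seed=42)
    s2, rep2 = module_score(m, gene_set, seed=42)
    assert np.array_equal(s1, s2)
    assert rep1["missing_genes"] == ["NOT_A_GENE"]
    with pytest.raises(ValueError):
        module_score(m, ["NOPE"], seed=0)


# ------------------------------------------------------------------ proportions


def geno_frame(labels_per_cell):
    return pd.DataFrame(
        {
            "cb": [f"BC{i:04d}" for i in range(len(labels_per_cell))],
            "genotype_label": labels_per_cell,
        }
    )


def test_cluster_proportions_min_cells_filter():
    genos = geno_frame(["WT"] * 10 + ["V2M"] * 4)
    labels = pd.Series(
        [0] * 14, index=[f"BC{i:04d}" for i in range(14)]
    )
    prop = cluster_proportions(genos, labels, min_cells=5)
    assert "WT" in prop.index and "V2M" not in prop.index


def test_cluster_proportions_one_hot():
    genos = geno_frame(["WT"] * 6)
    labels = pd.Series([2] * 6, index=[f"BC{i:04d}" for i in range(6)])
    prop = cluster_proportions(genos, labels)
    assert prop.loc["WT", 2] == 1.0


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10**6))
def test_cluster_proportions_rows_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 60))
    labels_per_cell = rng.choice(["WT", "A", "B"], size=n)
    clusters = rng.integers(0, 4, size=n)
    genos = geno_frame(list(labels_per_cell))
    labels = pd.Series(clusters, index=genos["cb"].to_numpy())
    prop = cluster_proportions(genos, labels, min_cells=1)
    assert np.allclose(prop.sum(axis=1), 1.0, atol=1e-9)


# ------------------------------------------------------------------ classify


def brute_force_complete_linkage(X, k):
    """Naive agglomerative oracle: recompute all merges with complete
    linkage until k clusters remain."""
    clusters = [[i] for i in range(len(X))]

    def dist(c1, c2):
        return max(
            np.linalg.norm(X[i] - X[j]) for i in c1 for j in c2
        )

    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = dist(clusters[a], clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(X), dtype=int)
    for ci, members in enumerate(clusters):
        for i in members:
            labels[i] = ci
    return labels


def test_classify_identical_to_wt_is_wt_like():
    prop = pd.DataFrame(
        [[0.5, 0.5], [0.5, 0.5], [0.0, 1.0]],
        index=["WT", "same", "far"],
        columns=[0, 1],
    )
    classes, _ = classify_variants(prop)
    assert classes["WT"] == CLASS_WT_LIKE
    assert classes["same"] == CLASS_WT_LIKE
    assert classes["far"] == CLASS_SIGNIFICANT


def test_classify_one_hot_groups():
    rows = {"WT": [1, 0], "a": [1, 0], "b": [0, 1], "c": [0, 1]}
    prop = pd.DataFrame.from_dict(rows, orient="index")
    classes, _ = classify_variants(prop)
    assert classes["a"] == CLASS_WT_LIKE
    assert classes["b"] == CLASS_SIGNIFICANT
    assert classes["c"] == CLASS_SIGNIFICANT


def test_classify_matches_bruteforce_oracle():
    rng = np.random.default_rng(10)
    for _ in range(10):
        X = rng.random((8, 4))
        X = X / X.sum(axis=1, keepdims=True)
        prop = pd.DataFrame(X, index=["WT"] + [f"v{i}" for i in range(7)])
        classes, _ = classify_variants(prop, k_cut=2)
        oracle = brute_force_complete_linkage(X, 2)
        wt_grp = oracle[0]
        expected = [
            CLASS_WT_LIKE if g == wt_grp else CLASS_SIGNIFICANT for g in oracle
        ]
        assert list(classes) == expected


def test_classify_missing_wt_raises():
    prop = pd.DataFrame([[1.0, 0.0]], index=["v1"])
    with pytest.raises(ValueError):
        classify_variants(prop)


def test_classify_single_wt_row():
    prop = pd.DataFrame([[1.0]], index=["WT"])
    classes, _ = classify_variants(prop)
    assert classes["WT"] == CLASS_WT_LIKE


# ------------------------------------------------------------------ stats


def test_score_test_identical_samples():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    t, p = score_test(x, x)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_score_test_welch_closed_form():
    a = np.array([1.1, 2.3, 2.9, 3.8, 4.4])
    b = np.array([2.0, 2.5, 3.6, 5.1, 5.9, 6.3])
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    t_expected = (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    from scipy.stats import t as tdist

    p_expected = 2 * tdist.sf(abs(t_expected), df)
    t, p = score_test(a, b)
    assert t == pytest.approx(t_expected, abs=1e-10)
    assert p == pytest.approx(p_expected, abs=1e-10)


def test_score_test_antisymmetry():
    rng = np.random.default_rng(11)
    a, b = rng.normal(0, 1, 30), rng.normal(0.5, 2, 40)
    t1, p1 = score_test(a, b)
    t2, p2 = score_test(b, a)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


def test_bh_adjust_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.8, 0.9])
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-12)
    assert np.all(q <= 1.0)
    assert q[0] == pytest.approx(0.005)


# ------------------------------------------------------------------ DGE


def test_dge_null_is_calibrated():
    rng = np.random.default_rng(12)
    m = normalize(make_matrix(rng.poisson(5, size=(200, 120))))
    res = dge_rank_sum(m, list(range(60)), list(range(60, 120)))
    assert (res["q"] < 0.05).sum() <= max(3, 0.05 * len(res))


def test_dge_recovers_planted_genes():
    rng = np.random.default_rng(13)
    counts = rng.poisson(5, size=(300, 400))
    planted = list(range(50))
    counts[planted, :200] *= 2
    m = normalize(make_matrix(counts))
    res = dge_rank_sum(m, list(range(200)), list(range(200, 400)))
    top100 = set(res.head(100)["gene"])
    hits = sum(f"G{i}" in top100 for i in planted)
    assert hits >= 45  # >=90% of planted genes in the top 100
    lfc = res.set_index("gene").loc["G0", "lfc"]
    assert lfc > 0.5


def test_dge_rank_invariance_under_monotone_transform():
    rng = np.random.default_rng(14)
    counts = rng.poisson(4, size=(50, 60))
    m = normalize(make_matrix(counts))
    res1 = dge_rank_sum(m, list(range(30)), list(range(30, 60)))
    m2 = ExpressionMatrix(m.genes, m.barcodes, m.X.power(3))  # monotone
    res2 = dge_rank_sum(m2, list(range(30)), list(range(30, 60)))
    merged = res1.merge(res2, on="gene", suffixes=("_1", "_2"))
    assert np.allclose(merged["p_1"], merged["p_2"])


# ------------------------------------------------------------------ integrate


def integration_inputs(rng, n_per=60, effect=0.3):
    from editscope.simulate import SimConfig, simulate_expression

    cells = []
    for label, eff in [("WT", 1.0), ("NULLV", 1.0), ("DOWNV", effect)]:
        for i in range(n_per):
            cells.append({"cb": f"{label}{i:04d}" + "A" * (16 - len(label) - 4),
                          "genotype_label": label, "effect": eff})
    truth = pd.DataFrame(cells)
    cfg = SimConfig(seed=int(rng.integers(1e6)), n_cells=len(truth))
    expr = simulate_expression(cfg, truth)
    geno = truth[["cb", "genotype_label"]].copy()
    geno["zygosity"] = "homozygous"
    return geno, expr


def test_integrate_classifies_planted_effects():
    rng = np.random.default_rng(15)
    geno, expr = integration_inputs(rng)
    variant_table, per_cell, report = integrate(
        geno, expr.matrix, expr.gene_set, IntegrateParams(k=6, seed=0)
    )
    classes = variant_table.set_index("genotype_label")["class"]
    assert classes["WT"] == CLASS_WT_LIKE
    assert classes["NULLV"] == CLASS_WT_LIKE
    assert classes["DOWNV"] == CLASS_SIGNIFICANT
    p_down = variant_table.set_index("genotype_label").loc["DOWNV", "p"]
    assert p_down < 1e-6
    assert variant_table["n_cells"].min() >= 5


def test_integrate_no_overlap_raises():
    rng = np.random.default_rng(16)
    geno, expr = integration_inputs(rng)
    geno["cb"] = "T" * 16
    with pytest.raises(JoinError):
        integrate(geno.head(3), expr.matrix, expr.gene_set)


def test_integrate_wt_only():
    rng = np.random.default_rng(17)
    geno, expr = integration_inputs(rng)
    wt_only = geno[geno.genotype_label == "WT"]
    keep = wt_only["cb"].tolist()
    idx = [i for i, b in enumerate(expr.matrix.barcodes) if b.split("-")[0] in keep]
    sub = expr.matrix.subset(cell_idx=np.array(idx))
    variant_table, _, _ = integrate(
        wt_only, sub, expr.gene_set, IntegrateParams(k=3, seed=0)
    )
    assert list(variant_table["genotype_label"]) == ["WT"]
    assert np.isnan(variant_table.iloc[0]["p"])


def test_integrate_deterministic():
    rng = np.random.default_rng(18)
    geno, expr = integration_inputs(rng)
    t1, c1, _ = integrate(geno, expr.matrix, expr.gene_set, IntegrateParams(seed=5))
    t2, c2, _ = integrate(geno, expr.matrix, expr.gene_set, IntegrateParams(seed=5))
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(c1, c2)


# ------------------------------------------------------------------ MTX IO


def test_mtx_round_trip(tmp_path):
    rng = np.random.default_rng(19)
    m = make_matrix(rng.poisson(1, size=(20, 10)))
    m.write_mtx_dir(tmp_path / "mtx")
    back = ExpressionMatrix.from_mtx_dir(tmp_path / "mtx")
    assert np.array_equal(
        np.asarray(back.X.todense()), np.asarray(m.X.todense())
    )
    assert list(back.genes) == list(m.genes)
    assert list(back.barcodes) == list(m.barcodes)
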