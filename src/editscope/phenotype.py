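"""Genotype-transcriptome integration and variant classification.

Takes per-cell genotypes plus a sparse counts matrix, computes QC-filtered
normalized expression, cluster labels (built-in PCA+k-means or precomputed),
pathway module scores, per-variant cluster-proportion profiles and a
hierarchical wild-type-like vs functionally-significant classification.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu, ttest_ind

WT_LABEL = "WT"
CLASS_WT_LIKE = "wild-type-like"
CLASS_SIGNIFICANT = "functionally-significant"


class JoinError(ValueError):
    """No barcode overlap between genotype table and expression matrix."""


class EmptyMatrixError(ValueError):
    """QC filtering removed every cell or gene."""


def strip_suffix(barcode: str) -> str:
    return barcode.split("-")[0]


@dataclass
class ExpressionMatrix:
    """Genes x cells raw (or normalized) counts with identifiers."""

    genes: np.ndarray
    barcodes: np.ndarray
    X: sp.csr_matrix

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("matrix shape does not match gene/barcode lists")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("cell barcodes must be unique")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def subset(self, gene_idx=None, cell_idx=None) -> "ExpressionMatrix":
        X = self.X
        genes, barcodes = self.genes, self.barcodes
        if gene_idx is not None:
            X = X[gene_idx]
            genes = genes[gene_idx]
        if cell_idx is not None:
            X = X[:, cell_idx]
            barcodes = barcodes[cell_idx]
        return ExpressionMatrix(genes, barcodes, sp.csr_matrix(X))

    @classmethod
    def from_mtx_dir(cls, path) -> "ExpressionMatrix":
        """Read a MatrixMarket triplet dir (matrix.mtx, features.tsv,
        barcodes.tsv; optionally gzipped)."""
        import os

        def find(stem):
            for suff in ("", ".gz"):
                p = os.path.join(str(path), stem + suff)
                if os.path.exists(p):
                    return p
            raise FileNotFoundError(f"{stem}[.gz] not found in {path}")

        def opener(p):
            return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

        with opener(find("matrix.mtx")) as fh:
            X = sp.csr_matrix(scipy.io.mmread(fh))
        with opener(find("features.tsv")) as fh:
            genes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        with opener(find("barcodes.tsv")) as fh:
            barcodes = [line.strip() for line in fh if line.strip()]
        return cls(np.array(genes, dtype=object), np.array(barcodes, dtype=object), X)

    def write_mtx_dir(self, path) -> None:
        import os

        os.makedirs(str(path), exist_ok=True)
        coo = self.X.tocoo()
        order = np.lexsort((coo.row, coo.col))
        with open(os.path.join(str(path), "matrix.mtx"), "w") as fh:
            fh.write("%%MatrixMarket matrix coordinate integer general\n")
            fh.write(f"{self.X.shape[0]} {self.X.shape[1]} {coo.nnz}\n")
            for i in order:
                fh.write(f"{coo.row[i] + 1} {coo.col[i] + 1} {int(coo.data[i])}\n")
        with open(os.path.join(str(path), "features.tsv"), "w") as fh:
            for g in self.genes:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with open(os.path.join(str(path), "barcodes.tsv"), "w") as fh:
            for b in self.barcodes:
                fh.write(f"{b}\n")


def qc_filter(
    m: ExpressionMatrix,
    min_genes: int = 100,
    max_genes: int = 8000,
    max_mito_frac: float = 0.30,
    min_cells_per_gene: int = 4,
    mito_prefix: str = "MT-",
) -> Tuple[ExpressionMatrix, dict]:
    """Remove low/high-complexity and high-mitochondrial cells, then genes
    detected in fewer than ``min_cells_per_gene`` cells (cells first)."""
    X = m.X
    genes_per_cell = np.asarray((X > 0).sum(axis=0)).ravel()
    totals = np.asarray(X.sum(axis=0)).ravel()
    is_mito = np.array([g.startswith(mito_prefix) for g in m.genes])
    mito_counts = (
        np.asarray(X[is_mito].sum(axis=0)).ravel() if is_mito.any() else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    low = genes_per_cell < min_genes
    high = genes_per_cell > max_genes
    mito_bad = mito_frac > max_mito_frac
    keep_cells = ~(low | high | mito_bad)
    m2 = m.subset(cell_idx=np.where(keep_cells)[0])
    cells_per_gene = np.asarray((m2.X > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    m3 = m2.subset(gene_idx=np.where(keep_genes)[0])
    report = {
        "cells_in": m.n_cells,
        "cells_removed_low_genes": int(low.sum()),
        "cells_removed_high_genes": int(high.sum()),
        "cells_removed_mito": int((mito_bad & ~(low | high)).sum()),
        "cells_kept": m3.n_cells,
        "genes_in": m.n_genes,
        "genes_removed_low_cells": int((~keep_genes).sum()),
        "genes_kept": m3.n_genes,
    }
    if m3.n_cells == 0 or m3.n_genes == 0:
        raise EmptyMatrixError(f"QC filtering left an empty matrix: {report}")
    return m3, report


def normalize(m: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization to ``target_sum`` per cell, then log1p."""
    X = sp.csc_matrix(m.X, dtype=float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    X = X @ sp.diags(scale)
    X.data = np.log1p(X.data)
    return ExpressionMatrix(m.genes.copy(), m.barcodes.copy(), sp.csr_matrix(X))


def _gene_stats(m: ExpressionMatrix) -> Tuple[np.ndarray, np.ndarray]:
    X = m.X
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    return mean, var


def cluster_cells(
    m_norm: ExpressionMatrix,
    n_hvg: int = 2000,
    n_pcs: int = 20,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Top-variance genes -> PCA -> k-means; deterministic for a fixed seed."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if k > m_norm.n_cells:
        raise ValueError(f"k={k} exceeds number of cells ({m_norm.n_cells})")
    if k == 1:
        return np.zeros(m_norm.n_cells, dtype=int)
    _, var = _gene_stats(m_norm)
    n_hvg = min(n_hvg, m_norm.n_genes)
    hvg = np.sort(np.argsort(var)[::-1][:n_hvg])
    dense = np.asarray(m_norm.X[hvg].todense()).T  # cells x genes
    n_comp = min(n_pcs, dense.shape[0] - 1, dense.shape[1])
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(
        dense
    )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(pcs)


def module_score(
    m_norm: ExpressionMatrix,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> Tuple[np.ndarray, dict]:
    """Expression-matched control-subtracted mean score per cell.

    Genes are binned by mean expression; each set gene contributes controls
    sampled (seeded, without replacement) from its bin, excluding set genes.
    Returns ``(scores, report)``; ``report`` lists gene-set members missing
    from the matrix.
    """
    gene_index = {g: i for i, g in enumerate(m_norm.genes)}
    present = [g for g in gene_set if g in gene_index]
    missing = [g for g in gene_set if g not in gene_index]
    if not present:
        raise ValueError("gene set has no overlap with the expression matrix")
    set_idx = np.array(sorted(gene_index[g] for g in present))
    mean, _ = _gene_stats(m_norm)
    order = np.argsort(mean, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    bins = (ranks * n_bins) // max(len(order), 1)

    rng = np.random.default_rng(seed)
    in_set = np.zeros(m_norm.n_genes, dtype=bool)
    in_set[set_idx] = True
    ctrl_idx: List[int] = []
    for b in np.unique(bins[set_idx]):
        n_here = int((bins[set_idx] == b).sum())
        pool = np.where((bins == b) & ~in_set)[0]
        want = min(n_ctrl * n_here, len(pool))
        if want > 0:
            ctrl_idx.extend(rng.choice(pool, size=want, replace=False))
    ctrl_idx = np.array(sorted(set(ctrl_idx)))
    set_mean = np.asarray(m_norm.X[set_idx].mean(axis=0)).ravel()
    if len(ctrl_idx):
        ctrl_mean = np.asarray(m_norm.X[ctrl_idx].mean(axis=0)).ravel()
    else:  # degenerate toy matrices: no control pool at all
        ctrl_mean = np.zeros_like(set_mean)
    report = {"n_set_genes": len(present), "missing_genes": missing, "n_ctrl_genes": len(ctrl_idx)}
    return set_mean - ctrl_mean, report


def cluster_proportions(
    cell_genotypes: pd.DataFrame,
    labels: pd.Series,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Variant x cluster proportion matrix; variants with fewer than
    ``min_cells`` genotyped cells are dropped.  Rows sum to one."""
    df = cell_genotypes[["cb", "genotype_label"]].copy()
    df["cluster"] = df["cb"].map(labels)
    df = df.dropna(subset=["cluster"])
    counts = df.groupby(["genotype_label", "cluster"]).size().unstack(fill_value=0)
    counts = counts.loc[counts.sum(axis=1) >= min_cells]
    if counts.empty:
        return counts.astype(float)
    return counts.div(counts.sum(axis=1), axis=0)


def classify_variants(
    prop: pd.DataFrame,
    wt_row: str = WT_LABEL,
    k_cut: int = 2,
    linkage_method: str = "complete",
    metric: str = "euclidean",
) -> Tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of proportion rows; variants grouped with the
    wild-type row are wild-type-like, the rest functionally significant."""
    if wt_row not in prop.index:
        raise ValueError(f"proportion matrix has no {wt_row!r} row")
    if len(prop) == 1:
        return pd.Series([CLASS_WT_LIKE], index=prop.index, name="class"), np.empty((0, 4))
    Z = linkage(prop.to_numpy(float), method=linkage_method, metric=metric)
    groups = fcluster(Z, t=min(k_cut, len(prop)), criterion="maxclust")
    wt_group = groups[prop.index.get_loc(wt_row)]
    classes = pd.Series(
        np.where(groups == wt_group, CLASS_WT_LIKE, CLASS_SIGNIFICANT),
        index=prop.index,
        name="class",
    )
    return classes, Z


def score_test(scores_variant, scores_wt) -> Tuple[float, float]:
    """Welch two-sided t-test of variant vs wild-type module scores."""
    res = ttest_ind(scores_variant, scores_wt, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def dge_rank_sum(
    m_norm: ExpressionMatrix,
    cells_a: Sequence[int],
    cells_b: Sequence[int],
    min_frac: float = 0.1,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DGE between two cell index groups.

    Genes expressed in at least ``min_frac`` of either group are tested;
    BH correction is applied across tested genes; output is sorted by p-value
    then descending absolute log2 fold change.
    """
    A = np.asarray(m_norm.X[:, cells_a].todense())
    B = np.asarray(m_norm.X[:, cells_b].todense())
    frac_a = (A > 0).mean(axis=1)
    frac_b = (B > 0).mean(axis=1)
    tested = np.where((frac_a >= min_frac) | (frac_b >= min_frac))[0]
    rows = []
    for gi in tested:
        x, y = A[gi], B[gi]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stat, p = 0.0, 1.0
        else:
            res = mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        ma = np.expm1(x).mean()
        mb = np.expm1(y).mean()
        lfc = float(np.log2((ma + 1e-9) / (mb + 1e-9)))
        rows.append({"gene": m_norm.genes[gi], "statistic": stat, "p": p, "lfc": lfc})
    df = pd.DataFrame(rows, columns=["gene", "statistic", "p", "lfc"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(
            ["p", "lfc"], key=lambda s: s if s.name == "p" else -s.abs()
        ).reset_index(drop=True)
    else:
        df["q"] = []
    return df


@dataclass
class IntegrateParams:
    min_genes: int = 100
    max_genes: int = 8000
    max_mito_frac: float = 0.30
    min_cells_per_gene: int = 4
    mito_prefix: str = "MT-"
    n_hvg: int = 2000
    n_pcs: int = 20
    k: int = 10
    k_cut: int = 2
    min_cells: int = 5
    n_bins: int = 24
    n_ctrl: int = 100
    linkage_method: str = "complete"
    metric: str = "euclidean"
    seed: int = 0


def integrate(
    cell_genotypes: pd.DataFrame,
    matrix: ExpressionMatrix,
    gene_set: Sequence[str],
    params: IntegrateParams = IntegrateParams(),
    labels: Optional[pd.Series] = None,
):
    """Join genotypes to expression and classify variants.

    ``cell_genotypes`` needs columns ``cb`` and ``genotype_label`` (rows with
    a ``zygosity`` column are restricted to homozygous calls).  ``labels``
    optionally supplies precomputed cluster labels per barcode; otherwise the
    built-in PCA+k-means is used.

    Returns ``(variant_table, per_cell_table, report)``.
    """
    geno = cell_genotypes.copy()
    if "zygosity" in geno.columns:
        geno = geno[geno["zygosity"] == "homozygous"]
    geno = geno.dropna(subset=["genotype_label"])
    geno["cb"] = geno["cb"].map(strip_suffix)
    geno = geno.drop_duplicates(subset="cb", keep="first")

    mat_bc = pd.Index([strip_suffix(b) for b in matrix.barcodes])
    overlap = set(geno["cb"]) & set(mat_bc)
    n_geno_only = len(set(geno["cb"]) - overlap)
    n_expr_only = len(set(mat_bc) - overlap)
    if not overlap:
        raise JoinError("no barcode overlap between genotypes and expression matrix")

    mfilt, qc_report = qc_filter(
        matrix,
        min_genes=params.min_genes,
        max_genes=params.max_genes,
        max_mito_frac=params.max_mito_frac,
        min_cells_per_gene=params.min_cells_per_gene,
        mito_prefix=params.mito_prefix,
    )
    mnorm = normalize(mfilt)
    filt_bc = pd.Index([strip_suffix(b) for b in mnorm.barcodes])

    if labels is not None:
        lab = pd.Series(labels).copy()
        lab.index = [strip_suffix(b) for b in lab.index]
        cell_labels = pd.Series(
            [lab.get(b, np.nan) for b in filt_bc], index=filt_bc
        )
    else:
        cell_labels = pd.Series(
            cluster_cells(
                mnorm, n_hvg=params.n_hvg, n_pcs=params.n_pcs, k=params.k,
                seed=params.seed,
            ),
            index=filt_bc,
        )

    scores, score_report = module_score(
        mnorm, gene_set, n_bins=params.n_bins, n_ctrl=params.n_ctrl, seed=params.seed
    )
    score_by_bc = pd.Series(scores, index=filt_bc)

    geno_kept = geno[geno["cb"].isin(filt_bc)]
    per_cell = pd.DataFrame(
        {
            "cb": geno_kept["cb"].to_numpy(),
            "genotype_label": geno_kept["genotype_label"].to_numpy(),
        }
    )
    per_cell["cluster"] = per_cell["cb"].map(cell_labels)
    per_cell["score"] = per_cell["cb"].map(score_by_bc)
    per_cell = per_cell.sort_values("cb").reset_index(drop=True)

    prop = cluster_proportions(per_cell, cell_labels, min_cells=params.min_cells)
    wt_scores = per_cell.loc[per_cell["genotype_label"] == WT_LABEL, "score"].to_numpy()

    rows = []
    if len(prop):
        classes, _ = classify_variants(
            prop,
            wt_row=WT_LABEL,
            k_cut=params.k_cut,
            linkage_method=params.linkage_method,
            metric=params.metric,
        ) if WT_LABEL in prop.index else (
            pd.Series(CLASS_SIGNIFICANT, index=prop.index, name="class"),
            None,
        )
        for label in prop.index:
            cells = per_cell[per_cell["genotype_label"] == label]
            sc = cells["score"].to_numpy()
            if label == WT_LABEL or not len(wt_scores):
                t = p = np.nan
            else:
                t, p = score_test(sc, wt_scores)
            rows.append(
                {
                    "genotype_label": label,
                    "n_cells": len(cells),
                    "mean_score": float(np.mean(sc)) if len(sc) else np.nan,
                    "sd_score": float(np.std(sc, ddof=1)) if len(sc) > 1 else np.nan,
                    "t": t,
                    "p": p,
                    "class": classes[label],
                    **{f"cluster_{c}": prop.loc[label, c] for c in prop.columns},
                }
            )
    variant_table = pd.DataFrame(rows)
    report = {
        "n_genotyped_cells": len(geno),
        "n_barcodes_genotype_only": n_geno_only,
        "n_barcodes_expression_only": n_expr_only,
        "qc": qc_report,
        "module_score": score_report,
        "n_variants_retained": len(variant_table),
    }
    return variant_table, per_cell, report


def load_gene_set(path) -> List[str]:
    return [line.strip() for line in open(path) if line.strip()]


def load_cluster_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["cb", "cluster"])
    return pd.Series(df["cluster"].to_numpy(), index=df["cb"])
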