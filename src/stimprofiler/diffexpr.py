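"""Differential expression between donor groups and the PCA overview.

Per gene, a two-sided Wilcoxon rank-sum between two donor groups within one
cell type, with Benjamini-Hochberg adjustment across genes.  Works on the
centralized layer (steady state) or the relative layer, where the
stimulation-vs-control difference is already encoded per donor so the group
comparison realizes the two-step contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from stimprofiler import matrix as mx
from stimprofiler._stats import bh_adjust, rank_sum_test_matrix
from stimprofiler.matrix import ExpressionMatrix

#: FDR thresholds: significance call and the stricter "highly significant"
SIGNIFICANCE_Q = 0.10
HIGH_SIGNIFICANCE_Q = 0.01

MIN_GROUP_SIZE = 3


def _group_samples(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    group: str,
    cell_type: str,
) -> list[str]:
    meta = samples[samples["sample_id"].isin(matrix.sample_ids)]
    meta = mx.passed_qc(meta)
    sel = meta[(meta["group"] == group) & (meta["cell_type"] == cell_type)]
    if matrix.layer == "centralized":
        sel = sel[sel["condition"] == "steady"]
    return list(sel["sample_id"])


def deg_test(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    cell_type: str,
) -> pd.DataFrame:
    """Per-gene rank-sum test of ``group_a`` vs ``group_b`` in one cell type.

    Returns a DataFrame indexed by gene with columns ``contrast``, ``stat``,
    ``p``, ``q``, ``direction`` ('up' = higher in ``group_b``),
    ``mean_diff`` (mean of b minus mean of a), ``significant`` (q <= 0.10)
    and ``highly_significant`` (q <= 0.01).
    """
    if matrix.layer not in ("centralized", "relative"):
        raise ValueError("deg_test expects the centralized or relative layer")
    samples = mx.validate_samples(samples)
    ids_a = _group_samples(matrix, samples, group_a, cell_type)
    ids_b = _group_samples(matrix, samples, group_b, cell_type)
    if len(ids_a) < MIN_GROUP_SIZE or len(ids_b) < MIN_GROUP_SIZE:
        raise ValueError(
            f"underpowered contrast: {group_a} n={len(ids_a)}, "
            f"{group_b} n={len(ids_b)} (need >= {MIN_GROUP_SIZE} each)"
        )
    a = matrix.values[ids_a].to_numpy(dtype=float)
    b = matrix.values[ids_b].to_numpy(dtype=float)
    stat, p = rank_sum_test_matrix(a, b, alternative="two-sided")
    q = bh_adjust(p)
    mean_diff = b.mean(axis=1) - a.mean(axis=1)
    contrast = f"{group_a}-vs-{group_b}|{cell_type}|{matrix.layer}"
    return pd.DataFrame(
        {
            "contrast": contrast,
            "stat": stat,
            "p": p,
            "q": q,
            "direction": np.where(mean_diff >= 0, "up", "down"),
            "mean_diff": mean_diff,
            "significant": q <= SIGNIFICANCE_Q,
            "highly_significant": q <= HIGH_SIGNIFICANCE_Q,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )


def rank_by_fdr(deg: pd.DataFrame, n_top: int = 50) -> tuple[list[str], list[str]]:
    """Top up- and down-regulated genes ranked by FDR.

    Sorting key: q ascending, then raw p, then |mean_diff| descending, then
    gene id — so any permutation of the input rows yields the same lists.
    Lists are truncated to the available genes per direction.
    """
    if n_top < 0:
        raise ValueError("n_top must be >= 0")
    ordered = deg.copy()
    ordered["_abs_diff"] = -ordered["mean_diff"].abs()
    ordered["_gene"] = ordered.index
    ordered = ordered.sort_values(
        ["q", "p", "_abs_diff", "_gene"], kind="mergesort"
    )
    up = [g for g in ordered.index[ordered["direction"] == "up"]][:n_top]
    down = [g for g in ordered.index[ordered["direction"] == "down"]][:n_top]
    return up, down


@dataclass
class PCAOverview:
    """Sample coordinates, explained-variance fractions and gene loadings."""

    coordinates: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x PCs

    def top_loading_genes(self, pc: int = 1, n: int = 50) -> list[str]:
        """Genes with the largest |loading| on the given (1-based) PC."""
        col = f"PC{pc}"
        return list(self.loadings[col].abs().sort_values(ascending=False).index[:n])


def pca_overview(matrix: ExpressionMatrix, samples: pd.DataFrame) -> PCAOverview:
    """Gene-centered PCA of samples, for the condition/group overview."""
    ids = [s for s in matrix.sample_ids if s in set(samples["sample_id"])]
    if len(ids) < 3:
        raise ValueError("need at least 3 samples for the PCA overview")
    block = matrix.values[ids].to_numpy(dtype=float).T  # samples x genes
    n_comp = min(10, len(ids) - 1, block.shape[1])
    model = PCA(n_components=n_comp)
    coords = model.fit_transform(block - block.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAOverview(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        explained_variance_ratio=model.explained_variance_ratio_,
        loadings=pd.DataFrame(model.components_.T, index=matrix.gene_ids, columns=cols),
    )
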