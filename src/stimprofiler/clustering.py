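"""k-means gene-module detection with size-based cluster selection.

Genes are observations; features are per-stratum (cell type x group) mean
expression values, matching the column layout of a condition-averaged
heatmap.  Clusters with at least ``max_size`` genes are flagged as not
retained; retained clusters are annotated against a marker catalog by
over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from stimprofiler import matrix as mx
from stimprofiler.genesets import GeneSetCatalog, ora
from stimprofiler.matrix import ExpressionMatrix

MAX_RETAINED_SIZE = 500


def stratum_means(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    by: tuple[str, ...] = ("cell_type", "group"),
) -> pd.DataFrame:
    """Per-gene mean expression for every stratum defined by ``by``."""
    samples = mx.validate_samples(samples)
    meta = mx.passed_qc(samples[samples["sample_id"].isin(matrix.sample_ids)])
    if meta.empty:
        raise ValueError("no overlapping, QC-passing samples")
    cols = {}
    for key, chunk in meta.groupby(list(by), sort=True):
        label = "|".join(map(str, key if isinstance(key, tuple) else (key,)))
        cols[label] = matrix.values[list(chunk["sample_id"])].mean(axis=1)
    return pd.DataFrame(cols)


@dataclass
class ClusterResult:
    """Gene partition with per-cluster sizes, profiles and retention flags."""

    assignment: pd.Series  # gene -> cluster id
    features: pd.DataFrame  # genes x strata
    inertia: float
    retained: dict[int, bool] = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def members(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster])

    def mean_profiles(self) -> pd.DataFrame:
        return self.features.groupby(self.assignment).mean()

    def retained_clusters(self) -> list[int]:
        return [c for c, keep in sorted(self.retained.items()) if keep]


def kmeans_genes(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    k: int,
    n_init: int = 50,
    seed: int = 0,
) -> ClusterResult:
    """Best-of-``n_init`` k-means over gene stratum-mean profiles."""
    if k < 2:
        raise ValueError("k must be >= 2")
    features = stratum_means(matrix, samples)
    if k > len(features):
        raise ValueError(f"k={k} exceeds the {len(features)} available genes")
    model = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = model.fit_predict(features.to_numpy())
    return ClusterResult(
        assignment=pd.Series(labels, index=features.index, name="cluster"),
        features=features,
        inertia=float(model.inertia_),
    )


def select_clusters(result: ClusterResult, max_size: int = MAX_RETAINED_SIZE) -> ClusterResult:
    """Flag clusters for retention: strictly fewer than ``max_size`` genes."""
    sizes = result.sizes
    result.retained = {int(c): bool(n < max_size) for c, n in sizes.items()}
    if not any(result.retained.values()):
        import warnings

        warnings.warn("no cluster retained: all reach the size limit", stacklevel=2)
    return result


def annotate_clusters(
    result: ClusterResult,
    markers: GeneSetCatalog,
    universe: Iterable[str],
) -> pd.DataFrame:
    """ORA-based annotation of each retained cluster against ``markers``.

    Returns one row per retained cluster: top label, its p and q, and the
    cluster size.  Empty when nothing is retained.
    """
    if not len(markers):
        raise ValueError("empty marker catalog")
    rows = []
    for cluster in result.retained_clusters():
        genes = result.members(cluster)
        res = ora(genes, markers, universe)
        res = res.sort_values(["p", "q"], kind="mergesort")
        top = res.index[0] if len(res) else ""
        rows.append(
            (
                cluster,
                len(genes),
                top,
                float(res["p"].iloc[0]) if len(res) else np.nan,
                float(res["q"].iloc[0]) if len(res) else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["cluster", "size", "label", "p", "q"])


def choose_k(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    ks: Iterable[int] = range(8, 15),
    n_init: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Silhouette report over a sweep of k values."""
    features = stratum_means(matrix, samples).to_numpy()
    rows = []
    for k in ks:
        model = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = model.fit_predict(features)
        rows.append((k, float(model.inertia_), float(silhouette_score(features, labels))))
    return pd.DataFrame(rows, columns=["k", "inertia", "silhouette"])


def write_clusters(result: ClusterResult, path) -> None:
    out = pd.DataFrame(
        {
            "gene": result.assignment.index,
            "cluster": result.assignment.to_numpy(),
            "retained": [
                result.retained.get(int(c), True) for c in result.assignment
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)
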