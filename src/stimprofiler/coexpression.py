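"""Guilt-by-association co-expression discovery around interferon genes.

For each stratum (cell type x group) of the centralized steady-state data,
the Euclidean distance between every candidate gene and each interferon
gene is computed across the stratum's samples (scale-normalized by the
square root of the sample count).  A permutation null resamples the pooled
distances of the same interferon gene across all strata; candidates with a
significantly lower distance are reported, and the per-stratum union feeds
over-representation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from stimprofiler import matrix as mx
from stimprofiler._stats import bh_adjust
from stimprofiler.genesets import GeneSetCatalog, ora
from stimprofiler.matrix import ExpressionMatrix

MIN_STRATUM_SAMPLES = 3
MIN_PERMUTATIONS = 100
DEFAULT_Q_THRESHOLD = 0.10


def stratum_key(cell_type: str, group: str) -> str:
    return f"{cell_type}|{group}"


def gba_distance(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    ifn_genes: Sequence[str],
    stratum: tuple[str, str],
    centroid: bool = False,
) -> pd.DataFrame:
    """Distances of every candidate gene to each interferon gene.

    ``stratum`` is (cell type, group); only QC-passing steady-state samples
    of that stratum enter.  Rows are candidate genes, columns interferon
    genes; values are Euclidean distances over the stratum's samples divided
    by sqrt(n_samples).  With ``centroid=True`` a single column ``centroid``
    holds distances to the mean interferon profile instead.
    """
    if matrix.layer != "centralized":
        raise ValueError("gba_distance expects the centralized layer")
    cell_type, group = stratum
    samples = mx.validate_samples(samples)
    meta = mx.passed_qc(samples[samples["sample_id"].isin(matrix.sample_ids)])
    sel = meta[
        (meta["cell_type"] == cell_type)
        & (meta["group"] == group)
        & (meta["condition"] == "steady")
    ]
    ids = list(sel["sample_id"])
    if len(ids) < MIN_STRATUM_SAMPLES:
        raise ValueError(
            f"stratum {stratum} has {len(ids)} samples (need >= {MIN_STRATUM_SAMPLES})"
        )
    present = [g for g in dict.fromkeys(ifn_genes) if g in matrix.values.index]
    if not present:
        raise ValueError("no interferon gene is expressed in the matrix")
    block = matrix.values[ids]
    targets = (
        block.loc[present].mean(axis=0).to_frame().T.to_numpy()
        if centroid
        else block.loc[present].to_numpy()
    )
    dist = cdist(block.to_numpy(), targets) / np.sqrt(len(ids))
    columns = ["centroid"] if centroid else present
    out = pd.DataFrame(dist, index=block.index, columns=columns)
    if not centroid:
        # a gene is not a candidate for itself
        for g in present:
            out.loc[g, g] = np.nan
    return out


def gba_distances_by_stratum(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    ifn_genes: Sequence[str],
    strata: Iterable[tuple[str, str]] | None = None,
    centroid: bool = False,
) -> dict[str, pd.DataFrame]:
    """Distance tables for every (cell type, group) stratum with enough samples."""
    samples = mx.validate_samples(samples)
    if strata is None:
        meta = mx.passed_qc(samples[samples["condition"] == "steady"])
        strata = sorted(
            {(ct, g) for ct, g in zip(meta["cell_type"], meta["group"])}
        )
    tables = {}
    for ct, group in strata:
        try:
            tables[stratum_key(ct, group)] = gba_distance(
                matrix, samples, ifn_genes, (ct, group), centroid=centroid
            )
        except ValueError:
            continue
    if not tables:
        raise ValueError("no stratum had enough samples")
    return tables


@dataclass
class GBAResult:
    """Long-format permutation-test results plus per-stratum unions."""

    table: pd.DataFrame  # condition, ifn_gene, gene, distance, p, q
    unions: dict[str, list[str]]
    n_perm: int
    q_threshold: float


def gba_permutation_test(
    distances: Mapping[str, pd.DataFrame],
    n_perm: int = 10000,
    seed: int = 0,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> GBAResult:
    """Permutation test of per-stratum distances against the pooled null.

    For each interferon gene the null distribution is ``n_perm`` draws with
    replacement from that gene's pooled distances across all strata;
    p = (1 + #{draws <= observed}) / (1 + n_perm).  BH runs across
    candidates within each (stratum, interferon gene); candidates at
    q <= ``q_threshold`` enter the per-stratum union.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS}")
    if not distances:
        raise ValueError("empty distance collection")
    rng = np.random.default_rng(seed)
    ifn_genes = list(next(iter(distances.values())).columns)
    pooled = {
        g: np.concatenate(
            [t[g].dropna().to_numpy() for t in distances.values() if g in t.columns]
        )
        for g in ifn_genes
    }
    draws = {}
    for g in ifn_genes:
        if pooled[g].size == 0:
            raise ValueError(f"empty pooled distances for {g}")
        draws[g] = np.sort(rng.choice(pooled[g], size=n_perm, replace=True))

    frames = []
    unions: dict[str, list[str]] = {}
    for condition, table in distances.items():
        chunk_frames = []
        for g in table.columns:
            observed = table[g].dropna()
            count = np.searchsorted(draws[g], observed.to_numpy(), side="right")
            p = (1.0 + count) / (1.0 + n_perm)
            chunk = pd.DataFrame(
                {
                    "condition": condition,
                    "ifn_gene": g,
                    "gene": observed.index,
                    "distance": observed.to_numpy(),
                    "p": p,
                    "q": bh_adjust(p),
                }
            )
            chunk_frames.append(chunk)
        chunk = pd.concat(chunk_frames, ignore_index=True)
        frames.append(chunk)
        hits = chunk.loc[chunk["q"] <= q_threshold, "gene"]
        unions[condition] = sorted(set(hits))
    return GBAResult(
        table=pd.concat(frames, ignore_index=True),
        unions=unions,
        n_perm=n_perm,
        q_threshold=q_threshold,
    )


def gba_to_ora(
    result: GBAResult,
    catalog: GeneSetCatalog,
    universe: Iterable[str],
) -> dict[str, pd.DataFrame]:
    """Over-representation of each stratum's union of associated genes."""
    uni = set(universe)
    out = {}
    for condition, union in result.unions.items():
        query = [g for g in union if g in uni]
        if not query:
            out[condition] = pd.DataFrame(
                columns=["overlap", "set_size", "query_size", "universe_size", "p", "q"]
            )
            continue
        out[condition] = ora(query, catalog, uni)
    return out
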