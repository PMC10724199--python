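"""Raw counts to analysis-ready layers.

FPKM normalization, sample-level QC (marker-signature check, mapped-read
threshold, PCA outliers), the percentile gene filter, per-donor relative
expression of stimulated vs control samples, and in-sample centralization
of steady-state values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from stimprofiler import matrix as mx
from stimprofiler.genesets import GeneSetCatalog
from stimprofiler.matrix import ExpressionMatrix

#: default pseudocount (FPKM) for the stimulated/control log-ratio
DEFAULT_PSEUDOCOUNT = 0.1


def fpkm(
    counts: ExpressionMatrix, gene_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    value = count / (length_kb * total_sample_counts / 1e6)
    """
    if counts.layer != "raw_counts":
        raise ValueError("fpkm expects the raw_counts layer")
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ValueError(f"missing gene lengths for {len(missing)} genes, e.g. {missing[:3]}")
    lengths = np.array([float(gene_lengths[g]) for g in counts.gene_ids])
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.values.sum(axis=0).to_numpy(dtype=float)
    zero_depth = counts.values.columns[totals <= 0].tolist()
    if zero_depth:
        raise ValueError(f"zero-depth samples: {zero_depth}")
    values = counts.values.to_numpy(dtype=float)
    out = values / (lengths[:, None] / 1000.0) / (totals[None, :] / 1e6)
    return counts.derive(
        pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        "fpkm",
        "FPKM normalization",
    )


def _signature_zscores(
    sample_values: np.ndarray, gene_ids: pd.Index, catalog: GeneSetCatalog
) -> dict[str, float]:
    """Per marker set: standardized rank-sum of marker genes vs the rest.

    Rank-based one-sided enrichment (markers greater), computed from the
    normal approximation of the Wilcoxon rank-sum statistic with tie
    correction — a self-contained stand-in for signature QC.
    """
    n = sample_values.size
    ranks = pd.Series(sample_values).rank().to_numpy()
    scores = {}
    for name in catalog.names():
        members = gene_ids.isin(catalog[name])
        n1 = int(members.sum())
        n2 = n - n1
        if n1 == 0 or n2 == 0:
            scores[name] = float("-inf")
            continue
        r1 = ranks[members].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        mean_u = n1 * n2 / 2.0
        # tie-corrected variance
        _, counts = np.unique(sample_values, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        scores[name] = float((u - mean_u) / np.sqrt(var_u)) if var_u > 0 else 0.0
    return scores


def qc_signature_check(
    fpkm_matrix: ExpressionMatrix,
    markers: GeneSetCatalog,
    samples: pd.DataFrame,
    min_mapped_fraction: float = 0.5,
    mapped_fractions: Mapping[str, float] | None = None,
    marker_prefix: str = "MARKERS_",
) -> pd.DataFrame:
    """Flag samples with the wrong cell-type signature or low mapping rate.

    For every sample, each cell type's marker set gets a rank-based
    enrichment z-score on log2(FPKM + 1); the sample is flagged
    ``signature_mismatch`` unless its own cell type's set scores highest.
    When ``mapped_fractions`` is given, samples below ``min_mapped_fraction``
    are flagged ``low_mapping``.  Returns an updated copy of ``samples``.
    """
    if fpkm_matrix.layer != "fpkm":
        raise ValueError("qc_signature_check expects the fpkm layer")
    samples = mx.validate_samples(samples)
    cell_types = sorted(samples["cell_type"].unique())
    set_for = {}
    for ct in cell_types:
        name = f"{marker_prefix}{ct}"
        if name not in markers:
            raise ValueError(f"no marker set {name!r} for declared cell type {ct!r}")
        set_for[ct] = name
    log_values = np.log2(fpkm_matrix.values.to_numpy(dtype=float) + 1.0)
    gene_ids = fpkm_matrix.values.index
    marker_catalog = markers.select(set_for.values())

    mismatched = []
    for j, sample_id in enumerate(fpkm_matrix.sample_ids):
        row = samples.loc[samples["sample_id"] == sample_id]
        if row.empty:
            continue
        own = set_for[row["cell_type"].iloc[0]]
        scores = _signature_zscores(log_values[:, j], gene_ids, marker_catalog)
        if max(scores, key=scores.get) != own:
            mismatched.append(sample_id)
    samples = mx.add_flag(samples, mismatched, "signature_mismatch")

    if mapped_fractions is not None:
        low = [
            s for s, frac in mapped_fractions.items() if frac < min_mapped_fraction
        ]
        samples = mx.add_flag(samples, low, "low_mapping")
    return samples


def pca_outlier_flag(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    k_sd: float = 4.0,
) -> pd.DataFrame:
    """Flag samples far from their stratum on PC1/PC2.

    Within each (cell type x condition) stratum with >= 3 samples, a sample
    is flagged ``pca_outlier`` when its PC1 or PC2 coordinate lies more than
    ``k_sd`` standard deviations from the stratum mean.
    """
    samples = mx.validate_samples(samples)
    if not np.isfinite(k_sd):
        return samples
    flagged = []
    meta = samples[samples["sample_id"].isin(matrix.sample_ids)]
    for _, chunk in meta.groupby(["cell_type", "condition"]):
        ids = list(chunk["sample_id"])
        if len(ids) < 3:
            continue
        block = matrix.values[ids].to_numpy(dtype=float).T
        centered = block - block.mean(axis=0)
        if not centered.any():
            continue
        coords = PCA(n_components=min(2, len(ids) - 1)).fit_transform(centered)
        for pc in range(coords.shape[1]):
            col = coords[:, pc]
            sd = col.std()
            if sd == 0:
                continue
            off = np.abs(col - col.mean()) > k_sd * sd
            flagged.extend(np.array(ids)[off])
    return mx.add_flag(samples, set(flagged), "pca_outlier")


def filter_genes(
    fpkm_matrix: ExpressionMatrix,
    coding_genes: Iterable[str],
    lo_pct: float = 45.0,
    hi_pct: float = 99.5,
    keep_genes: Iterable[str] = (),
) -> ExpressionMatrix:
    """Percentile filter on per-gene totals, restricted to coding genes.

    Percentiles are computed on the coding subset with the lower-value
    convention (the largest observed total not exceeding the interpolated
    rank), and both bounds are inclusive.  ``keep_genes`` are retained
    regardless of their totals (forced keep-list).
    """
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
    coding = [g for g in fpkm_matrix.gene_ids if g in set(coding_genes)]
    if not coding:
        raise ValueError("no coding genes in matrix")
    totals = fpkm_matrix.values.loc[coding].sum(axis=1)
    lo, hi = np.percentile(totals.to_numpy(), [lo_pct, hi_pct], method="lower")
    kept = totals[(totals >= lo) & (totals <= hi)].index
    forced = [g for g in keep_genes if g in fpkm_matrix.values.index]
    kept = pd.Index(forced).union(kept, sort=False)
    kept = [g for g in fpkm_matrix.gene_ids if g in set(kept)]  # original order
    if not kept:
        raise ValueError("gene filter removed every gene")
    return fpkm_matrix.derive(
        fpkm_matrix.values.loc[kept],
        fpkm_matrix.layer,
        f"percentile gene filter [{lo_pct}, {hi_pct}] on {len(coding)} coding genes",
    )


def relative_expression(
    fpkm_matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ExpressionMatrix:
    """log2 ratio of stimulated over PBS-control FPKM, per donor and cell type.

    value = log2((FPKM_aCD3 + pseudocount) / (FPKM_PBS + pseudocount)).
    Output columns are the stimulated sample ids (one per donor x cell
    type); stimulated samples without a same-donor, same-cell-type PBS
    partner are excluded with a provenance entry.
    """
    if fpkm_matrix.layer != "fpkm":
        raise ValueError("relative_expression expects the fpkm layer")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    samples = mx.validate_samples(samples)
    meta = samples[samples["sample_id"].isin(fpkm_matrix.sample_ids)]
    pbs = meta[meta["condition"] == "PBS"].set_index(["donor_id", "cell_type"])
    stim = meta[meta["condition"] == "aCD3"]
    columns, pairs, unpaired = [], [], []
    for _, row in stim.iterrows():
        key = (row["donor_id"], row["cell_type"])
        if key in pbs.index:
            pairs.append((row["sample_id"], pbs.loc[key, "sample_id"]))
            columns.append(row["sample_id"])
        else:
            unpaired.append(row["sample_id"])
    if not pairs:
        raise ValueError("no stimulated sample has a PBS partner")
    a = fpkm_matrix.values[[s for s, _ in pairs]].to_numpy(dtype=float)
    b = fpkm_matrix.values[[p for _, p in pairs]].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        out = np.log2(a + pseudocount) - np.log2(b + pseudocount)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite log-ratios; use a positive pseudocount")
    note = f"relative expression (log2, pseudocount={pseudocount})"
    if unpaired:
        note += f"; excluded unpaired stimulated samples: {sorted(unpaired)}"
    return fpkm_matrix.derive(
        pd.DataFrame(out, index=fpkm_matrix.values.index, columns=columns),
        "relative",
        note,
    )


def centralize(fpkm_matrix: ExpressionMatrix) -> ExpressionMatrix:
    """In-sample centralization: per sample, (x - median) / SD.

    SD is the sample standard deviation (n-1 denominator), so e.g. the
    sample {1, 2, 3} maps to {-1, 0, 1}.
    """
    if fpkm_matrix.layer != "fpkm":
        raise ValueError("centralize expects the fpkm layer")
    values = fpkm_matrix.values.to_numpy(dtype=float)
    med = np.median(values, axis=0)
    sd = values.std(axis=0, ddof=1)
    degenerate = fpkm_matrix.values.columns[sd <= 0].tolist()
    if degenerate:
        raise ValueError(f"constant samples cannot be centralized: {degenerate}")
    out = (values - med[None, :]) / sd[None, :]
    return fpkm_matrix.derive(
        pd.DataFrame(out, index=fpkm_matrix.values.index, columns=fpkm_matrix.values.columns),
        "centralized",
        "in-sample centralization (median, SD)",
    )


def write_provenance(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Append-style JSON-lines provenance log."""
    with open(path, "w") as fh:
        for entry in matrix.provenance:
            fh.write(json.dumps({"layer": matrix.layer, "note": entry}) + "\n")
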