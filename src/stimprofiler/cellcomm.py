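"""Ligand-receptor co-occurrence and cytokine-activity group statistics.

A potential interaction is "detected" in a donor when the ligand ranks in
the top fraction of up-regulated genes of the sender cell's stimulated
relative-expression profile and the receptor is expressed in the receiver
cell.  Detected fractions are compared between donor groups with Fisher
exact tests.  Downstream of any externally supplied cytokine-activity
Z-score matrix, per-cytokine group comparisons use a t-test (stimulated
layer) or a rank-sum test (steady layer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from stimprofiler import matrix as mx
from stimprofiler._stats import bh_adjust, rank_sum_test
from stimprofiler.matrix import ExpressionMatrix

DEFAULT_SENDERS = ("Th", "CTL")
DEFAULT_LIGAND_TOP_FRACTION = 0.10
DEFAULT_RECEPTOR_MIN_FPKM = 1.0
MIN_GROUP_SIZE = 3


def validate_lr_table(lr: pd.DataFrame) -> pd.DataFrame:
    from stimprofiler.synthetic_data import LR_CATEGORIES

    required = {"ligand", "receptor", "category"}
    missing = required - set(lr.columns)
    if missing:
        raise ValueError(f"ligand-receptor table missing columns: {sorted(missing)}")
    if lr.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate ligand-receptor pairs")
    bad = set(lr["category"]) - set(LR_CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    return lr


@dataclass
class InteractionOccurrence:
    """Donor-level detection flags and per-group fractions."""

    flags: pd.DataFrame  # sender, receiver, ligand, receptor, category, group, donor, detected
    fractions: pd.DataFrame  # sender, receiver, ligand, receptor, category, group, n_donors, n_detected, fraction
    tests: pd.DataFrame | None = None


def _eligible_donors(
    relative: ExpressionMatrix,
    fpkm: ExpressionMatrix,
    samples: pd.DataFrame,
    cell_types: Sequence[str],
) -> dict[str, dict[str, tuple[str, str]]]:
    """Donors whose every cell type has QC-passing relative and stimulated
    FPKM samples; maps donor -> cell type -> (relative column, fpkm column)."""
    meta = mx.passed_qc(samples)
    acd3 = meta[meta["condition"] == "aCD3"]
    rel_cols = set(relative.sample_ids)
    fpkm_cols = set(fpkm.sample_ids)
    by_donor: dict[str, dict[str, tuple[str, str]]] = {}
    for donor, chunk in acd3.groupby("donor_id"):
        mapping = {}
        for _, row in chunk.iterrows():
            sid = row["sample_id"]
            if sid in rel_cols and sid in fpkm_cols:
                mapping[row["cell_type"]] = (sid, sid)
        if all(ct in mapping for ct in cell_types):
            by_donor[donor] = mapping
    return by_donor


def detect_interactions(
    relative: ExpressionMatrix,
    fpkm: ExpressionMatrix,
    samples: pd.DataFrame,
    lr: pd.DataFrame,
    ligand_top_fraction: float = DEFAULT_LIGAND_TOP_FRACTION,
    receptor_min_fpkm: float = DEFAULT_RECEPTOR_MIN_FPKM,
    senders: Sequence[str] = DEFAULT_SENDERS,
) -> InteractionOccurrence:
    """Donor-level ligand-receptor detection across sender/receiver pairs.

    Only donors with complete, QC-passing data for every cell type are
    considered.  Senders default to the T cell subsets; every cell type may
    receive.  A pair is detected in a donor when the ligand's relative
    value in the sender sample ranks within the top ``ligand_top_fraction``
    of that sample's up-regulated (positive) genes and the receptor's FPKM
    in the receiver's stimulated sample exceeds ``receptor_min_fpkm``.
    """
    if relative.layer != "relative":
        raise ValueError("detect_interactions expects a relative-layer matrix")
    if fpkm.layer != "fpkm":
        raise ValueError("receptor expression requires an fpkm-layer matrix")
    if not 0 < ligand_top_fraction <= 1:
        raise ValueError("ligand_top_fraction must be in (0, 1]")
    lr = validate_lr_table(lr)
    samples = mx.validate_samples(samples)
    cell_types = sorted(samples["cell_type"].unique())
    receivers = cell_types
    donors = _eligible_donors(relative, fpkm, samples, cell_types)
    donor_group = samples.drop_duplicates("donor_id").set_index("donor_id")["group"]

    in_universe = lr["ligand"].isin(relative.values.index) & lr["receptor"].isin(
        fpkm.values.index
    )
    skipped = lr[~in_universe]
    lr = lr[in_universe]

    # per (donor, sender): the set of top up-regulated genes
    top_genes: dict[tuple[str, str], set[str]] = {}
    expressed: dict[tuple[str, str], pd.Series] = {}
    for donor, mapping in donors.items():
        for ct in cell_types:
            rel_col, fpkm_col = mapping[ct]
            vec = relative.values[rel_col]
            pos = vec[vec > 0]
            n_top = int(np.floor(ligand_top_fraction * len(pos)))
            top = set(pos.sort_values(ascending=False).index[:n_top])
            top_genes[(donor, ct)] = top
            expressed[(donor, ct)] = fpkm.values[fpkm_col] > receptor_min_fpkm

    rows = []
    for sender in senders:
        if sender not in cell_types:
            continue
        for receiver in receivers:
            for _, pair in lr.iterrows():
                ligand, receptor, category = (
                    pair["ligand"],
                    pair["receptor"],
                    pair["category"],
                )
                for donor in donors:
                    detected = bool(
                        ligand in top_genes[(donor, sender)]
                        and expressed[(donor, receiver)][receptor]
                    )
                    rows.append(
                        (
                            sender,
                            receiver,
                            ligand,
                            receptor,
                            category,
                            donor_group[donor],
                            donor,
                            detected,
                        )
                    )
    flags = pd.DataFrame(
        rows,
        columns=[
            "sender",
            "receiver",
            "ligand",
            "receptor",
            "category",
            "group",
            "donor",
            "detected",
        ],
    )
    if not skipped.empty:
        flags.attrs["skipped_pairs"] = skipped[["ligand", "receptor"]].to_records(
            index=False
        ).tolist()
    fractions = (
        flags.groupby(
            ["sender", "receiver", "ligand", "receptor", "category", "group"],
            sort=True,
        )["detected"]
        .agg(n_donors="size", n_detected="sum")
        .reset_index()
    )
    fractions["fraction"] = np.where(
        fractions["n_donors"] > 0,
        fractions["n_detected"] / fractions["n_donors"],
        0.0,
    )
    return InteractionOccurrence(flags=flags, fractions=fractions)


def interaction_group_test(
    occ: InteractionOccurrence,
    group_a: str,
    group_b: str,
    alternative: str = "two-sided",
) -> InteractionOccurrence:
    """Fisher exact test per detected pair between two donor groups.

    Pairs detected in at least one donor of either group are tested on the
    2x2 table (detected / not) x (group); BH runs across tested pairs.
    Direction is 'up' when the detected fraction is higher in ``group_b``.
    """
    keys = ["sender", "receiver", "ligand", "receptor", "category"]
    frac = occ.fractions
    a = frac[frac["group"] == group_a].set_index(keys)
    b = frac[frac["group"] == group_b].set_index(keys)
    if a.empty or b.empty:
        raise ValueError("both groups need at least one donor")
    shared = a.index.intersection(b.index)
    rows = []
    for key in shared:
        det_a, n_a = int(a.loc[key, "n_detected"]), int(a.loc[key, "n_donors"])
        det_b, n_b = int(b.loc[key, "n_detected"]), int(b.loc[key, "n_donors"])
        if det_a + det_b == 0:
            continue
        table = [[det_a, n_a - det_a], [det_b, n_b - det_b]]
        p = float(stats.fisher_exact(table, alternative=alternative)[1])
        frac_a = det_a / n_a if n_a else 0.0
        frac_b = det_b / n_b if n_b else 0.0
        rows.append(
            (*key, det_a, n_a, det_b, n_b, frac_a, frac_b, p,
             "up" if frac_b >= frac_a else "down")
        )
    tests = pd.DataFrame(
        rows,
        columns=[
            *keys,
            f"detected_{group_a}",
            f"n_{group_a}",
            f"detected_{group_b}",
            f"n_{group_b}",
            f"fraction_{group_a}",
            f"fraction_{group_b}",
            "p",
            "direction",
        ],
    )
    if not tests.empty:
        tests["q"] = bh_adjust(tests["p"].to_numpy())
    else:
        tests["q"] = pd.Series(dtype=float)
    return InteractionOccurrence(flags=occ.flags, fractions=occ.fractions, tests=tests)


def comm_gene_enrichment(
    up_genes: Sequence[str],
    down_genes: Sequence[str],
    comm_genes: Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Fisher enrichment of communication genes among up/down genes.

    One row per direction with the 2x2 table counts and the one-sided
    (enrichment) Fisher p.
    """
    uni = set(universe)
    comm = set(comm_genes) & uni
    rows = []
    for label, genes in (("up", up_genes), ("down", down_genes)):
        sel = set(genes) & uni
        a = len(sel & comm)
        b = len(sel - comm)
        c = len(comm - sel)
        d = len(uni - sel - comm)
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
        rows.append((label, a, b, c, d, p))
    return pd.DataFrame(
        rows, columns=["direction", "in_comm", "not_comm", "comm_rest", "rest", "p"]
    )


@dataclass
class ActivityMatrix:
    """Cytokine x sample Z-score matrix with a layer tag."""

    values: pd.DataFrame
    layer: str  # "steady" | "stimulated"

    def __post_init__(self) -> None:
        if self.layer not in ("steady", "stimulated"):
            raise ValueError("activity layer must be 'steady' or 'stimulated'")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("activity values must be finite")


def signature_activity(matrix: ExpressionMatrix, catalog) -> ActivityMatrix:
    """Plain signature projection: per-set mean of column-z-scored values.

    A simplified stand-in for an external cytokine-activity model, intended
    for synthetic testing only; it is NOT a reimplementation of any hosted
    scoring service.
    """
    values = matrix.values.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=0)) / sd
    zdf = pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns)
    rows = {}
    for name in catalog.names():
        members = [g for g in catalog[name] if g in zdf.index]
        if members:
            rows[name] = zdf.loc[members].mean(axis=0)
    layer = "stimulated" if matrix.layer == "relative" else "steady"
    return ActivityMatrix(pd.DataFrame(rows).T, layer)


def compare_activity(
    activity: ActivityMatrix,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-cytokine two-group comparison on an activity matrix.

    Stimulated layer: two-sided t-test; steady layer: two-sided rank-sum
    (never the t-test).  BH across cytokines; ``mean_diff`` is mean(b) -
    mean(a).  The dispatched test is recorded in the ``test`` column.
    """
    samples = mx.validate_samples(samples)
    meta = samples[samples["sample_id"].isin(activity.values.columns)]
    ids_a = list(meta.loc[meta["group"] == group_a, "sample_id"])
    ids_b = list(meta.loc[meta["group"] == group_b, "sample_id"])
    if len(ids_a) < MIN_GROUP_SIZE or len(ids_b) < MIN_GROUP_SIZE:
        raise ValueError(
            f"underpowered comparison: {group_a} n={len(ids_a)}, {group_b} n={len(ids_b)}"
        )
    test_name = "ttest" if activity.layer == "stimulated" else "wilcoxon"
    rows = []
    for cytokine in activity.values.index:
        x = activity.values.loc[cytokine, ids_a].to_numpy(dtype=float)
        y = activity.values.loc[cytokine, ids_b].to_numpy(dtype=float)
        if test_name == "ttest":
            stat, p = stats.ttest_ind(x, y)
            stat, p = float(stat), float(p)
        else:
            stat, p = rank_sum_test(x, y)
        rows.append((cytokine, test_name, stat, p, float(y.mean() - x.mean())))
    out = pd.DataFrame(rows, columns=["cytokine", "test", "stat", "p", "mean_diff"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
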