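"""End-to-end orchestration of the analysis on a (simulated) dataset."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from stimprofiler import (
    cellcomm,
    clustering,
    coexpression,
    diffexpr,
    preprocess,
    synthetic_data,
)
from stimprofiler import matrix as mx
from stimprofiler.genesets import activity_profile, ora


def run_pipeline(
    config: synthetic_data.SimulationConfig,
    outdir: str | Path,
    n_perm: int = 2000,
    k_clusters: int = 6,
    n_ifn_for_gba: int = 5,
) -> dict:
    """Simulate a dataset and run every analysis stage, writing all outputs.

    Returns a dict of in-memory results keyed by stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts, lengths, samples, truth = synthetic_data.simulate_dataset(config)
    catalog = synthetic_data.simulate_genesets(truth, seed=config.seed)
    lr_table = synthetic_data.simulate_lr_table(truth, seed=config.seed)
    synthetic_data.write_dataset(
        outdir, counts, lengths, samples, truth, catalog, lr_table
    )

    fpkm = preprocess.fpkm(counts, lengths)
    samples = preprocess.qc_signature_check(fpkm, catalog, samples)
    samples = preprocess.pca_outlier_flag(fpkm, samples)
    mx.write_samples(samples, outdir / "samples.tsv")
    fpkm = preprocess.filter_genes(fpkm, fpkm.gene_ids, 5.0, 99.5)
    relative = preprocess.relative_expression(fpkm, samples)
    steady_ids = list(
        samples.loc[samples["condition"] == "steady", "sample_id"]
    )
    steady_ids = [s for s in steady_ids if s in fpkm.sample_ids]
    centralized = preprocess.centralize(fpkm.subset(samples=steady_ids))
    preprocess.write_provenance(centralized, outdir / "provenance.jsonl")

    results: dict = {"samples": samples, "truth": truth}

    # differential expression per patient group, both layers, one cell type each
    groups = [g for g, n in config.group_sizes.items() if g != "HD" and n > 0]
    deg_tables = {}
    for group in groups:
        for layer_matrix in (centralized, relative):
            try:
                deg = diffexpr.deg_test(layer_matrix, samples, "HD", group, "B")
            except ValueError:
                continue
            label = deg["contrast"].iloc[0].replace("|", "_")
            deg.to_csv(outdir / f"deg_{label}.tsv", sep="\t")
            deg_tables[label] = deg
    results["deg"] = deg_tables

    # ORA on the FDR-ranked genes of each contrast
    universe = centralized.gene_ids
    ora_tables = {}
    for label, deg in deg_tables.items():
        up, down = diffexpr.rank_by_fdr(deg, 50)
        ora_tables[label] = {
            "up": ora(up, catalog, universe),
            "down": ora(down, catalog, universe),
        }
    results["ora"] = ora_tables

    # PCA overview on the full FPKM matrix
    results["pca"] = diffexpr.pca_overview(fpkm, samples)

    # activity-stratified regulatory scores
    regscore = activity_profile(centralized, samples, catalog)
    regscore.to_csv(outdir / "regscore.tsv", sep="\t", index=False)
    results["regscore"] = regscore

    # guilt-by-association co-expression around the planted interferon genes
    ifn_genes = [g for g in truth.ifn_genes if g in centralized.values.index]
    ifn_genes = ifn_genes[:n_ifn_for_gba]
    distances = coexpression.gba_distances_by_stratum(
        centralized, samples, ifn_genes
    )
    gba = coexpression.gba_permutation_test(
        distances, n_perm=n_perm, seed=config.seed
    )
    for condition, chunk in gba.table.groupby("condition"):
        safe = condition.replace("|", "_")
        chunk.to_csv(outdir / f"gba_{safe}.tsv", sep="\t", index=False)
    results["gba"] = gba
    results["gba_ora"] = coexpression.gba_to_ora(gba, catalog, universe)

    # gene modules
    clusters = clustering.kmeans_genes(
        centralized, samples, k=k_clusters, n_init=10, seed=config.seed
    )
    clusters = clustering.select_clusters(clusters)
    clustering.write_clusters(clusters, outdir / "clusters.tsv")
    annotation = clustering.annotate_clusters(clusters, catalog, universe)
    annotation.to_csv(outdir / "cluster_annotation.tsv", sep="\t", index=False)
    results["clusters"] = clusters
    results["cluster_annotation"] = annotation

    # ligand-receptor occurrence and group tests
    occ = cellcomm.detect_interactions(relative, fpkm, samples, lr_table)
    tested = []
    for group in groups:
        res = cellcomm.interaction_group_test(occ, "HD", group)
        res.tests["contrast"] = f"HD-vs-{group}"
        tested.append(res.tests)
    interactions = (
        pd.concat(tested, ignore_index=True) if tested else occ.fractions
    )
    interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    results["interactions"] = interactions

    # cytokine-activity group comparison on the signature-projection fallback
    activity = cellcomm.signature_activity(centralized, catalog)
    stats_frames = []
    for group in groups:
        frame = cellcomm.compare_activity(activity, samples, "HD", group)
        frame["contrast"] = f"HD-vs-{group}"
        stats_frames.append(frame)
    activity_stats = pd.concat(stats_frames, ignore_index=True)
    activity_stats.to_csv(outdir / "activity_stats.tsv", sep="\t", index=False)
    results["activity_stats"] = activity_stats
    return results
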