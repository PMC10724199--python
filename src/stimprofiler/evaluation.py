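"""Criterion-level evaluation experiments on the synthetic-data generator.

Each function recomputes one verifiable property of the pipeline from
scratch — oracle equivalence against brute-force enumeration, calibration
of permutation/rank tests under null simulations, and recovery of planted
structure — and returns plain numbers.  Used by the acceptance test suite
and the standalone acceptance report script.

The enumeration oracles here are deliberately independent of the package's
statistical code paths: combinatorial enumeration with exact rational
arithmetic, no `scipy.stats` distributions.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd

from stimprofiler import (
    cellcomm as cc,
    clustering as cl,
    coexpression as cx,
    diffexpr as dx,
    preprocess as pp,
    synthetic_data as sd,
)
from stimprofiler import genesets as gs


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ora_enumeration_oracle(
    universe_size: int, set_genes: frozenset, query_size: int, observed: int
) -> float:
    """P(overlap >= observed) by enumerating every possible query draw."""
    hits = total = 0
    mask = 0
    for g in set_genes:
        mask |= 1 << g
    for draw in itertools.combinations(range(universe_size), query_size):
        total += 1
        dm = 0
        for g in draw:
            dm |= 1 << g
        if bin(dm & mask).count("1") >= observed:
            hits += 1
    return hits / total


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


def fisher_onesided_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p by enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)
    total = Fraction(0)
    for x in range(a, min(r1, c1) + 1):
        total += Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
    return float(total)


def ks_bruteforce_oracle(set_values: np.ndarray, bg_values: np.ndarray) -> float:
    """Max absolute CDF difference via a double loop over all thresholds."""
    best = 0.0
    for t in np.concatenate([set_values, bg_values]):
        diff = abs((bg_values <= t).mean() - (set_values <= t).mean())
        best = max(best, diff)
    return float(best)


# ---------------------------------------------------------------------------
# criterion experiments
# ---------------------------------------------------------------------------

def ora_oracle_equivalence(seed: int = 0, n_random: int = 60) -> dict:
    """Max |ora p - enumeration p| over small universes (<= 20 genes)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    cases = 0
    for _ in range(n_random):
        n_uni = int(rng.integers(3, 21))
        universe = [f"g{i}" for i in range(n_uni)]
        set_size = int(rng.integers(1, n_uni + 1))
        query_size = int(rng.integers(1, min(n_uni, 8) + 1))
        set_idx = rng.choice(n_uni, size=set_size, replace=False)
        query_idx = rng.choice(n_uni, size=query_size, replace=False)
        observed = len(set(set_idx) & set(query_idx))
        expected = ora_enumeration_oracle(
            n_uni, frozenset(int(i) for i in set_idx), query_size, observed
        )
        catalog = gs.GeneSetCatalog({"S": [universe[i] for i in set_idx]})
        res = gs.ora(
            [universe[i] for i in query_idx], catalog, universe,
            min_size=1, max_size=10**6,
        )
        worst = max(worst, abs(float(res.loc["S", "p"]) - expected))
        cases += 1
    return {"max_abs_diff": worst, "n": cases}


def fisher_oracle_equivalence(seed: int = 0, n_random: int = 120) -> dict:
    """Max |Fisher p - enumeration p| for tables with margins <= 30.

    Covers both the two-sided pair test and the one-sided communication-gene
    enrichment, plus the fixed 13-vs-9 donor occurrence table.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    cases = []
    for _ in range(n_random):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        cases.append((a, b, c, d))
    cases.append((5, 8, 8, 1))  # 5/13 vs 8/9 donor occurrence
    for a, b, c, d in cases:
        occ = _occurrence_from_counts(a, a + b, c, c + d)
        res = cc.interaction_group_test(occ, "HD", "SLE")
        worst = max(
            worst, abs(float(res.tests["p"].iloc[0]) - fisher_enumeration_oracle(a, b, c, d))
        )
    # one-sided enrichment path
    for _ in range(30):
        n_uni = int(rng.integers(8, 30))
        universe = [f"g{i}" for i in range(n_uni)]
        comm = list(rng.choice(universe, size=int(rng.integers(1, n_uni)), replace=False))
        up = list(rng.choice(universe, size=int(rng.integers(1, n_uni)), replace=False))
        out = cc.comm_gene_enrichment(up, [], comm, universe)
        a = len(set(up) & set(comm))
        b = len(set(up) - set(comm))
        c = len(set(comm) - set(up))
        d = n_uni - a - b - c
        expected = fisher_onesided_oracle(a, b, c, d)
        worst = max(worst, abs(float(out["p"].iloc[0]) - expected))
        cases.append((a, b, c, d))
    return {"max_abs_diff": worst, "n": len(cases)}


def _occurrence_from_counts(det_a, n_a, det_b, n_b) -> cc.InteractionOccurrence:
    rows = []
    for group, det, n in (("HD", det_a, n_a), ("SLE", det_b, n_b)):
        for i in range(n):
            rows.append(
                ("Th", "B", "L", "R", "Cytokines", group, f"{group}{i}", i < det)
            )
    flags = pd.DataFrame(
        rows,
        columns=["sender", "receiver", "ligand", "receptor", "category",
                 "group", "donor", "detected"],
    )
    fractions = (
        flags.groupby(
            ["sender", "receiver", "ligand", "receptor", "category", "group"]
        )["detected"]
        .agg(n_donors="size", n_detected="sum")
        .reset_index()
    )
    fractions["fraction"] = fractions["n_detected"] / fractions["n_donors"]
    return cc.InteractionOccurrence(flags=flags, fractions=fractions)


def ks_oracle_equivalence(seed: int = 0, n_instances: int = 1000) -> dict:
    """Max |ks_regscore D - brute-force D| over random instances (n <= 100)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(8, 101))
        k = int(rng.integers(3, n - 3))
        vals = rng.normal(size=n)
        if rng.random() < 0.3:
            vals = np.round(vals * 2) / 2  # inject ties
        if np.unique(vals).size == 1:
            continue
        genes = [f"g{i}" for i in range(n)]
        entry = gs.ks_regscore(pd.Series(vals, index=genes), genes[:k])
        expected = ks_bruteforce_oracle(vals[:k], vals[k:])
        worst = max(worst, abs(abs(entry.d) - expected))
    return {"max_abs_diff": worst, "n": n_instances}


def _null_gba_config(seed: int, **overrides) -> sd.SimulationConfig:
    params = dict(
        seed=seed,
        n_genes=2000,
        n_deg=0,
        n_stim_genes=0,
        deg_log2fc=0.0,
        stim_log2fc=0.0,
        ifn_set_size=10,
        activity_effect={"Low": 0.0, "Moderate": 0.0, "High": 0.0},
        n_modules=0,
        module_sizes=(),
        lr_events=[],
        n_markers=0,
        marker_log2fc=0.0,
        qc_dropout=0.0,
    )
    params.update(overrides)
    return sd.SimulationConfig(**params)


def _centralized_steady(config: sd.SimulationConfig):
    counts, lengths, samples, truth = sd.simulate_dataset(config)
    fpkm = pp.fpkm(counts, lengths)
    steady = list(samples.loc[samples["condition"] == "steady", "sample_id"])
    return pp.centralize(fpkm.subset(samples=steady)), samples, truth, fpkm

def gba_calibration(seed: int = 0, n_seeds: int = 20, n_perm: int = 1000) -> dict:
    """Fraction of GBA candidates at p <= 0.05 under the null simulator."""
    fractions = []
    for offset in range(n_seeds):
        cen, samples, truth, _ = _centralized_steady(_null_gba_config(seed + offset))
        dist = cx.gba_distances_by_stratum(cen, samples, truth.ifn_genes)
        res = cx.gba_permutation_test(dist, n_perm=n_perm, seed=seed + offset)
        fractions.append(float((res.table["p"] <= 0.05).mean()))
    return {
        "fraction_p_le_05": float(np.mean(fractions)),
        "per_seed": fractions,
        "n": n_seeds,
    }


def gba_sensitivity(seed: int = 0, n_seeds: int = 20, n_perm: int = 50000) -> dict:
    """Recovery of partners planted at correlation 0.9 with interferon genes."""
    sens = []
    for offset in range(n_seeds):
        config = _null_gba_config(
            seed + offset,
            ifn_set_size=5,
            n_coexpr=100,
            coexpr_rho=0.9,
            coexpr_stratum=("Th", "SLE"),
        )
        cen, samples, truth, _ = _centralized_steady(config)
        dist = cx.gba_distances_by_stratum(cen, samples, truth.ifn_genes)
        res = cx.gba_permutation_test(dist, n_perm=n_perm, seed=seed + offset)
        sub = res.table[res.table.condition == "Th|SLE"].set_index(
            ["ifn_gene", "gene"]
        )
        hits = sum(
            1
            for partner, info in truth.coexpr_partners.items()
            if sub.loc[(info["ifn_gene"], partner), "q"] <= 0.10
        )
        sens.append(hits / len(truth.coexpr_partners))
    return {"sensitivity": float(np.mean(sens)), "per_seed": sens, "n": n_seeds}


def deg_recovery(seed: int = 0, n_seeds: int = 10) -> dict:
    """Sensitivity and FDP for 100 planted DEGs at log2FC 1.5, 12 vs 12."""
    sens, fdp = [], []
    for offset in range(n_seeds):
        config = sd.SimulationConfig(
            seed=seed + offset,
            group_sizes={"HD": 12, "pSS": 0, "SLE": 12},
            n_deg=100,
            deg_log2fc=1.5,
            qc_dropout=0.0,
        )
        counts, lengths, samples, truth = sd.simulate_dataset(config)
        rel = pp.relative_expression(pp.fpkm(counts, lengths), samples)
        deg = dx.deg_test(rel, samples, "HD", "SLE", "Th")
        called = set(deg.index[deg["significant"]])
        planted = set(truth.deg_genes["SLE"])
        sens.append(len(called & planted) / len(planted))
        fdp.append(len(called - planted) / max(1, len(called)))
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdp)),
        "n": n_seeds,
    }


def trajectory_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Monotone vs bell-shaped activity effects on the planted IFN set."""
    def run(s, effect):
        config = sd.SimulationConfig(
            seed=s,
            n_deg=0,
            n_stim_genes=0,
            ifn_set_size=50,
            activity_effect=effect,
            n_modules=0,
            module_sizes=(),
            lr_events=[],
            n_markers=0,
            marker_log2fc=0.0,
            qc_dropout=0.0,
        )
        cen, samples, truth, _ = _centralized_steady(config)
        catalog = gs.GeneSetCatalog({"IFN_TYPE_I_SYNTH": truth.ifn_genes})
        profile = gs.activity_profile(cen, samples, catalog)
        # one trajectory per patient group: median D across cell types
        shapes = []
        for _, chunk in profile.groupby("group"):
            d = chunk.groupby("activity_class")["D"].median()
            if {"Low", "Moderate", "High"} <= set(d.index):
                shapes.append((d["Low"], d["Moderate"], d["High"]))
        return shapes

    mono_ok = bell_ok = 0
    for offset in range(n_seeds):
        shapes = run(seed + offset, {"Low": 0.5, "Moderate": 1.0, "High": 2.0})
        mono_ok += all(lo < mid < hi for lo, mid, hi in shapes)
        shapes = run(seed + 1000 + offset, {"Low": 0.5, "Moderate": 2.0, "High": 0.5})
        bell_ok += all(mid > lo and mid > hi for lo, mid, hi in shapes)
    return {"monotone_ok": mono_ok, "bell_ok": bell_ok, "n": n_seeds}


def module_recovery(seed: int = 0, n_seeds: int = 5) -> dict:
    """k-means ARI against planted modules at 3-SD separation."""
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for offset in range(n_seeds):
        config = sd.SimulationConfig(
            seed=seed + offset,
            n_modules=4,
            module_sizes=(60, 60, 60, 60),
            module_sep=3.0,
            n_deg=0,
            n_stim_genes=0,
            lr_events=[],
            n_markers=0,
            marker_log2fc=0.0,
            activity_effect={"Low": 0.0, "Moderate": 0.0, "High": 0.0},
            qc_dropout=0.0,
        )
        counts, lengths, samples, truth = sd.simulate_dataset(config)
        rel = pp.relative_expression(pp.fpkm(counts, lengths), samples)
        result = cl.kmeans_genes(rel, samples, k=5, n_init=20, seed=seed + offset)
        genes = list(truth.module_assignment)
        aris.append(
            adjusted_rand_score(
                [truth.module_assignment[g] for g in genes],
                result.assignment.loc[genes],
            )
        )
    return {"ari": float(np.mean(aris)), "per_seed": aris, "n": n_seeds}


def lr_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Planted ligand-receptor detection probabilities and group tests."""
    frac_hd, frac_dis = [], []
    planted_hits = planted_n = 0
    null_hits = null_n = 0
    for offset in range(n_seeds):
        events = [
            sd.LREventSpec("Th", "B", {"HD": 0.3, "SLE": 0.9}),
            sd.LREventSpec("CTL", "NK", {"HD": 0.3, "SLE": 0.9}),
            sd.LREventSpec("Th", "CTL", {"HD": 0.3, "SLE": 0.9}),
        ]
        config = sd.SimulationConfig(
            seed=seed + offset,
            group_sizes={"HD": 24, "pSS": 0, "SLE": 25},
            lr_events=events,
            n_deg=0,
            n_stim_genes=0,
            n_modules=0,
            module_sizes=(),
            n_markers=0,
            marker_log2fc=0.0,
            activity_effect={"Low": 0.0, "Moderate": 0.0, "High": 0.0},
            qc_dropout=0.0,
        )
        counts, lengths, samples, truth = sd.simulate_dataset(config)
        fpkm = pp.fpkm(counts, lengths)
        rel = pp.relative_expression(fpkm, samples)
        lr = sd.simulate_lr_table(truth, n_decoy_pairs=5, seed=seed + offset)
        occ = cc.detect_interactions(rel, fpkm, samples, lr)
        res = cc.interaction_group_test(occ, "HD", "SLE")
        tests = res.tests.set_index(["sender", "receiver", "ligand", "receptor"])
        planted_ligands = set()
        for event in truth.lr_events:
            key = (event["sender"], event["receiver"], event["ligand"],
                   event["receptor"])
            planted_ligands.add(event["ligand"])
            row = tests.loc[key]
            frac_hd.append(float(row["fraction_HD"]))
            frac_dis.append(float(row["fraction_SLE"]))
            planted_hits += bool(row["q"] <= 0.10)
            planted_n += 1
        # null = decoy pairs: neither gene belongs to a planted event
        null_rows = res.tests[~res.tests["ligand"].isin(planted_ligands)]
        null_hits += int((null_rows["q"] <= 0.10).sum())
        null_n += len(null_rows)
    return {
        "frac_hd": float(np.mean(frac_hd)),
        "frac_disease": float(np.mean(frac_dis)),
        "planted_q_rate": planted_hits / planted_n,
        "null_q_rate": null_hits / max(1, null_n),
        "null_n": null_n,
        "n": n_seeds,
    }


def end_to_end(seed: int = 0, outdir=None) -> dict:
    """Full pipeline on the default cohort; checks every declared output."""
    import tempfile
    import time
    from pathlib import Path

    expected = [
        "counts.tsv", "gene_lengths.tsv", "samples.tsv", "truth.json",
        "sets.gmt", "lr_pairs.tsv", "provenance.jsonl", "regscore.tsv",
        "clusters.tsv", "cluster_annotation.tsv", "interactions.tsv",
        "activity_stats.tsv",
    ]
    start = time.perf_counter()
    with tempfile.TemporaryDirectory() as tmp:
        target = Path(outdir) if outdir else Path(tmp)
        target.mkdir(parents=True, exist_ok=True)
        from stimprofiler.pipeline import run_pipeline

        run_pipeline(
            sd.SimulationConfig(seed=seed, qc_dropout=0.03), target, n_perm=2000
        )
        names = {p.name for p in target.iterdir()}
        missing = [n for n in expected if n not in names]
        has_deg = any(n.startswith("deg_") for n in names)
        has_gba = any(n.startswith("gba_") for n in names)
    elapsed = time.perf_counter() - start
    return {
        "missing_outputs": missing,
        "has_deg": has_deg,
        "has_gba": has_gba,
        "runtime_s": elapsed,
        "n": 1,
    }
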