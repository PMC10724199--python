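import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimprofiler import cellcomm as cc, preprocess as pp, synthetic_data as sd
from stimprofiler.genesets import GeneSetCatalog
from stimprofiler.matrix import ExpressionMatrix, validate_samples
from tests.conftest import small_config


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full enumeration over fixed margins."""
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


@pytest.fixture(scope="module")
def lr_dataset():
    events = [
        sd.LREventSpec("Th", "B", {"HD": 0.3, "SLE": 0.9}),
        sd.LREventSpec("CTL", "NK", {"HD": 0.2, "SLE": 0.8}),
    ]
    cfg = small_config(
        seed=81,
        group_sizes={"HD": 12, "pSS": 0, "SLE": 12},
        lr_events=events,
        n_deg=0,
        n_stim_genes=0,
    )
    counts, lengths, samples, truth = sd.simulate_dataset(cfg)
    fpkm = pp.fpkm(counts, lengths)
    rel = pp.relative_expression(fpkm, samples)
    lr = sd.simulate_lr_table(truth, n_decoy_pairs=5, seed=81)
    return rel, fpkm, samples, truth, lr


class TestDetectInteractions:
    def test_rank_rule_boundary(self):
        # 100 positive genes: rank 10 detected, rank 11 not (top 10%)
        genes = [f"g{i}" for i in range(120)]
        rel_vals = np.linspace(100, 100 - 119, 120)  # g0 highest ... strictly ordered
        samples = validate_samples(
            pd.DataFrame(
                {
                    "sample_id": [f"d1_{ct}_aCD3" for ct in ("Th", "CTL", "NK", "B")],
                    "donor_id": "d1",
                    "group": "HD",
                    "cell_type": ["Th", "CTL", "NK", "B"],
                    "condition": "aCD3",
                }
            )
        )
        rel_df = pd.DataFrame(
            {sid: rel_vals for sid in samples["sample_id"]}, index=genes
        )
        # exactly 100 positive values
        rel_df[rel_df < rel_vals[99]] = -1.0
        relative = ExpressionMatrix(rel_df, "relative")
        fpkm = ExpressionMatrix(
            pd.DataFrame(10.0, index=genes, columns=samples["sample_id"]), "fpkm"
        )
        lr = pd.DataFrame(
            {
                "ligand": ["g9", "g10"],
                "receptor": ["g0", "g1"],
                "category": ["Cytokines", "TNF"],
            }
        )
        occ = cc.detect_interactions(relative, fpkm, samples, lr)
        det = occ.flags.groupby("ligand")["detected"].any()
        assert bool(det["g9"]) is True  # rank 10 of 100
        assert bool(det["g10"]) is False  # rank 11 of 100

    def test_receptor_expression_required(self, lr_dataset):
        rel, fpkm, samples, truth, lr = lr_dataset
        occ_lo = cc.detect_interactions(rel, fpkm, samples, lr, receptor_min_fpkm=1.0)
        occ_hi = cc.detect_interactions(rel, fpkm, samples, lr, receptor_min_fpkm=1e9)
        assert not occ_hi.flags["detected"].any()
        assert occ_lo.flags["detected"].any()

    def test_monotone_in_top_fraction(self, lr_dataset):
        rel, fpkm, samples, truth, lr = lr_dataset
        small = cc.detect_interactions(rel, fpkm, samples, lr, ligand_top_fraction=0.05)
        large = cc.detect_interactions(rel, fpkm, samples, lr, ligand_top_fraction=0.20)
        merged = small.flags.merge(
            large.flags,
            on=["sender", "receiver", "ligand", "receptor", "group", "donor"],
            suffixes=("_small", "_large"),
        )
        assert not (merged["detected_small"] & ~merged["detected_large"]).any()

    def test_absent_pair_skipped(self, lr_dataset):
        rel, fpkm, samples, truth, lr = lr_dataset
        lr2 = pd.concat(
            [lr, pd.DataFrame([{"ligand": "NOPE", "receptor": "NADA",
                                "category": "others"}])],
            ignore_index=True,
        )
        occ = cc.detect_interactions(rel, fpkm, samples, lr2)
        assert "NOPE" not in set(occ.flags["ligand"])
        assert ("NOPE", "NADA") in occ.flags.attrs["skipped_pairs"]

    def test_planted_fractions_recovered(self, lr_dataset):
        rel, fpkm, samples, truth, lr = lr_dataset
        occ = cc.detect_interactions(rel, fpkm, samples, lr)
        frac = occ.fractions.set_index(
            ["sender", "receiver", "ligand", "receptor", "group"]
        )["fraction"]
        for event in truth.lr_events:
            key = (event["sender"], event["receiver"], event["ligand"],
                   event["receptor"])
            planted = pd.Series(event["planted"])
            for group in ("HD", "SLE"):
                donors = [d for d in planted.index if d.startswith(group)]
                expected = planted[donors].mean()
                assert frac[(*key, group)] == pytest.approx(expected, abs=0.25)


class TestInteractionGroupTest:
    def _occ_from_counts(self, det_a, n_a, det_b, n_b):
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

    def test_identical_fractions_p_one(self):
        occ = self._occ_from_counts(5, 10, 5, 10)
        res = cc.interaction_group_test(occ, "HD", "SLE")
        assert res.tests["p"].iloc[0] == pytest.approx(1.0)

    def test_paper_derived_table_matches_enumeration(self):
        # 5/13 detected vs 8/9 detected
        occ = self._occ_from_counts(5, 13, 8, 9)
        res = cc.interaction_group_test(occ, "HD", "SLE")
        expected = fisher_two_sided_oracle(5, 8, 8, 1)
        assert res.tests["p"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert res.tests["direction"].iloc[0] == "up"

    def test_group_swap_symmetry(self):
        occ = self._occ_from_counts(2, 10, 7, 12)
        ab = cc.interaction_group_test(occ, "HD", "SLE")
        ba = cc.interaction_group_test(occ, "SLE", "HD")
        assert ab.tests["p"].iloc[0] == pytest.approx(ba.tests["p"].iloc[0])
        assert {ab.tests["direction"].iloc[0], ba.tests["direction"].iloc[0]} == {
            "up",
            "down",
        }

    def test_fisher_matches_oracle_random_margins(self, rng):
        for _ in range(50):
            n_a, n_b = int(rng.integers(2, 16)), int(rng.integers(2, 16))
            det_a = int(rng.integers(0, n_a + 1))
            det_b = int(rng.integers(0, n_b + 1))
            if det_a + det_b == 0:
                continue
            occ = self._occ_from_counts(det_a, n_a, det_b, n_b)
            res = cc.interaction_group_test(occ, "HD", "SLE")
            expected = fisher_two_sided_oracle(
                det_a, n_a - det_a, det_b, n_b - det_b
            )
            assert res.tests["p"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestCommGeneEnrichment:
    def test_full_overlap_minimal_p(self):
        universe = [f"g{i}" for i in range(20)]
        comm = universe[:10]
        out = cc.comm_gene_enrichment(comm, [], comm, universe)
        up = out[out["direction"] == "up"].iloc[0]
        # one-tailed minimal p: all 10 comm genes drawn in a 10-gene query
        expected = 1 / math.comb(20, 10)
        assert up["p"] == pytest.approx(expected, abs=1e-12)

    def test_disjoint_up_set_not_enriched(self):
        universe = [f"g{i}" for i in range(20)]
        out = cc.comm_gene_enrichment(universe[10:14], [], universe[:10], universe)
        assert out[out["direction"] == "up"]["p"].iloc[0] >= 0.5

    def test_empty_up_set_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        out = cc.comm_gene_enrichment([], [], universe[:5], universe)
        assert out["p"].tolist() == [1.0, 1.0]


class TestCompareActivity:
    def _activity(self, rng, layer, shift=0.0, n=12):
        cols = {}
        rows_meta = []
        for group in ("HD", "SLE"):
            for i in range(n):
                sid = f"{group}{i}"
                cols[sid] = rng.normal(size=5) + (shift if group == "SLE" else 0.0)
                rows_meta.append((sid, sid, group, "B", "steady"))
        samples = validate_samples(
            pd.DataFrame(
                rows_meta,
                columns=["sample_id", "donor_id", "group", "cell_type", "condition"],
            )
        )
        values = pd.DataFrame(cols, index=[f"cyt{i}" for i in range(5)])
        return cc.ActivityMatrix(values, layer), samples

    def test_steady_layer_never_uses_ttest(self, rng):
        activity, samples = self._activity(rng, "steady")
        out = cc.compare_activity(activity, samples, "HD", "SLE")
        assert (out["test"] == "wilcoxon").all()

    def test_stimulated_layer_uses_ttest(self, rng):
        activity, samples = self._activity(rng, "stimulated")
        out = cc.compare_activity(activity, samples, "HD", "SLE")
        assert (out["test"] == "ttest").all()

    def test_identical_groups(self, rng):
        activity, samples = self._activity(rng, "steady")
        sym = activity.values.copy()
        for i in range(12):
            sym[f"SLE{i}"] = sym[f"HD{i}"]
        out = cc.compare_activity(
            cc.ActivityMatrix(sym, "steady"), samples, "HD", "SLE"
        )
        assert np.allclose(out["p"], 1.0)

    def test_planted_shift_detected(self, rng):
        activity, samples = self._activity(rng, "stimulated", shift=1.5)
        out = cc.compare_activity(activity, samples, "HD", "SLE")
        assert (out["q"] <= 0.10).all()

    def test_underpowered_refused(self, rng):
        activity, samples = self._activity(rng, "steady", n=2)
        with pytest.raises(ValueError, match="underpowered"):
            cc.compare_activity(activity, samples, "HD", "SLE")


def test_signature_activity_layer_dispatch(small_fpkm, small_dataset):
    _, _, samples, truth = small_dataset
    catalog = GeneSetCatalog({"SET": truth.ifn_genes})
    from stimprofiler.preprocess import centralize

    cen = centralize(small_fpkm)
    act = cc.signature_activity(cen, catalog)
    assert act.layer == "steady"
    assert act.values.shape[0] == 1
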