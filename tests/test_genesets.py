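import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stimprofiler import preprocess as pp, synthetic_data as sd
from stimprofiler import genesets as gs
from tests.conftest import small_config


class TestGMT:
    def test_parse_single_set(self, tmp_path):
        path = tmp_path / "a.gmt"
        path.write_text("S\td\tg1\tg2\n")
        catalog = gs.read_gmt(path)
        assert catalog.sets == {"S": ["g1", "g2"]}
        assert catalog.descriptions["S"] == "d"

    def test_duplicate_name_rejected(self, tmp_path):
        path = tmp_path / "a.gmt"
        path.write_text("S\td\tg1\nS\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate set name"):
            gs.read_gmt(path)

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "a.gmt"
        path.write_text("S\td\tg1\nBAD\tx\n")
        with pytest.raises(ValueError, match=":2"):
            gs.read_gmt(path)

    def test_roundtrip_on_simulated_catalog(self, tmp_path, small_dataset):
        *_, truth = small_dataset
        catalog = sd.simulate_genesets(truth, n_decoy_sets=5, seed=2)
        gs.write_gmt(catalog, tmp_path / "sets.gmt")
        back = gs.read_gmt(tmp_path / "sets.gmt")
        assert back.sets == catalog.sets
        assert back.descriptions == catalog.descriptions


class TestFilterSets:
    def test_too_small_removed(self):
        catalog = gs.GeneSetCatalog({"S": ["a", "b"]})
        assert "S" not in gs.filter_sets(catalog, {"a", "b", "c"}, 3, 500)

    def test_exact_max_retained(self):
        genes = [f"g{i}" for i in range(500)]
        catalog = gs.GeneSetCatalog({"S": genes})
        assert "S" in gs.filter_sets(catalog, set(genes), 3, 500)

    def test_universe_reduction(self):
        catalog = gs.GeneSetCatalog({"S": ["a", "b", "c", "z"]})
        out = gs.filter_sets(catalog, {"a", "b", "c"}, 3, 500)
        assert out["S"] == ["a", "b", "c"]


class TestORA:
    def test_full_overlap_enumeration_value(self):
        # universe 10, set 5, query 5, overlap 5 -> 1 / C(10,5)
        universe = [f"g{i}" for i in range(10)]
        catalog = gs.GeneSetCatalog({"S": universe[:5]})
        res = gs.ora(universe[:5], catalog, universe)
        assert res.loc["S", "p"] == pytest.approx(1 / 252, abs=1e-15)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        catalog = gs.GeneSetCatalog({"S": universe[:3]})
        res = gs.ora(universe[7:], catalog, universe)
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_size_rule_forces_p_one(self):
        universe = [f"g{i}" for i in range(400)]
        catalog = gs.GeneSetCatalog({"BIG": universe[:301], "TINY": universe[:2]})
        res = gs.ora(universe[:50], catalog, universe)
        assert res.loc["BIG", "p"] == 1.0
        assert res.loc["TINY", "p"] == 1.0
        assert res.loc["BIG", "q"] == 1.0

    def test_boundary_sizes_tested(self):
        universe = [f"g{i}" for i in range(400)]
        catalog = gs.GeneSetCatalog({"S300": universe[:300], "S3": universe[:3]})
        res = gs.ora(universe[:10], catalog, universe)
        assert res.loc["S300", "p"] < 1.0
        assert res.loc["S3", "p"] < 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            gs.ora(["a"], gs.GeneSetCatalog({"S": ["a"]}), [])

    def test_enumeration_oracle_small_universes(self, rng):
        # independent oracle: enumerate every possible query draw
        for _ in range(25):
            n_universe = int(rng.integers(4, 15))
            universe = [f"g{i}" for i in range(n_universe)]
            set_size = int(rng.integers(1, n_universe + 1))
            query_size = int(rng.integers(1, min(n_universe, 8) + 1))
            set_genes = list(rng.choice(universe, size=set_size, replace=False))
            query = list(rng.choice(universe, size=query_size, replace=False))
            observed = len(set(query) & set(set_genes))
            hits = total = 0
            for draw in itertools.combinations(universe, query_size):
                total += 1
                if len(set(draw) & set(set_genes)) >= observed:
                    hits += 1
            catalog = gs.GeneSetCatalog({"S": set_genes})
            res = gs.ora(query, catalog, universe, min_size=1, max_size=10**6)
            assert res.loc["S", "p"] == pytest.approx(hits / total, abs=1e-12)


class TestClassifyActivity:
    @pytest.mark.parametrize(
        "score,expected",
        [(1, "Low"), (3, "Low"), (4, "Moderate"), (7, "Moderate"),
         (8, "High"), (14, "High")],
    )
    def test_boundaries(self, score, expected):
        assert gs.classify_activity(score)[0] == expected

    def test_zero_score_flagged_low(self):
        cls, flags = gs.classify_activity(0)
        assert cls == "Low" and flags == ["zero-score"]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gs.classify_activity(-1)

    def test_high_cutoff_configurable(self):
        assert gs.classify_activity(8, high_cutoff=9)[0] == "Moderate"


class TestKSRegscore:
    def test_complete_separation(self):
        values = pd.Series({"a": 3.0, "b": 4.0, "c": 1.0, "d": 2.0})
        entry = gs.ks_regscore(values, ["a", "b"])
        assert entry.d == pytest.approx(1.0)

    def test_interleaved(self):
        values = pd.Series({"a": 1.0, "b": 3.0, "c": 2.0, "d": 4.0})
        assert abs(gs.ks_regscore(values, ["a", "b"]).d) == pytest.approx(0.5)

    def test_sign_convention(self, rng):
        background = {f"b{i}": v for i, v in enumerate(rng.normal(0, 1, 50))}
        shifted = {f"s{i}": v for i, v in enumerate(rng.normal(3, 1, 10))}
        values = pd.Series({**background, **shifted})
        entry = gs.ks_regscore(values, list(shifted))
        assert entry.d > 0.8  # set stochastically larger -> positive
        low = {f"s{i}": v for i, v in enumerate(rng.normal(-3, 1, 10))}
        values2 = pd.Series({**background, **low})
        assert gs.ks_regscore(values2, list(low)).d < -0.8

    def test_degenerate_profile_rejected(self):
        values = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        with pytest.raises(ValueError, match="degenerate"):
            gs.ks_regscore(values, ["a", "b"])

    def test_null_calibration(self, rng):
        # random subsets: D small on average; the direction-selected
        # one-sided p is valid at small thresholds (union bound over the
        # two directions doubles the nominal level)
        n = 300
        values = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        ps, ds = [], []
        for _ in range(400):
            subset = rng.choice(values.index, size=40, replace=False)
            entry = gs.ks_regscore(values, list(subset))
            ps.append(entry.p)
            ds.append(abs(entry.d))
        ps = np.array(ps)
        assert np.mean(ds) < 0.25
        assert (ps <= 0.05).mean() <= 0.10 + 2 * np.sqrt(0.1 * 0.9 / len(ps))
        assert (ps <= 0.20).mean() <= 0.40 + 2 * np.sqrt(0.4 * 0.6 / len(ps))

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_brute_force_equivalence(self, data):
        n = data.draw(st.integers(8, 60))
        k = data.draw(st.integers(3, n - 4))
        vals = data.draw(
            st.lists(
                st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n
            )
        )
        values = pd.Series(vals, index=[f"g{i}" for i in range(n)])
        if values.nunique() == 1:
            return
        entry = gs.ks_regscore(values, [f"g{i}" for i in range(k)])
        sv = np.array(vals[:k])
        bv = np.array(vals[k:])
        best = 0.0
        for t in vals:
            best = max(best, abs((bv <= t).mean() - (sv <= t).mean()))
        assert abs(entry.d) == pytest.approx(best, abs=1e-12)


@pytest.fixture(scope="module")
def profiled():
    cfg = small_config(
        seed=51,
        group_sizes={"HD": 4, "pSS": 12, "SLE": 12},
        ifn_set_size=20,
        activity_effect={"Low": 0.5, "Moderate": 1.0, "High": 2.0},
    )
    counts, lengths, samples, truth = sd.simulate_dataset(cfg)
    fpkm = pp.fpkm(counts, lengths)
    steady = list(samples.loc[samples["condition"] == "steady", "sample_id"])
    cen = pp.centralize(fpkm.subset(samples=steady))
    catalog = gs.GeneSetCatalog({"IFN_TYPE_I_SYNTH": truth.ifn_genes})
    return gs.activity_profile(cen, samples, catalog), samples


class TestActivityProfile:

    def test_monotone_trajectory(self, profiled):
        table, _ = profiled
        for _, chunk in table.groupby(["group", "cell_type"]):
            d = chunk.set_index("activity_class")["D"]
            if {"Low", "Moderate", "High"} <= set(d.index):
                assert d["Low"] < d["High"]

    def test_hd_excluded(self, profiled):
        table, _ = profiled
        assert "HD" not in set(table["group"])

    def test_class_ordering(self, profiled):
        table, _ = profiled
        order = {"Low": 0, "Moderate": 1, "High": 2}
        for _, chunk in table.groupby(["set", "group", "cell_type"]):
            codes = chunk["activity_class"].map(order).to_numpy()
            assert (np.diff(codes) > 0).all()

    def test_wrong_layer_rejected(self, small_fpkm, small_dataset):
        samples, truth = small_dataset[2], small_dataset[3]
        catalog = gs.GeneSetCatalog({"S": truth.ifn_genes})
        with pytest.raises(ValueError, match="centralized"):
            gs.activity_profile(small_fpkm, samples, catalog)


class TestDriverGenes:
    def _setup(self, rng, n_samples_per_class=4):
        genes = [f"g{i}" for i in range(10)]
        rows, cols = [], {}
        sample_idx = 0
        for cls in ("Low", "Moderate", "High"):
            for _ in range(n_samples_per_class):
                sid = f"s{sample_idx}"
                sample_idx += 1
                rows.append((sid, f"d{sample_idx}", "SLE", "B", "steady", 1, cls))
                cols[sid] = rng.normal(size=10) * 0.01
        samples = pd.DataFrame(
            rows,
            columns=["sample_id", "donor_id", "group", "cell_type",
                     "condition", "activity_score", "activity_class"],
        )
        values = pd.DataFrame(cols, index=genes)
        return genes, samples, values

    def test_big_range_gene_selected(self, rng):
        from stimprofiler.matrix import ExpressionMatrix, validate_samples

        genes, samples, values = self._setup(rng)
        high_ids = samples.loc[samples["activity_class"] == "High", "sample_id"]
        values.loc["g0", high_ids] += 10.0
        m = ExpressionMatrix(values, "centralized")
        out = gs.driver_genes(m, validate_samples(samples), genes, 0.10)
        assert out == ["g0"]

    def test_constant_gene_never_selected(self, rng):
        from stimprofiler.matrix import ExpressionMatrix, validate_samples

        genes, samples, values = self._setup(rng)
        values.loc["g1"] = 0.0
        for g in genes:
            if g != "g1":
                values.loc[g] += rng.normal(size=len(values.columns))
        m = ExpressionMatrix(values, "centralized")
        out = gs.driver_genes(m, validate_samples(samples), genes, 0.5)
        assert "g1" not in out

    def test_needs_two_classes(self, rng):
        from stimprofiler.matrix import ExpressionMatrix, validate_samples

        genes, samples, values = self._setup(rng)
        samples["activity_class"] = "Low"
        samples["sample_id"] = [f"s{i}" for i in range(len(samples))]
        m = ExpressionMatrix(values, "centralized")
        with pytest.raises(ValueError, match="two populated"):
            gs.driver_genes(m, validate_samples(samples), genes)


def test_bh_row_order_invariance(rng):
    from stimprofiler._stats import bh_adjust

    p = rng.uniform(size=200)
    q = bh_adjust(p)
    perm = rng.permutation(200)
    assert np.allclose(bh_adjust(p[perm]), q[perm])
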