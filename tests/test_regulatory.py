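import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from neutrokit import (RegulatoryModel, ValidationError, bh_adjust,
                       hcluster_matrix, module_bin_enrichment,
                       pair_enrichment, regulator_cluster_matrix,
                       select_regulators)


def _model(module_genes: dict, regulator_modules: dict) -> RegulatoryModel:
    targets = pd.Series({g: m for m, genes in module_genes.items()
                         for g in genes})
    rows = [(r, m, 1.0) for r, mods in regulator_modules.items() for m in mods]
    assoc = pd.DataFrame(rows, columns=["regulator_id", "module_id", "weight"])
    return RegulatoryModel(targets, assoc)


@pytest.fixture
def toy_model():
    return _model(
        {"m1": ["a", "b"], "m2": ["c"], "m3": ["d"]},
        {"R1": ["m1"], "R2": ["m2", "m3"]},
    )


class TestModelValidation:
    def test_module_without_regulator_rejected(self):
        with pytest.raises(ValidationError, match="m2"):
            _model({"m1": ["a"], "m2": ["b"]}, {"R1": ["m1"]})

    def test_gene_in_two_modules_rejected(self):
        targets = pd.Series(["m1", "m2"], index=["a", "a"])
        assoc = pd.DataFrame([("R", "m1", 1.0), ("R", "m2", 1.0)],
                             columns=["regulator_id", "module_id", "weight"])
        with pytest.raises(ValidationError, match="a"):
            RegulatoryModel(targets, assoc)

    def test_pair_counts_derived_from_modules(self, toy_model):
        pairs = toy_model.max_pairs_per_regulator
        assert pairs["R1"] == 2  # m1 has two targets
        assert pairs["R2"] == 2  # m2 + m3, one each
        assert toy_model.total_pairs == 4

    def test_round_trip(self, toy_model, tmp_path):
        toy_model.save(tmp_path / "t.tsv", tmp_path / "r.tsv")
        loaded = RegulatoryModel.load(tmp_path / "t.tsv", tmp_path / "r.tsv")
        assert loaded.targets.sort_index().equals(
            toy_model.targets.sort_index())


class TestModuleBinEnrichment:
    def test_matches_exact_hypergeometric_tail(self, toy_model):
        """Drawing both genes of the 2-gene module from 4 targets:
        P(count >= 2) = C(2,2)/C(4,2) = 1/6."""
        res = module_bin_enrichment(["a", "b"], toy_model, n_perm=10_000,
                                    seed=1)
        exact = 1 / 6
        mc_se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(res.loc["m1", "p"] - exact) < 3 * mc_se + 2e-4

    def test_saturated_list_gives_p_one(self, toy_model):
        res = module_bin_enrichment(["a", "b", "c", "d"], toy_model,
                                    n_perm=500, seed=0)
        assert (res["observed"] == res["size"]).all()
        assert (res["p"] == 1.0).all()

    def test_non_target_genes_dropped_with_count(self, toy_model):
        res = module_bin_enrichment(["a", "not_in_model"], toy_model,
                                    n_perm=200, seed=0)
        assert res.attrs["x"] == 1
        assert res.attrs["n_dropped"] == 1

    def test_empty_intersection_rejected(self, toy_model):
        with pytest.raises(ValidationError):
            module_bin_enrichment(["nope"], toy_model, n_perm=100, seed=0)


class TestPairEnrichment:
    def test_hand_computed_chi_square(self):
        """R1 and R2 each with 10 maximum pairs; the list generates 8
        R1-pairs and 2 R2-pairs -> table [[8,2],[2,8]], chi2 = 7.2."""
        model = _model(
            {"mA": [f"a{i}" for i in range(10)],
             "mB": [f"b{i}" for i in range(10)]},
            {"R1": ["mA"], "R2": ["mB"]},
        )
        genes = [f"a{i}" for i in range(8)] + ["b0", "b1"]
        res = pair_enrichment(genes, model)
        assert res.loc["R1", "observed"] == 8
        assert res.loc["R1", "statistic"] == pytest.approx(7.2)
        from scipy.stats import chi2
        assert res.loc["R1", "p"] == pytest.approx(chi2.sf(7.2, 1), rel=1e-9)

    def test_proportional_list_gives_p_one(self):
        model = _model(
            {"mA": [f"a{i}" for i in range(10)],
             "mB": [f"b{i}" for i in range(10)]},
            {"R1": ["mA"], "R2": ["mB"]},
        )
        genes = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        res = pair_enrichment(genes, model)
        assert res["statistic"].fillna(0).max() == pytest.approx(0.0)
        assert (res["p"] > 0.99).all()

    def test_total_pairs_conserved(self, synthetic_default):
        _, _, truth, model, _ = synthetic_default
        genes = list(truth.index[truth["role"] == "archetype"])
        res = pair_enrichment(genes, model)
        hits = pd.Index(genes).intersection(model.targets.index)
        per_gene = model.targets.loc[hits].map(model.regulators_per_module)
        assert res["observed"].sum() == per_gene.sum()
        assert res.attrs["total_pairs_in_list"] == per_gene.sum()


class TestSelection:
    def _results(self, pair_rows, module_rows, model):
        pair = pd.DataFrame(pair_rows, columns=["regulator_id", "q",
                                                "over"]).set_index(
                                                    "regulator_id")
        module = pd.DataFrame(module_rows,
                              columns=["module_id", "q"]).set_index(
                                  "module_id")
        return {"up": pair}, {"up": module}

    def test_pair_hit_without_enriched_module_excluded(self, toy_model):
        pair, module = self._results([("R1", 0.001, True)], [("m1", 0.9)],
                                     toy_model)
        assert select_regulators(pair, module, toy_model) == []

    def test_module_hit_without_pair_significance_excluded(self, toy_model):
        pair, module = self._results([("R1", 0.5, True)], [("m1", 0.001)],
                                     toy_model)
        assert select_regulators(pair, module, toy_model) == []

    def test_dual_signal_regulator_included(self, toy_model):
        pair, module = self._results([("R1", 0.001, True)], [("m1", 0.001)],
                                     toy_model)
        assert select_regulators(pair, module, toy_model) == ["R1"]


class TestPMatrix:
    def test_extreme_enrichment_and_empty_cluster(self):
        model = _model(
            {"mA": [f"a{i}" for i in range(20)],
             "mB": [f"b{i}" for i in range(20)]},
            {"R1": ["mA"], "R2": ["mB"]},
        )
        clusters = {
            "c_hit": [f"a{i}" for i in range(20)],
            "c_none": ["zz1", "zz2"],
        }
        matrix, flagged = regulator_cluster_matrix(clusters, ["R1", "R2"],
                                                   model)
        assert matrix.loc["R1", "c_hit"] < 1e-4
        assert (matrix["c_none"] == 1.0).all()
        assert flagged == ["c_none"]

    def test_null_clusters_give_uniformish_entries(self, synthetic_default):
        _, _, _, model, _ = synthetic_default
        rng = np.random.default_rng(17)
        regs = model.regulator_ids[:10]
        clusters = {
            f"c{i}": list(rng.choice(model.targets.index, 60, replace=False))
            for i in range(5)
        }
        matrix, _ = regulator_cluster_matrix(clusters, regs, model)
        # raw p-values under the null should not pile up near zero
        assert (matrix.to_numpy() < 0.01).mean() < 0.1


class TestHCluster:
    def test_two_by_two_single_merge_each_axis(self):
        m = pd.DataFrame([[1e-6, 0.9], [0.8, 1e-5]],
                         index=["r1", "r2"], columns=["c1", "c2"])
        res = hcluster_matrix(m)
        assert len(res.row_linkage) == 1 and len(res.col_linkage) == 1
        assert set(res.row_order) == {"r1", "r2"}

    def test_block_structure_separates_groups(self):
        rng = np.random.default_rng(4)
        lo, hi = 1e-8, 0.8
        block = np.full((6, 6), hi)
        block[:3, :3] = lo
        block[3:, 3:] = lo
        jitter = rng.uniform(1.0, 1.5, size=block.shape)
        m = pd.DataFrame(block * jitter,
                         index=[f"r{i}" for i in range(6)],
                         columns=[f"c{i}" for i in range(6)])
        res = hcluster_matrix(m)
        rows = [res.row_order.index(f"r{i}") for i in range(6)]
        assert ({rows[0], rows[1], rows[2]} == {0, 1, 2}
                or {rows[0], rows[1], rows[2]} == {3, 4, 5})

    def test_row_permutation_preserves_block_contiguity(self):
        lo, hi = 1e-8, 0.8
        block = np.full((6, 4), hi)
        block[:3, :2] = lo
        block[3:, 2:] = lo
        m = pd.DataFrame(block, index=[f"r{i}" for i in range(6)],
                         columns=[f"c{i}" for i in range(4)])
        shuffled = m.iloc[[3, 0, 4, 1, 5, 2]]
        res = hcluster_matrix(shuffled)
        first_half = set(res.row_order[:3])
        assert first_half in ({"r0", "r1", "r2"}, {"r3", "r4", "r5"})

    def test_degenerate_matrix_flagged(self):
        m = pd.DataFrame(np.full((3, 3), 0.5))
        res = hcluster_matrix(m)
        assert res.degenerate


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            ours = bh_adjust(p)
            theirs = sm.multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs, atol=1e-12)

    def test_rejections_match_stepup_rule(self):
        """q < alpha reproduces the classical step-up rejection set."""
        rng = np.random.default_rng(11)
        alpha = 0.05
        for _ in range(50):
            p = rng.uniform(size=8) ** rng.uniform(0.5, 3)
            q = bh_adjust(p)
            order = np.argsort(p)
            n = len(p)
            k = 0
            for i, idx in enumerate(order, start=1):
                if p[idx] <= alpha * i / n:
                    k = i
            rejected_oracle = set(order[:k])
            assert set(np.where(q < alpha)[0]) <= rejected_oracle
            assert set(np.where(q <= alpha)[0]) >= rejected_oracle
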