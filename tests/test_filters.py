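import math

import numpy as np
import pandas as pd
import pytest

from neutrokit import (ExpressionMatrix, ValidationError,
                       category_count_compare, condition_correlation,
                       condition_specific_genes, fold_vs_reference,
                       variation_filter, venn_counts)


def _matrix(gene_rows: dict, conditions=("BL", "SF", "UA", "TG"), reps=3):
    """Build a neutrophil-only ExpressionMatrix from per-gene replicate rows."""
    columns = [f"{c}_r{i}" for c in conditions for i in range(reps)]
    values = pd.DataFrame(gene_rows, index=columns).T
    values.index.name = "gene_id"
    pops = pd.DataFrame({
        "population_id": [c.split("_")[0] for c in columns],
        "group_class": ["neutrophil"] * len(columns),
        "condition": [c.split("_")[0] for c in columns],
    }, index=pd.Index(columns, name="sample_id"))
    return ExpressionMatrix(values.astype(float), pops)


class TestVariationFilter:
    def test_constant_gene_fails_anova_and_fold(self):
        m = _matrix({"flat": [500.0] * 12})
        res = variation_filter(m, ["BL", "SF", "UA", "TG"])
        row = res.table.loc["flat"]
        assert not row["pass_anova"] and not row["pass_fold"]
        assert row["pass_presence"] and row["pass_cv"]

    def test_strong_condition_effect_passes_all_four(self):
        # condition means (100, 100, 100, 300) with tight replicates
        rows = {"hit": [98, 100, 102, 99, 100, 101, 100, 102, 98,
                        295, 300, 305]}
        m = _matrix(rows)
        res = variation_filter(m, ["BL", "SF", "UA", "TG"])
        assert res.table.loc["hit", "pass_all"]
        # check the ANOVA p against a textbook F computation on log2 values
        groups = [np.log2(np.array(rows["hit"][i * 3:(i + 1) * 3], float))
                  for i in range(4)]
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_stat = (ss_between / 3) / (ss_within / 8)
        from scipy.stats import f as f_dist
        p_oracle = f_dist.sf(f_stat, 3, 8)
        assert res.table.loc["hit", "anova_p"] == pytest.approx(p_oracle,
                                                                rel=1e-9)

    def test_below_threshold_gene_fails_presence(self):
        rows = {"dim": [50, 52, 48, 90, 88, 92, 60, 61, 59, 100, 99, 101]}
        res = variation_filter(_matrix(rows), ["BL", "SF", "UA", "TG"])
        assert not res.table.loc["dim", "pass_presence"]
        assert not res.table.loc["dim", "pass_all"]

    def test_filter_is_intersection_of_flags(self, synthetic_default):
        _, matrix, _, _, _ = synthetic_default
        res = variation_filter(matrix,
                               matrix.populations_of_class("neutrophil"))
        t = res.table
        combined = (t["pass_presence"] & t["pass_anova"]
                    & t["pass_fold"] & t["pass_cv"])
        assert (t["pass_all"] == combined).all()
        assert len(res.genes) == combined.sum()

    def test_single_replicate_condition_rejected(self):
        columns = ["A_r0", "A_r1", "B_r0"]
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=columns)
        pops = pd.DataFrame({
            "population_id": ["A", "A", "B"],
            "group_class": ["neutrophil"] * 3,
            "condition": ["BL", "BL", "SF"],
        }, index=pd.Index(columns, name="sample_id"))
        m = ExpressionMatrix(values, pops)
        with pytest.raises(ValidationError, match="B"):
            variation_filter(m, ["A", "B"])


class TestFoldVsReference:
    def test_arithmetic_and_identity(self):
        means = pd.DataFrame({"BL": [120.0, 50.0], "SF": [240.0, 50.0]},
                             index=["g1", "g2"])
        fc = fold_vs_reference(means, ["SF", "BL"], "BL")
        assert fc.loc["g1", "SF"] == pytest.approx(2.0)
        assert (fc["BL"] == 1.0).all()

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        means = pd.DataFrame(rng.uniform(10, 500, (20, 4)),
                             columns=["BL", "SF", "UA", "TG"],
                             index=[f"g{i}" for i in range(20)])
        fc = fold_vs_reference(means, ["SF", "UA", "TG"], "BL")
        for g in means.index:
            for c in ("SF", "UA", "TG"):
                assert fc.loc[g, c] == pytest.approx(
                    means.loc[g, c] / means.loc[g, "BL"])


class TestConditionCorrelation:
    def test_self_comparison_is_identity(self):
        x = [1.0, 2.0, 4.0, 8.0, 3.0]
        res = condition_correlation(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_power_law_gives_slope_two(self):
        x = np.array([1.0, 2.0, 4.0, 0.5, 8.0])
        res = condition_correlation(x, x ** 2)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_recovers_known_log_scale_correlation(self):
        rng = np.random.default_rng(2024)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        z = rng.multivariate_normal([0, 0], cov, size=200)
        res = condition_correlation(2.0 ** z[:, 0], 2.0 ** z[:, 1])
        assert res.r == pytest.approx(0.8, abs=0.1)
        assert res.slope_ci[0] < res.slope < res.slope_ci[1]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            condition_correlation([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def _brute_force_regions(fc, strict, relaxed, direction):
    """Exhaustive per-gene classification oracle for the Venn rule."""
    conds = list(fc.columns)
    counts = {frozenset(s): 0 for s in
              [(a,) for a in conds]
              + [(a, b) for i, a in enumerate(conds) for b in conds[i + 1:]]
              + [tuple(conds)]}
    for _, row in fc.iterrows():
        f = {c: (1 / row[c] if direction == "down" else row[c])
             for c in conds}
        s = {c for c in conds if f[c] > strict}
        if not s:
            continue
        if relaxed is None:
            counts[frozenset(s)] += 1
            continue
        r = {c for c in conds if f[c] > relaxed}
        if r == set(conds):
            counts[frozenset(conds)] += 1
        else:
            counts[frozenset(s | r)] += 1
    return counts


class TestVennCounts:
    def test_no_change_anywhere_gives_empty_regions(self):
        fc = pd.DataFrame(np.ones((5, 3)), columns=["SF", "UA", "TG"])
        counts = venn_counts(fc, strict=2.0)
        assert all(v == 0 for v in counts.values())

    def test_relaxed_rule_promotes_partial_hits(self):
        fc = pd.DataFrame([[2.5, 1.2, 1.7]], columns=["SF", "UA", "TG"])
        strict = venn_counts(fc, strict=2.0)
        assert strict[frozenset(["SF"])] == 1
        relaxed = venn_counts(fc, strict=2.0, relaxed=1.5)
        assert relaxed[frozenset(["SF", "TG"])] == 1
        assert relaxed[frozenset(["SF"])] == 0

    @pytest.mark.parametrize("relaxed", [None, 1.5])
    @pytest.mark.parametrize("direction", ["up", "down"])
    def test_matches_brute_force_oracle(self, relaxed, direction):
        rng = np.random.default_rng(8)
        fc = pd.DataFrame(2.0 ** rng.normal(0, 1.2, size=(300, 3)),
                          columns=["SF", "UA", "TG"])
        got = venn_counts(fc, strict=2.0, relaxed=relaxed,
                          direction=direction)
        oracle = _brute_force_regions(fc, 2.0, relaxed, direction)
        assert got == oracle
        # regions sum to the genes passing strict in >= 1 condition
        f = 1.0 / fc if direction == "down" else fc
        assert sum(got.values()) == int((f > 2.0).any(axis=1).sum())

    def test_relaxed_shared_regions_contain_strict_shared(self):
        rng = np.random.default_rng(9)
        fc = pd.DataFrame(2.0 ** rng.normal(0, 1.2, size=(400, 3)),
                          columns=["SF", "UA", "TG"])
        strict = venn_counts(fc, strict=2.0)
        relaxed = venn_counts(fc, strict=2.0, relaxed=1.5)
        n_shared = lambda counts: sum(v for k, v in counts.items()
                                      if len(k) >= 2)
        assert n_shared(relaxed) >= n_shared(strict)

    def test_wrong_condition_count_rejected(self):
        fc = pd.DataFrame(np.ones((2, 2)), columns=["SF", "UA"])
        with pytest.raises(ValidationError):
            venn_counts(fc, strict=2.0)


class TestConditionSpecific:
    def test_constructed_specific_gene(self):
        means = pd.DataFrame(
            {"SF": [800.0, 200.0], "TG": [300.0, 200.0],
             "UA": [200.0, 200.0], "BL": [100.0, 200.0]},
            index=["sf_gene", "flat"])
        hits = condition_specific_genes(means, "SF", ["TG", "UA"], "BL", 2.0)
        assert list(hits) == ["sf_gene"]

    def test_planted_archetypes_recovered_at_zero_noise(self,
                                                        synthetic_clean):
        from neutrokit import population_means
        _, matrix, truth = synthetic_clean
        means = population_means(matrix)
        hits = set(condition_specific_genes(means, "SF", ["TG", "UA"],
                                            "BL", 2.0))
        planted = set(truth.index[truth["archetype"] == "sf_only"])
        # sf_only genes are 4-fold up in SF only; the mixed archetype is
        # 4-fold up in SF but down in UA, hence also SF-specific by >= 2x
        mixed = set(truth.index[truth["archetype"] == "mixed"])
        assert planted <= hits <= planted | mixed


class TestCategoryCounts:
    def test_identical_proportions_give_p_one(self):
        assert category_count_compare(5, 50, 5, 50) == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # [[10, 0], [0, 10]]: only tables with X=10 or X=0 are as extreme
        p_exact = 2 * math.comb(10, 10) * math.comb(10, 0) / math.comb(20, 10)
        got = category_count_compare(10, 10, 0, 10, method="fisher")
        assert got == pytest.approx(p_exact, rel=1e-9)

    def test_chisq_and_fisher_agree_in_direction(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            k1, k2 = rng.integers(20, 80, size=2)
            p_f = category_count_compare(int(k1), 100, int(k2), 100,
                                         method="fisher")
            p_c = category_count_compare(int(k1), 100, int(k2), 100,
                                         method="chisq")
            assert (p_f < 0.05) == (p_c < 0.05) or abs(p_f - p_c) < 0.05

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            category_count_compare(11, 10, 1, 10)
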