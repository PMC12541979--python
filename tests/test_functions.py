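import numpy as np
import pandas as pd
import pytest

from coresat import (abundant_pathways, aggregate_to_pathways, clr_transform,
                     compare_pathways, pathway_pcoa, bray_curtis, pcoa,
                     satellite_exclusive_pathways, stratify_by_partition)


def _contrib(records):
    return pd.DataFrame(records, columns=["sample_id", "taxon_id",
                                          "function_id", "abundance"])


class TestAggregate:
    def test_additivity_within_pathway(self):
        c = _contrib([("s1", "t1", "K1", 3.0), ("s1", "t1", "K2", 7.0)])
        mapping = {"K1": ["pwA"], "K2": ["pwA"]}
        out = aggregate_to_pathways(c, mapping, normalize=False)
        assert out.loc["pwA", "s1"] == pytest.approx(10.0)

    def test_multi_pathway_ko_counts_fully_in_each(self):
        c = _contrib([("s1", "t1", "K1", 4.0)])
        out = aggregate_to_pathways(c, {"K1": ["pwA", "pwB"]}, normalize=False)
        assert out.loc["pwA", "s1"] == out.loc["pwB", "s1"] == 4.0

    def test_unmapped_ko_excluded_and_counted(self):
        c = _contrib([("s1", "t1", "K1", 3.0), ("s1", "t1", "Kx", 5.0)])
        out = aggregate_to_pathways(c, {"K1": ["pwA"]}, normalize=False)
        assert "Kx" not in out.index
        assert out.attrs["n_unmapped_functions"] == 1

    def test_empty_mapping_errors(self):
        c = _contrib([("s1", "t1", "K1", 3.0)])
        with pytest.raises(ValueError, match="empty"):
            aggregate_to_pathways(c, {})

    def test_normalized_columns_sum_100(self, small_cohort):
        _, _, _, contrib = small_cohort
        out = aggregate_to_pathways(contrib)
        assert np.allclose(out.sum(axis=0), 100.0, atol=1e-9)


class TestStratify:
    def test_core_only_contributions_empty_satellite(self):
        c = _contrib([("s1", "t1", "P1", 3.0), ("s1", "t2", "P1", 2.0)])
        labels = pd.Series({"t1": "core", "t2": "core"})
        sat = stratify_by_partition(c, labels, "satellite", normalize=False)
        assert sat.shape[1] == 0 or (sat.to_numpy() == 0).all()

    def test_whole_equals_core_plus_satellite_before_normalization(
            self, small_cohort):
        _, m, truth, contrib = small_cohort
        labels = truth.labels.iloc[:, 0]
        whole = stratify_by_partition(contrib, labels, "whole", normalize=False)
        core = stratify_by_partition(contrib, labels, "core", normalize=False)
        sat = stratify_by_partition(contrib, labels, "satellite", normalize=False)
        rebuilt = core.reindex_like(whole).fillna(0) + \
            sat.reindex(index=whole.index, columns=whole.columns, fill_value=0)
        assert np.allclose(rebuilt, whole)

    def test_planted_exclusive_pathway_absent_from_core(self, small_cohort):
        _, _, truth, contrib = small_cohort
        labels = truth.labels.iloc[:, 0]
        core = stratify_by_partition(contrib, labels, "core", normalize=False)
        for pid in truth.satellite_exclusive_pathways:
            assert pid not in core.index or (core.loc[pid] == 0).all()


class TestAbundantPathways:
    def test_exact_threshold_excluded(self):
        t = pd.DataFrame({"s1": [1.0, 99.0]}, index=["rare", "common"])
        kept = abundant_pathways(t, 1.0)
        assert "rare" not in kept.index  # exactly 1 % -> strict > excludes

    def test_single_pathway_kept(self):
        t = pd.DataFrame({"s1": [42.0]}, index=["only"])
        assert list(abundant_pathways(t, 1.0).index) == ["only"]

    def test_matches_brute_force_share(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.uniform(0, 5, size=(20, 6)),
                         index=[f"p{i}" for i in range(20)])
        kept = abundant_pathways(t, 1.0)
        shares = 100 * t.sum(axis=1) / t.to_numpy().sum()
        assert set(kept.index) == set(shares.index[shares > 1.0])

    def test_zero_threshold_keeps_everything_positive(self):
        t = pd.DataFrame({"s1": [0.5, 0.0]}, index=["a", "b"])
        assert list(abundant_pathways(t, 0.0).index) == ["a"]


class TestExclusive:
    def test_brute_force_set_comparison(self):
        rng = np.random.default_rng(1)
        core = pd.DataFrame(rng.integers(0, 2, size=(10, 4)).astype(float),
                            index=[f"p{i}" for i in range(10)])
        sat = pd.DataFrame(rng.integers(0, 2, size=(12, 4)).astype(float),
                           index=[f"p{i}" for i in range(12)])
        got = satellite_exclusive_pathways(core, sat)
        expected = sorted(
            p for p in sat.index
            if (sat.loc[p] > 0).any()
            and (p not in core.index or (core.loc[p] == 0).all())
        )
        assert got == expected


class TestClr:
    def test_equal_composition_all_zero(self):
        t = pd.DataFrame({"s1": [25.0, 25.0, 25.0, 25.0]})
        assert np.allclose(clr_transform(t), 0.0)

    def test_hand_evaluation(self):
        t = pd.DataFrame({"s1": [1.0, 1.0, 4.0]})
        out = clr_transform(t)["s1"].to_numpy()
        g = 4 ** (1 / 3)
        assert out == pytest.approx(np.log([1 / g, 1 / g, 4 / g]), abs=1e-10)

    def test_per_sample_sums_zero_with_zero_replacement(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.uniform(0, 3, size=(15, 8)))
        t[t < 0.5] = 0.0
        t = t.loc[t.sum(axis=1) > 0, t.sum(axis=0) > 0]
        t = 100 * t / t.sum()
        out = clr_transform(t)
        assert np.abs(out.sum(axis=0)).max() < 1e-9

    def test_matches_scikit_bio_when_dense(self):
        comp = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.uniform(1, 5, size=(6, 4)))
        ours = clr_transform(t).to_numpy()
        theirs = comp.clr(t.to_numpy().T).T
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_all_zero_sample_errors(self):
        t = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]})
        with pytest.raises(ValueError, match="s2"):
            clr_transform(t)


class TestComparePathways:
    def _planted(self):
        rng = np.random.default_rng(4)
        n_per = 10
        cols = [f"{g}{i}" for g in ("a", "b", "c") for i in range(n_per)]
        X = pd.DataFrame(rng.normal(size=(12, 30)), columns=cols,
                         index=[f"p{i}" for i in range(12)])
        X.loc["p0", [c for c in cols if c.startswith("b")]] += 3.0
        groups = pd.Series({c: c[0] for c in cols})
        return X, groups

    @pytest.mark.parametrize("test", ["kw", "anova"])
    def test_planted_shift_ranks_first(self, test):
        X, groups = self._planted()
        out = compare_pathways(X, groups, test=test)
        assert out.index[0] == "p0"
        assert out["adjusted_pvalue"].iloc[0] < 0.01

    def test_pairwise_bonferroni_multiplier(self):
        X, groups = self._planted()
        out = compare_pathways(X, groups, test="kw")
        assert np.allclose(out["p_adj_a_vs_b"],
                           np.minimum(1.0, out["p_a_vs_b"] * 3))

    def test_constant_pathway_skipped(self):
        X, groups = self._planted()
        X.loc["p1"] = 5.0
        out = compare_pathways(X, groups)
        assert "p1" not in out.index

    def test_null_table_yields_no_discoveries(self):
        rng = np.random.default_rng(5)
        cols = [f"{g}{i}" for g in ("a", "b", "c") for i in range(8)]
        X = pd.DataFrame(rng.normal(size=(40, 24)), columns=cols)
        groups = pd.Series({c: c[0] for c in cols})
        out = compare_pathways(X, groups)
        assert (out["adjusted_pvalue"] <= 0.05).sum() <= 1


class TestPathwayPcoa:
    def test_identical_profiles_collapse_to_origin(self):
        t = pd.DataFrame({f"s{i}": [30.0, 70.0] for i in range(4)},
                         index=["p1", "p2"])
        res, _ = pathway_pcoa(t)
        assert np.allclose(res.coordinates.to_numpy(), 0.0, atol=1e-8)

    def test_two_planted_clusters_strong_anosim(self):
        rng = np.random.default_rng(6)
        a = {f"a{i}": [80, 10, 10] + rng.normal(0, 1, 3) for i in range(5)}
        b = {f"b{i}": [10, 10, 80] + rng.normal(0, 1, 3) for i in range(5)}
        t = pd.DataFrame({**a, **b}, index=["p1", "p2", "p3"]).clip(lower=0)
        groups = pd.Series({c: c[0] for c in t.columns})
        res, an = pathway_pcoa(t, groups, n_perm=99, seed=0)
        assert an.r > 0.5

    def test_composition_oracle(self, small_cohort):
        _, m, _, contrib = small_cohort
        from coresat import aggregate_to_pathways
        t = aggregate_to_pathways(contrib)
        res, _ = pathway_pcoa(t)
        manual = pcoa(bray_curtis(t))
        assert np.allclose(np.abs(res.coordinates.to_numpy()),
                           np.abs(manual.coordinates.to_numpy()), atol=1e-10)
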