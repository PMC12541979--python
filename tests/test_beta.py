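import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from coresat import (CountMatrix, anosim, bray_curtis, confidence_ellipse,
                     group_similarity_summary, pairwise_anosim, pcoa, simper,
                     to_relative_abundance)
from coresat.beta import DistanceMatrix


def _dm(arr, ids):
    return DistanceMatrix(pd.DataFrame(arr, index=ids, columns=ids))


def _random_distance(rng, n):
    pts = rng.uniform(0, 1, size=(n, 3))
    d = squareform(pdist(pts, metric="braycurtis"))
    ids = [f"s{i}" for i in range(n)]
    return _dm(d, ids), ids


class TestBrayCurtis:
    def test_identical_samples_similarity_one(self):
        X = pd.DataFrame({"s1": [1, 2, 3], "s2": [1, 2, 3]},
                         index=["a", "b", "c"], dtype=float)
        D = bray_curtis(X)
        assert D.similarity().loc["s1", "s2"] == pytest.approx(1.0)

    def test_disjoint_support_similarity_zero(self):
        X = pd.DataFrame({"s1": [1, 0.0], "s2": [0, 2.0]}, index=["a", "b"])
        D = bray_curtis(X)
        assert D.data.loc["s1", "s2"] == pytest.approx(1.0)

    def test_hand_evaluation(self):
        X = pd.DataFrame({"s1": [1, 2, 3.0], "s2": [3, 2, 1.0]},
                         index=["a", "b", "c"])
        D = bray_curtis(X)
        assert D.data.loc["s1", "s2"] == pytest.approx(4 / 12)

    def test_counts_normalized_first(self, random_matrix):
        D1 = bray_curtis(random_matrix)
        D2 = bray_curtis(to_relative_abundance(random_matrix))
        assert np.allclose(D1.data, D2.data)


class TestGroupSimilarity:
    def test_all_identical(self):
        X = pd.DataFrame({f"s{i}": [1, 2.0] for i in range(4)},
                         index=["a", "b"])
        D = bray_curtis(X)
        g = pd.Series({f"s{i}": ("g1" if i < 2 else "g2") for i in range(4)})
        out = group_similarity_summary(D, g)
        assert np.allclose(out["mean_similarity"], 1.0)
        assert np.allclose(out["sd_similarity"], 0.0)

    def test_block_structure(self):
        X = pd.DataFrame(
            {"a1": [1, 0.0], "a2": [1, 0.0], "b1": [0, 1.0], "b2": [0, 1.0]},
            index=["t1", "t2"])
        D = bray_curtis(X)
        g = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        out = group_similarity_summary(D, g).set_index(["group_a", "group_b"])
        assert out.loc[("A", "A"), "mean_similarity"] == pytest.approx(1.0)
        assert out.loc[("A", "B"), "mean_similarity"] == pytest.approx(0.0)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        D, ids = _random_distance(rng, 9)
        g = pd.Series({s: f"g{i % 3}" for i, s in enumerate(ids)})
        out = group_similarity_summary(D, g).set_index(["group_a", "group_b"])
        sim = 1 - D.data
        # brute force one intra and one inter cell
        intra = [sim.loc[a, b] for a, b in
                 itertools.combinations([s for s in ids if g[s] == "g0"], 2)]
        inter = [sim.loc[a, b]
                 for a in ids if g[a] == "g0" for b in ids if g[b] == "g1"]
        assert out.loc[("g0", "g0"), "mean_similarity"] == pytest.approx(np.mean(intra))
        assert out.loc[("g0", "g1"), "mean_similarity"] == pytest.approx(np.mean(inter))
        assert out.loc[("g0", "g1"), "sd_similarity"] == pytest.approx(np.std(inter))


def _brute_force_anosim(d, labels):
    """Independent ANOSIM oracle: rank formula + exhaustive relabeling."""
    n = len(labels)
    cond = squareform(d, checks=False)
    ranks = stats.rankdata(cond)
    ii, jj = np.triu_indices(n, k=1)

    def r_stat(lab):
        lab = np.asarray(lab)
        within = lab[ii] == lab[jj]
        return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4)

    r_obs = r_stat(labels)
    perms = set(itertools.permutations(labels))
    count = sum(1 for p in perms if r_stat(p) >= r_obs - 1e-12)
    return r_obs, count / len(perms)


class TestAnosim:
    def test_maximal_separation_r_one(self):
        # between-group distances all strictly larger than within-group
        d = np.array([
            [0.0, 0.1, 0.9, 0.8],
            [0.1, 0.0, 0.7, 0.9],
            [0.9, 0.7, 0.0, 0.2],
            [0.8, 0.9, 0.2, 0.0],
        ])
        D = _dm(d, list("abcd"))
        g = pd.Series({"a": "x", "b": "x", "c": "y", "d": "y"})
        res = anosim(D, g, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(size=(6, 2))
        d = squareform(pdist(pts, metric="braycurtis"))
        ids = [f"s{i}" for i in range(6)]
        labels = ["x", "x", "x", "y", "y", "y"]
        D = _dm(d, ids)
        res = anosim(D, pd.Series(labels, index=ids), exact=True)
        r_oracle, p_oracle = _brute_force_anosim(d, labels)
        assert res.r == pytest.approx(r_oracle)
        assert res.pvalue == pytest.approx(p_oracle)
        assert res.n_permutations == 20  # C(6,3) distinct assignments

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        D, ids = _random_distance(rng, 8)
        g = pd.Series({s: ("u" if i < 4 else "v") for i, s in enumerate(ids)})
        r1 = anosim(D, g, n_perm=49, seed=1).r
        warped = _dm(np.sqrt(D.data.to_numpy()), ids)  # order-preserving
        r2 = anosim(warped, g, n_perm=49, seed=1).r
        assert r1 == pytest.approx(r2)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim
        rng = np.random.default_rng(10)
        D, ids = _random_distance(rng, 10)
        g = pd.Series({s: ("u" if i < 5 else "v") for i, s in enumerate(ids)})
        res = anosim(D, g, n_perm=99, seed=2)
        sk = sk_anosim(skbio.DistanceMatrix(D.data.to_numpy(), ids),
                       grouping=[g[s] for s in ids], permutations=0)
        assert res.r == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_singleton_group_errors(self):
        d = np.zeros((3, 3))
        D = _dm(d, list("abc"))
        g = pd.Series({"a": "x", "b": "x", "c": "y"})
        with pytest.raises(ValueError):
            anosim(D, g, n_perm=9)


class TestPairwiseAnosim:
    def test_three_groups_bonferroni(self):
        rng = np.random.default_rng(11)
        D, ids = _random_distance(rng, 9)
        g = pd.Series({s: f"g{i % 3}" for i, s in enumerate(ids)})
        out = pairwise_anosim(D, g, n_perm=99, seed=0)
        assert len(out) == 3
        for res in out.values():
            assert res.adjusted_pvalue == pytest.approx(
                min(1.0, res.pvalue * 3))
            assert res.adjusted_pvalue >= res.pvalue

    def test_pair_submatrix_consistency(self):
        rng = np.random.default_rng(12)
        D, ids = _random_distance(rng, 9)
        g = pd.Series({s: f"g{i % 3}" for i, s in enumerate(ids)})
        out = pairwise_anosim(D, g, n_perm=49, seed=0)
        keep = [s for s in ids if g[s] in ("g0", "g1")]
        alone = anosim(D.submatrix(keep), g.loc[keep], n_perm=49, seed=0)
        assert out[("g0", "g1")].r == pytest.approx(alone.r)


class TestSimper:
    def test_identical_groups_zero_contributions(self):
        X = pd.DataFrame({f"s{i}": [100.0] for i in range(4)}, index=["only"])
        g = pd.Series({f"s{i}": ("a" if i < 2 else "b") for i in range(4)})
        tab = simper(X, g, "a", "b")
        assert tab["mean_contribution"].sum() == pytest.approx(0.0)

    def test_single_driver_contributes_everything(self):
        # on a common (unclosed) scale only one taxon differs
        X = pd.DataFrame({"s1": [5, 5.0], "s2": [1, 5.0]},
                         index=["driver", "steady"])
        g = pd.Series({"s1": "a", "s2": "b"})
        tab = simper(X, g, "a", "b")
        assert tab.loc["driver", "pct_contribution"] == pytest.approx(100.0)
        assert tab.loc["steady", "pct_contribution"] == pytest.approx(0.0)
        assert tab["pct_contribution"].sum() == pytest.approx(100.0)

    def test_conservation_identity_on_random_data(self):
        """Sum of per-taxon contributions equals the mean between-group
        Bray-Curtis dissimilarity, to 1e-10."""
        rng = np.random.default_rng(13)
        for _ in range(25):
            X = pd.DataFrame(rng.uniform(0, 5, size=(8, 6)),
                             index=[f"t{i}" for i in range(8)],
                             columns=[f"s{j}" for j in range(6)])
            X = 100 * X / X.sum()
            g = pd.Series({f"s{j}": ("a" if j < 3 else "b") for j in range(6)})
            tab = simper(X, g, "a", "b")
            D = bray_curtis(X)
            between = [D.data.loc[f"s{i}", f"s{j}"]
                       for i in range(3) for j in range(3, 6)]
            assert abs(tab["mean_contribution"].sum() - np.mean(between)) < 1e-10


class TestPcoa:
    def test_two_samples_forced_geometry(self):
        D = _dm(np.array([[0, 0.4], [0.4, 0.0]]), ["s1", "s2"])
        res = pcoa(D)
        coords = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        assert coords == pytest.approx([-0.2, 0.2])

    def test_euclidean_embedding_reconstructs_distances(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(5, 2))
        d = squareform(pdist(pts))
        d = d / (d.max() * 1.1)  # scale into [0, 1] for the container
        D = _dm(d, [f"s{i}" for i in range(5)])
        res = pcoa(D)
        re_d = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(re_d, d, atol=1e-8)

    def test_positive_eigenvalue_sum_equals_centered_inertia(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        d = d / (d.max() * 1.1)
        D = _dm(d, [f"s{i}" for i in range(6)])
        res = pcoa(D)
        a = D.data.to_numpy()
        J = np.eye(6) - np.ones((6, 6)) / 6
        B = -0.5 * J @ (a**2) @ J
        assert res.eigenvalues.sum() == pytest.approx(np.trace(B), abs=1e-8)

    def test_matches_scikit_bio_eigenvalues(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa
        rng = np.random.default_rng(16)
        D, ids = _random_distance(rng, 7)
        res = pcoa(D)
        sk = sk_pcoa(skbio.DistanceMatrix(D.data.to_numpy(), ids))
        sk_pos = sk.eigvals[sk.eigvals > 1e-10].to_numpy()
        assert np.allclose(np.sort(res.eigenvalues), np.sort(sk_pos), atol=1e-8)


class TestConfidenceEllipse:
    def test_isotropic_cloud_semi_axes(self):
        rng = np.random.default_rng(17)
        pts = pd.DataFrame(rng.normal(size=(4000, 2)))
        ell = confidence_ellipse(pts)
        expected = math.sqrt(stats.chi2.ppf(0.95, 2))
        assert np.allclose(ell.semi_axes, expected, rtol=0.07)
        assert not ell.degenerate

    def test_identical_points_degenerate(self):
        pts = pd.DataFrame(np.ones((5, 2)))
        ell = confidence_ellipse(pts)
        assert ell.degenerate
        assert np.allclose(ell.semi_axes, 0.0)

    def test_rotation_recovers_principal_axis(self):
        rng = np.random.default_rng(18)
        theta = np.deg2rad(30)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        pts = rng.normal(size=(500, 2)) * [3.0, 0.5] @ R.T
        ell = confidence_ellipse(pd.DataFrame(pts))
        angle = ell.rotation_deg % 180
        assert min(abs(angle - 30), abs(angle - 210 % 180)) < 5.0
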