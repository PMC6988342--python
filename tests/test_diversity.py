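import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from mgnet.diversity import (
    DistanceMatrix,
    alpha_diversity,
    alpha_group_test,
    beta_diversity,
    chao1,
    observed_otus,
    pcoa,
    permanova,
    rarefy,
    shannon,
)
from mgnet.tables import FeatureTable, SampleMetadata, ValidationError, read_tree


def _table(mat, fids=None, sids=None):
    mat = np.asarray(mat)
    fids = fids or [f"F{i}" for i in range(mat.shape[0])]
    sids = sids or [f"S{i}" for i in range(mat.shape[1])]
    return FeatureTable(mat.astype(float), "counts", feature_ids=fids,
                        sample_ids=sids)


class TestRarefy:
    def test_identity_at_full_depth(self):
        t = _table([[3], [7]])
        out = rarefy(t, 10, seed=1)
        np.testing.assert_array_equal(out.values, t.values)

    def test_forced_subsample(self):
        t = _table([[10], [0]])
        out = rarefy(t, 5, seed=1)
        np.testing.assert_array_equal(out.values, [[5], [0]])

    def test_all_columns_sum_to_depth(self, toy_table):
        depth = int(toy_table.values.sum(axis=0).min())
        out = rarefy(toy_table, depth, seed=3)
        np.testing.assert_array_equal(out.values.sum(axis=0), depth)

    def test_depth_too_large_names_samples(self):
        t = _table([[3, 100], [2, 100]])
        with pytest.raises(ValidationError, match="S0"):
            rarefy(t, 50, seed=1)


class TestAlphaMetrics:
    def test_chao1_hand_value(self):
        assert chao1(np.array([4, 1, 1, 2, 3])) == pytest.approx(5.5)

    def test_shannon_uniform(self):
        assert shannon(np.array([5, 5, 5, 5])) == pytest.approx(np.log(4))

    def test_chao1_no_singletons_equals_observed(self):
        x = np.array([3, 4, 5, 0])
        assert chao1(x) == observed_otus(x) == 3

    def test_brute_force_oracle_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.integers(0, 6, size=8)
            if x.sum() == 0:
                continue
            # independent brute-force reimplementations
            bf_chao = float((x > 0).sum()) + \
                ((x == 1).sum() * ((x == 1).sum() - 1)
                 / (2.0 * ((x == 2).sum() + 1)))
            p = x[x > 0] / x.sum()
            bf_shannon = -sum(pi * np.log(pi) for pi in p)
            assert abs(chao1(x) - bf_chao) < 1e-12
            assert abs(shannon(x) - bf_shannon) < 1e-12


class TestAlphaDiversity:
    def test_reproducible_and_bounded(self, toy_table):
        depth = int(toy_table.values.sum(axis=0).min())
        r1 = alpha_diversity(toy_table, "observed_otus", depth,
                             n_resamples=20, seed=9)
        r2 = alpha_diversity(toy_table, "observed_otus", depth,
                             n_resamples=20, seed=9)
        assert [x.value for x in r1] == [x.value for x in r2]
        # mean lies between the deterministic single-draw extremes: features
        # that cannot be exhausted must appear; absent features never can
        col = toy_table.values[:, 0]
        lower = ((col > col.sum() - depth).sum())
        upper = (col > 0).sum()
        assert lower <= r1[0].value <= upper

    def test_observed_not_above_chao1(self, toy_table):
        depth = int(toy_table.values.sum(axis=0).min())
        obs = alpha_diversity(toy_table, "observed_otus", depth,
                              n_resamples=10, seed=2)
        ch = alpha_diversity(toy_table, "chao1", depth,
                             n_resamples=10, seed=2)
        for o, c in zip(obs, ch):
            assert o.value <= c.value + 1e-12

    def test_unknown_metric(self, toy_table):
        with pytest.raises(ValidationError, match="metric"):
            alpha_diversity(toy_table, "simpson", 10)


class TestAlphaGroupTest:
    def _results(self, values):
        from mgnet.diversity import AlphaDiversityResult
        return [AlphaDiversityResult(sid, "chao1", v, 1, 10)
                for sid, v in values.items()]

    def _meta(self):
        return ([SampleMetadata(f"A{i}", "CF", "CF_other", False)
                 for i in range(3)]
                + [SampleMetadata(f"B{i}", "Healthy", "Healthy", False)
                   for i in range(3)])

    def test_exact_p_for_separated_groups(self):
        res = self._results({"A0": 1, "A1": 2, "A2": 3,
                             "B0": 4, "B1": 5, "B2": 6})
        _, p = alpha_group_test(res, self._meta())
        assert p == pytest.approx(0.1)

    def test_identical_values_p_one(self):
        res = self._results({s: 2.0 for s in
                             ["A0", "A1", "A2", "B0", "B1", "B2"]})
        _, p = alpha_group_test(res, self._meta())
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        res = self._results({"A0": 5, "A1": 1, "A2": 9,
                             "B0": 2, "B1": 8, "B2": 3})
        meta = self._meta()
        swapped = [SampleMetadata(m.sample_id.replace("A", "X"),
                                  "Healthy" if m.condition == "CF" else "CF",
                                  "Healthy" if m.condition == "CF"
                                  else "CF_other", False)
                   for m in meta]
        res_sw = self._results({"X0": 5, "X1": 1, "X2": 9,
                                "B0": 2, "B1": 8, "B2": 3})
        # swapping which condition owns which values leaves p unchanged
        _, p1 = alpha_group_test(res, meta)
        _, p2 = alpha_group_test(res_sw, swapped)
        assert p1 == pytest.approx(p2)


class TestBetaDiversity:
    def test_bray_curtis_disjoint(self):
        t = _table([[1, 0], [0, 1]])
        dm = beta_diversity(t, "bray_curtis")
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_identical_samples_zero(self, tmp_path):
        t = _table([[3, 3], [5, 5]], fids=["A", "B"])
        (tmp_path / "t.nwk").write_text("(A:1,B:1):0;")
        tree = read_tree(tmp_path / "t.nwk")
        for metric in ("bray_curtis", "unweighted_unifrac",
                       "weighted_unifrac"):
            dm = beta_diversity(t, metric, tree=tree)
            assert dm.values[0, 1] == pytest.approx(0.0)

    def test_unweighted_unifrac_star_tree(self, tmp_path):
        (tmp_path / "t.nwk").write_text("(A:1,B:1):0;")
        tree = read_tree(tmp_path / "t.nwk")
        t = _table([[4, 0], [0, 9]], fids=["A", "B"])
        dm = beta_diversity(t, "unweighted_unifrac", tree=tree)
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            mat = rng.integers(0, 20, size=(6, 2)).astype(float)
            if mat.sum() == 0:
                continue
            t = _table(mat)
            got = beta_diversity(t, "bray_curtis").values[0, 1]
            x, y = mat[:, 0], mat[:, 1]
            want = np.abs(x - y).sum() / (x + y).sum()
            assert abs(got - want) < 1e-12

    def test_unifrac_against_skbio(self, small_dataset):
        from skbio.diversity import beta_diversity as skbio_beta
        otus = small_dataset.otus
        true_cols = [s for s in otus.sample_ids if not s.startswith("NC")][:8]
        sub = otus.select_samples(true_cols)
        tree = small_dataset.tree
        for metric, kw in [("unweighted_unifrac", {}),
                           ("weighted_unifrac", {"normalized": True})]:
            ours = beta_diversity(sub, metric, tree=tree)
            theirs = skbio_beta(metric, sub.values.T.astype(int),
                                ids=sub.sample_ids, tree=tree,
                                taxa=sub.feature_ids, **kw)
            np.testing.assert_allclose(ours.values, theirs.data, atol=1e-10)

    def test_missing_tip_listed(self, tmp_path):
        (tmp_path / "t.nwk").write_text("(A:1,B:1):0;")
        tree = read_tree(tmp_path / "t.nwk")
        t = _table([[1, 2], [3, 4]], fids=["A", "Z"])
        with pytest.raises(ValidationError, match="Z"):
            beta_diversity(t, "unweighted_unifrac", tree=tree)


class TestPcoa:
    def test_two_points(self):
        dm = DistanceMatrix([[0, 4], [4, 0]], ["a", "b"])
        coords, eigvals, pct = pcoa(dm)
        np.testing.assert_allclose(sorted(coords["PC1"]), [-2, 2],
                                   atol=1e-9)

    def test_euclidean_self_consistency(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(7)])
        coords, _, _ = pcoa(dm)
        d2 = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(d2, d, atol=1e-9)

    def test_duplicate_sample_coincident(self):
        d = np.array([[0, 0, 3.0], [0, 0, 3.0], [3.0, 3.0, 0]])
        dm = DistanceMatrix(d, ["a", "b", "c"])
        coords, _, _ = pcoa(dm)
        np.testing.assert_allclose(coords.loc["a"], coords.loc["b"],
                                   atol=1e-9)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix([[0, np.nan], [np.nan, 0]], ["a", "b"])


class TestPermanova:
    def _meta(self, labels):
        return [SampleMetadata(f"s{i}", c,
                               "Healthy" if c == "Healthy" else "CF_other",
                               False)
                for i, c in enumerate(labels)]

    def test_two_tight_clusters(self):
        # partition-preserving label permutations tie the observed F, so
        # the attainable floor is ~2*(k!)^2/(2k)!; 6-per-group gets the
        # permutation p below 0.005
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.01, (6, 2)),
                         rng.normal(10, 0.01, (6, 2))])
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(12)])
        meta = self._meta(["CF"] * 6 + ["Healthy"] * 6)
        res = permanova(dm, meta, n_permutations=719, seed=1)
        assert res.p <= 0.005
        assert res.p >= 1 / 720

    def test_joint_reordering_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(8)]
        labels = ["CF"] * 4 + ["Healthy"] * 4
        dm = DistanceMatrix(d, ids)
        meta = self._meta(labels)
        res1 = permanova(dm, meta, n_permutations=9, seed=2)
        perm = rng.permutation(8)
        dm2 = DistanceMatrix(d[np.ix_(perm, perm)], [ids[i] for i in perm])
        res2 = permanova(dm2, meta, n_permutations=9, seed=2)
        assert res1.pseudo_F == pytest.approx(res2.pseudo_F)

    def test_single_group_rejected(self):
        d = np.zeros((4, 4))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(4)])
        with pytest.raises(ValidationError):
            permanova(dm, self._meta(["CF"] * 4))
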