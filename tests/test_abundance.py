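import numpy as np
import pandas as pd
import pytest

from mgnet import simulate as sim
from mgnet.abundance import (
    DifferentialResult,
    agglomerate,
    bh_adjust,
    de_summary,
    nb_lrt,
    nb_wald,
    prevalence_abundance_filter,
    size_factors,
    wilcoxon_feature_test,
)
from mgnet.tables import (
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
)


class TestBH:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)

        def brute(p):
            m = len(p)
            order = np.argsort(p)
            q = np.full(m, np.inf)
            for i in range(m):
                # step-up: min over j with p_j >= p_i of p_j * m / rank_j
                for rank, j in enumerate(order, start=1):
                    if p[j] >= p[i] - 1e-15:
                        q[i] = min(q[i], min(1.0, p[j] * m / rank))
            return q

        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(bh_adjust(p), brute(p), atol=1e-12)


class TestAgglomerate:
    def _tax(self):
        return TaxonomyMap({
            "o1": ["k__K", "p__P1", "c__C", "o__O", "f__F1", "g__G1"],
            "o2": ["k__K", "p__P1", "c__C", "o__O", "f__F1", "g__G1"],
            "o3": ["k__K", "p__P1", "c__C", "o__O", "f__F1"],
            "o4": ["k__K", "p__P2"],
        })

    def _table(self):
        return FeatureTable([[3, 1], [5, 2], [7, 4], [11, 8]], "counts",
                            feature_ids=["o1", "o2", "o3", "o4"],
                            sample_ids=["s1", "s2"])

    def test_same_genus_summed(self):
        out = agglomerate(self._table(), self._tax(), "genus")
        assert out.data.loc["g__G1"].tolist() == [8, 3]

    def test_last_characterized_fallback(self):
        out = agglomerate(self._table(), self._tax(), "genus")
        assert "f__F1" in out.feature_ids     # o3 grouped at family
        assert "p__P2" in out.feature_ids     # o4 grouped at phylum

    def test_counts_conserved_per_sample(self, small_dataset):
        t = small_dataset.otus
        for rank in ("genus", "family", "phylum"):
            out = agglomerate(t, small_dataset.taxonomy, rank)
            np.testing.assert_allclose(out.values.sum(axis=0),
                                       t.values.sum(axis=0))

    def test_identity_on_already_collapsed(self):
        tax = TaxonomyMap({"a": ["k__K", "p__P1"], "b": ["k__K", "p__P2"]})
        t = FeatureTable([[1, 2], [3, 4]], "counts",
                         feature_ids=["a", "b"], sample_ids=["s1", "s2"])
        out = agglomerate(t, tax, "phylum")
        np.testing.assert_array_equal(out.values, t.values)

    def test_unknown_rank(self):
        with pytest.raises(ValidationError, match="rank"):
            agglomerate(self._table(), self._tax(), "species")


class TestPrevalenceAbundanceFilter:
    def _meta(self, n_cf=10, n_healthy=12):
        return ([SampleMetadata(f"CF{i}", "CF", "CF_other", False)
                 for i in range(n_cf)]
                + [SampleMetadata(f"H{i}", "Healthy", "Healthy", False)
                   for i in range(n_healthy)])

    def _table(self, feature_rows, depth=10000):
        """Rows are per-sample relative abundances of the focal features;
        a filler feature absorbs the rest of each column."""
        rows = np.asarray(feature_rows, dtype=float) * depth
        filler = depth - rows.sum(axis=0)
        mat = np.vstack([rows, filler])
        ids = [f"F{i}" for i in range(len(feature_rows))] + ["filler"]
        sids = [f"CF{i}" for i in range(10)] + [f"H{i}" for i in range(12)]
        return FeatureTable(mat, "counts", feature_ids=ids, sample_ids=sids)

    def test_threshold_is_five_for_10v12(self):
        # >= 0.1% in only 4 samples -> dropped; in 5 -> kept
        row4 = [0.002] * 4 + [0.0] * 18
        row5 = [0.002] * 5 + [0.0] * 17
        t = self._table([row4, row5])
        out = prevalence_abundance_filter(t, self._meta())
        assert "F0" not in out.feature_ids
        assert "F1" in out.feature_ids

    def test_boundary_exact_rel_abundance_kept(self):
        row = [0.001] * 5 + [0.0] * 17
        t = self._table([row])
        out = prevalence_abundance_filter(t, self._meta())
        assert "F0" in out.feature_ids

    def test_ubiquitous_identity(self):
        row = [0.01] * 22
        t = self._table([row])
        out = prevalence_abundance_filter(t, self._meta())
        assert set(out.feature_ids) == {"F0", "filler"}

    def test_sample_scaling_invariance(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(1, 2000, size=(6, 22)).astype(float)
        sids = [f"CF{i}" for i in range(10)] + [f"H{i}" for i in range(12)]
        t1 = FeatureTable(mat, "counts",
                          feature_ids=[f"F{i}" for i in range(6)],
                          sample_ids=sids)
        scale = rng.uniform(0.5, 3.0, size=22)
        t2 = FeatureTable(mat * scale, "counts",
                          feature_ids=[f"F{i}" for i in range(6)],
                          sample_ids=sids)
        out1 = prevalence_abundance_filter(t1, self._meta())
        out2 = prevalence_abundance_filter(t2, self._meta())
        assert out1.feature_ids == out2.feature_ids

    def test_bad_threshold(self):
        t = self._table([[0.01] * 22])
        with pytest.raises(ValidationError):
            prevalence_abundance_filter(t, self._meta(), min_rel_abund=2.0)


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        t = FeatureTable([[1, 2], [2, 4]], "counts",
                         feature_ids=["a", "b"], sample_ids=["s1", "s2"])
        s = size_factors(t)
        np.testing.assert_allclose(s.to_numpy(),
                                   [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_identical_columns_equal_factors(self):
        t = FeatureTable([[5, 5, 5], [9, 9, 9]], "counts",
                         feature_ids=["a", "b"], sample_ids=list("xyz"))
        s = size_factors(t)
        assert len(set(np.round(s.to_numpy(), 12))) == 1

    def test_single_sample_convention(self):
        t = FeatureTable([[5], [9]], "counts", feature_ids=["a", "b"],
                         sample_ids=["s"])
        assert size_factors(t).tolist() == [1.0]

    def test_poscounts_fallback_on_sparse(self):
        t = FeatureTable([[0, 4], [3, 0], [10, 12]], "counts",
                         feature_ids=["a", "b", "c"], sample_ids=["s1", "s2"])
        t.data.loc["c", "s1"] = 0  # now no all-positive feature
        s = size_factors(t)
        assert (s > 0).all()
        with pytest.raises(ValidationError):
            size_factors(t, fallback=False)


def _make_meta(cfg):
    return sim.make_metadata(cfg)


class TestNbWald:
    def test_all_zero_feature_flagged(self):
        sids = [f"CF{i}" for i in range(3)] + [f"H{i}" for i in range(3)]
        meta = ([SampleMetadata(s, "CF", "CF_other", False)
                 for s in sids[:3]]
                + [SampleMetadata(s, "Healthy", "Healthy", False)
                   for s in sids[3:]])
        t = FeatureTable([[0] * 6, [5, 6, 7, 8, 9, 10]], "counts",
                         feature_ids=["z", "ok"], sample_ids=sids)
        res = {r.feature_id: r for r in nb_wald(t, meta)}
        assert res["z"].p == 1.0 and res["z"].log2fc == 0.0
        assert res["z"].flag == "all zero"

    def test_statistic_sign_matches_lfc(self, small_dataset):
        res = nb_wald(small_dataset.genes, small_dataset.metadata)
        for r in res:
            if r.flag == "" and r.statistic != 0:
                assert np.sign(r.statistic) == np.sign(r.log2fc)

    def test_null_type_one_error(self):
        cfg = sim.SimulationConfig(seed=42, n_genes=2000, n_cf=10,
                                   n_healthy=12, nb_dispersion=0.2,
                                   seq_depth_range=(9551, 30000))
        table = sim.simulate_gene_counts(cfg, sim.SyntheticTruth())
        res = nb_wald(table, _make_meta(cfg))
        ps = np.array([r.p for r in res if r.flag == ""])
        frac = np.mean(ps < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_planted_lfc_recovery(self):
        # 200 planted features, mu=100, known unit size factors
        rng = np.random.default_rng(3)
        n = 20
        mu_h, mu_cf = 100.0, 400.0
        counts = np.column_stack([
            rng.negative_binomial(10, 10 / (10 + mu_cf), size=(200, n)),
            rng.negative_binomial(10, 10 / (10 + mu_h), size=(200, n)),
        ])
        sids = [f"CF{i}" for i in range(n)] + [f"H{i}" for i in range(n)]
        meta = ([SampleMetadata(s, "CF", "CF_other", False)
                 for s in sids[:n]]
                + [SampleMetadata(s, "Healthy", "Healthy", False)
                   for s in sids[n:]])
        t = FeatureTable(counts.astype(float), "counts",
                         feature_ids=[f"F{i}" for i in range(200)],
                         sample_ids=sids)
        res = nb_wald(t, meta, sf=pd.Series(1.0, index=sids))
        med = np.median([r.log2fc for r in res])
        assert 1.7 <= med <= 2.3

    def test_wald_ci_coverage(self):
        # 95% CIs for the condition coefficient on self-generated data
        cfg = sim.SimulationConfig(seed=8, n_genes=500, n_cf=12,
                                   n_healthy=12, nb_dispersion=0.1,
                                   seq_depth_range=(20000, 20000),
                                   gene_mean_log=-5.0, gene_mean_sd=0.3)
        truth = sim.SyntheticTruth(
            de_genes=[(g, 1.0) for g in cfg.gene_ids[:50]])
        table = sim.simulate_gene_counts(cfg, truth)
        res = nb_wald(table, _make_meta(cfg),
                      sf=table.params["size_factors"])
        true_lfc = {g: 1.0 for g in cfg.gene_ids[:50]}
        cover = [abs(r.log2fc - true_lfc.get(r.feature_id, 0.0))
                 <= 1.96 * r.se
                 for r in res if r.flag == "" and np.isfinite(r.se)]
        assert 0.90 <= np.mean(cover) <= 0.98


class TestNbLrt:
    def test_null_three_groups_uniform_p(self):
        cfg = sim.SimulationConfig(seed=17, n_genes=1000, n_cf=12,
                                   n_healthy=12, nb_dispersion=0.2,
                                   seq_depth_range=(9551, 30000))
        table = sim.simulate_gene_counts(cfg, sim.SyntheticTruth())
        res = nb_lrt(table, _make_meta(cfg))
        ps = np.array([r.p for r in res if r.flag == ""])
        from scipy import stats
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_trend_ranks_high(self):
        # monotone 3-level trend on one feature among nulls, n=8/8/8
        rng = np.random.default_rng(6)
        mus = {"Healthy": 50.0, "CF_df508": 400.0, "CF_other": 140.0}
        meta, cols = [], {}
        for g, n in [("CF_df508", 8), ("CF_other", 8), ("Healthy", 8)]:
            for i in range(n):
                sid = f"{g}_{i}"
                cond = "Healthy" if g == "Healthy" else "CF"
                meta.append(SampleMetadata(sid, cond, g, False))
                cols[sid] = g
        sids = list(cols)
        n_feat = 200
        counts = rng.negative_binomial(
            10, 10 / (10 + 80.0), size=(n_feat, len(sids))).astype(float)
        planted = np.array([rng.negative_binomial(
            10, 10 / (10 + mus[cols[s]])) for s in sids], dtype=float)
        counts[0] = planted
        t = FeatureTable(counts, "counts",
                         feature_ids=[f"F{i}" for i in range(n_feat)],
                         sample_ids=sids)
        res = nb_lrt(t, meta, sf=pd.Series(1.0, index=sids))
        ps = np.array([r.p for r in res])
        assert ps[0] <= np.quantile(ps, 0.05)

    def test_category_too_small_rejected(self, toy_table, toy_meta):
        # toy_meta has only 2 genotype categories represented with >= 2
        meta = toy_meta[:]
        meta[1] = SampleMetadata("A2", "CF", "CF_df508", False)
        with pytest.raises(ValidationError, match="CF_other"):
            nb_lrt(toy_table, meta)


class TestWilcoxon:
    def _meta(self):
        return ([SampleMetadata(f"CF{i}", "CF", "CF_other", False)
                 for i in range(11)]
                + [SampleMetadata(f"H{i}", "Healthy", "Healthy", False)
                   for i in range(11)])

    def test_counts_table_rejected(self, toy_table, toy_meta):
        with pytest.raises(ValidationError, match="normalize"):
            wilcoxon_feature_test(toy_table, toy_meta)

    def test_prevalence_over_all_samples(self):
        # feature above threshold in 10 of 22 -> dropped (needs >= 11)
        n = 22
        row_10 = np.array([0.02] * 10 + [0.0005] * 12)
        row_11 = np.array([0.02] * 11 + [0.0005] * 11)
        filler = 1.0 - row_10 - row_11
        t = FeatureTable(np.vstack([row_10, row_11, filler]), "relative",
                         feature_ids=["ten", "eleven", "filler"],
                         sample_ids=[m.sample_id for m in self._meta()])
        res = wilcoxon_feature_test(t, self._meta())
        ids = {r.feature_id for r in res}
        assert "ten" not in ids and "eleven" in ids

    def test_identical_distributions_p_one(self):
        row = np.full(22, 0.5)
        t = FeatureTable(np.vstack([row, 1 - row]), "relative",
                         feature_ids=["a", "b"],
                         sample_ids=[m.sample_id for m in self._meta()])
        res = wilcoxon_feature_test(t, self._meta())
        assert all(r.p == 1.0 for r in res)


class TestDeSummary:
    def test_printed_up_down_split(self):
        res = ([DifferentialResult(f"u{i}", 1, 1.0, 0.1, 5, 1e-4, 0.01,
                                   "wald") for i in range(919)]
               + [DifferentialResult(f"d{i}", 1, -1.0, 0.1, -5, 1e-4, 0.01,
                                     "wald") for i in range(624)])
        s = de_summary(res, alpha=0.05)
        assert s["n_significant"] == 1543
        assert s["n_up"] == 919
        assert s["pct_up_display"] == 59
        assert s["pct_down_display"] == 40  # 40.44 truncates to 40

    def test_empty(self):
        s = de_summary([], alpha=0.05)
        assert s["n_significant"] == 0
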