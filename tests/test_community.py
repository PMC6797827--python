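"""Rarefaction, Bray-Curtis, PERMANOVA and SIMPER from first principles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mofette as m


def _table(counts, groups):
    n, k = np.asarray(counts).shape
    ids = [f"s{i}" for i in range(n)]
    return m.OtuTable(
        counts=pd.DataFrame(
            np.asarray(counts), index=ids, columns=[f"o{j + 1}" for j in range(k)]
        ),
        groups=pd.Series(dict(zip(ids, groups))),
    )


class TestRarefy:
    def test_sums_equal_depth(self):
        t = _table([[50, 30, 20], [10, 80, 10], [5, 5, 90]], ["A", "A", "B"])
        r = m.rarefy(t, 40, seed=1)
        assert (r.counts.sum(axis=1) == 40).all()

    def test_full_depth_sample_unchanged(self):
        t = _table([[5, 3, 2], [10, 80, 10]], ["A", "B"])
        r = m.rarefy(t, 10, seed=0)
        assert list(r.counts.loc["s0"]) == [5, 3, 2]

    def test_single_taxon_composition(self):
        t = _table([[100, 0, 0], [50, 50, 0]], ["A", "B"])
        r = m.rarefy(t, 10, seed=0)
        assert list(r.counts.loc["s0"]) == [10, 0, 0]

    def test_depth_beyond_total_rejected(self):
        t = _table([[5, 3, 2], [10, 80, 10]], ["A", "B"])
        with pytest.raises(ValueError, match="s0"):
            m.rarefy(t, 11, seed=0)

    def test_seed_reproducibility(self):
        t = _table(np.random.default_rng(0).integers(0, 100, (4, 20)), list("AABB"))
        a = m.rarefy(t, 100, seed=7).counts
        b = m.rarefy(t, 100, seed=7).counts
        pd.testing.assert_frame_equal(a, b)


class TestBrayCurtis:
    def test_hand_computed_pair(self):
        d = m.bray_curtis(_table([[3, 0, 1], [1, 2, 1]], ["A", "B"]))
        assert d.data[0, 1] == pytest.approx(0.5)  # (2+2+0)/(4+2+2)

    def test_identity_and_disjoint_support(self):
        d = m.bray_curtis(_table([[4, 4, 0], [4, 4, 0], [0, 0, 9]], ["A", "A", "B"]))
        assert d.data[0, 1] == 0.0
        assert d.data[0, 2] == 1.0

    def test_matches_reference_implementation(self):
        """Agreement with scikit-bio on random tables (independent oracle)."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.integers(0, 60, size=(6, 15))
            mine = m.bray_curtis(_table(x, list("AAABBB"))).data
            ref = skbio.diversity.beta_diversity("braycurtis", x).data
            np.testing.assert_allclose(mine, ref, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_metric_properties_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 50, size=(5, 8))
        x[0] += 1  # avoid all-zero warning path
        d = m.bray_curtis(_table(x, list("AABBB"))).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            m.bray_curtis(np.array([[1.0, -2.0], [0.0, 1.0]]))


class TestPermanova:
    def _toy_dist(self):
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        return m.DistanceMatrix(d, ["a", "b", "c", "d"])

    def test_exhaustive_enumeration_on_toy_example(self):
        """Two clean 2-sample clusters: only the observed labeling and its
        mirror reach the maximal F, so exhaustive p = 2/6."""
        res = m.permanova(self._toy_dist(), ["g1", "g1", "g2", "g2"], 999, seed=0)
        assert res.method == "exhaustive"
        assert res.n_permutations == 6
        assert res.p_value == pytest.approx(1 / 3)
        assert 0 <= res.R2 <= 1

    def test_r2_partition(self):
        res = m.permanova(self._toy_dist(), ["g1", "g1", "g2", "g2"], 999, seed=0)
        # SS_total = (4*0.81*... ) hand check: between-SS dominates
        assert res.R2 > 0.9

    def test_identical_samples_degenerate(self):
        d = m.DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        res = m.permanova(d, ["g1", "g1", "g2", "g2"], 99, seed=0)
        assert res.pseudo_F == 0.0 and res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            m.permanova(self._toy_dist(), ["g1", "g1", "g1", "g1"], 99, seed=0)

    def test_seeded_p_value_reproducible(self):
        tab, _ = m.gen_otu_tables(
            n_hc=5, n_lc=5, richness_hc=40, richness_lc=40, pool_size=40,
            effect_size=1.0, depth=800, seed=3
        )
        d = m.bray_curtis(tab)
        a = m.permanova(d, tab.groups, 199, seed=11)
        b = m.permanova(d, tab.groups, 199, seed=11)
        assert a.p_value == b.p_value and a.method == "monte-carlo"

    def test_pseudo_f_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.integers(0, 60, size=(8, 12))
            tab = _table(x, list("AAAABBBB"))
            d = m.bray_curtis(tab)
            mine = m.permanova(d, tab.groups, 99, seed=0)
            ref = sk_permanova(SkDM(d.data, ids=d.sample_ids), tab.groups.to_numpy(), permutations=99)
            assert mine.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_null_calibration_quick(self):
        """Small Monte-Carlo sanity check of type-I error (the full 2000-run
        calibration lives in the acceptance suite)."""
        rej = 0
        n = 200
        for s in range(n):
            tab, _ = m.gen_otu_tables(
                n_hc=5, n_lc=5, richness_hc=30, richness_lc=30, pool_size=30,
                effect_size=0.0, n_effect_otus=0, depth=400, overdispersion=50, seed=s
            )
            d = m.bray_curtis(tab)
            if m.permanova(d, tab.groups, 99, seed=s + 1).p_value <= 0.05:
                rej += 1
        assert 0.01 <= rej / n <= 0.10


class TestSimper:
    def test_hand_computed_single_pair(self):
        t = _table([[3, 0, 1], [1, 2, 1]], ["HC", "LC"])
        sim = m.simper(t)
        assert sim.table.loc["o1", "contribution"] == pytest.approx(0.25)
        assert sim.table.loc["o2", "contribution"] == pytest.approx(0.25)
        assert sim.table.loc["o3", "contribution"] == pytest.approx(0.0)
        assert list(sim.table["pct_con"]) == [pytest.approx(50), pytest.approx(50), pytest.approx(0)]
        assert list(sim.table["pct_cum"]) == [pytest.approx(50), pytest.approx(100), pytest.approx(100)]

    def test_contributions_sum_to_mean_dissimilarity(self):
        """Conservation: Σ per-OTU contributions equals the mean
        between-group Bray-Curtis dissimilarity to 1e-12."""
        rng = np.random.default_rng(9)
        x = rng.integers(0, 80, size=(7, 25))
        t = _table(x, ["HC"] * 3 + ["LC"] * 4)
        sim = m.simper(t)
        d = m.bray_curtis(t).data
        between = d[:3, 3:].mean()
        assert sim.table["contribution"].sum() == pytest.approx(between, abs=1e-12)

    def test_identical_groups_zero_dissimilarity(self):
        t = _table([[4, 1, 2], [4, 1, 2]], ["HC", "LC"])
        sim = m.simper(t)
        assert sim.overall_mean_dissimilarity_pct == 0.0
        assert (sim.table["contribution"] == 0).all()

    def test_more_than_two_groups_rejected(self):
        t = _table([[1, 2], [3, 4], [5, 6]], ["A", "B", "C"])
        with pytest.raises(ValueError):
            m.simper(t)

    def test_cumulative_matches_printed_table(self):
        """The printed %Con column reproduces the published %Cum values
        (4.04 and 5.31 at ranks 2 and 3) by plain accumulation."""
        printed = m.datasets.load_simper_printed()
        cum = m.cumulative_percent(printed["pct_con"])
        assert cum[1] == 4.04 and cum[2] == 5.31
        # beyond rank 3 the published cumulative reflects unrounded %Con,
        # so accumulation of the printed column can drift by one rounding ulp
        assert np.allclose(cum, printed["pct_cum"], atol=0.011)

    def test_tie_break_is_lexicographic(self):
        t = _table([[5, 5, 0], [0, 0, 10]], ["HC", "LC"])
        sim = m.simper(t)
        # o3 contributes most; o1 and o2 tie and fall back to id order
        assert list(sim.table.index) == ["o3", "o1", "o2"]


class TestRichness:
    def test_observed_richness_counts_nonzero(self):
        t = _table([[5, 0, 2], [1, 1, 1]], ["A", "B"])
        assert list(m.observed_richness(t)) == [2, 3]

    def test_curve_at_full_depth_equals_observed(self):
        t = _table([[5, 0, 5], [2, 4, 4]], ["A", "B"])
        curve = m.rarefaction_curve(t, depths=[10], replicates=5, seed=0)
        assert list(curve.loc[10]) == [2, 3]

    def test_groups_separate_when_richness_differs(self):
        tab, _ = m.gen_otu_tables(
            n_hc=4, n_lc=4, richness_hc=50, richness_lc=200, pool_size=250,
            effect_size=0.0, n_effect_otus=0, depth=3000, seed=1
        )
        rich = m.observed_richness(tab).groupby(tab.groups).mean()
        assert rich["HC"] < rich["LC"]
        curve = m.rarefaction_curve(tab, depths=[500, 1500, 3000], replicates=3, seed=2)
        hc_cols = [s for s in tab.sample_ids if s.startswith("HC")]
        lc_cols = [s for s in tab.sample_ids if s.startswith("LC")]
        for depth in curve.index:
            assert curve.loc[depth, hc_cols].mean() < curve.loc[depth, lc_cols].mean()
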