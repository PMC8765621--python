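import numpy as np
import pytest
from itertools import product
from scipy import stats

import facefreq as ff
from facefreq.cluster import (
    _friedman_prep,
    _kruskal_prep,
    _site_graph,
    friedman_stats,
    kruskal_stats,
    ranksum_stats,
    signed_rank_stats,
)
from facefreq.layout import SensorLayout


def line_layout(n_ch=3):
    """Minimal chain layout: E1 - E2 - ... - En."""
    pos = np.column_stack([np.linspace(-1, 1, n_ch), np.zeros(n_ch)])
    adj = np.zeros((n_ch, n_ch), dtype=bool)
    for i in range(n_ch - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return SensorLayout(names=[f"E{i+1}" for i in range(n_ch)], pos=pos,
                        adjacency=adj)


class TestPointwiseStats:
    def test_friedman_hand_case_strictly_ordered(self):
        # 3 participants x 3 conditions, strictly increasing values:
        # ranks are 1,2,3 for everyone -> chi2 = 6.0 with df = 2
        data = np.zeros((3, 3, 1, 1))
        for i in range(3):
            data[i, :, 0, 0] = [1 + i, 5 + i, 9 + i]
        sm = ff.pointwise_stats(data, "paired")
        assert sm.test == "friedman"
        assert sm.stat[0, 0] == pytest.approx(6.0)
        assert sm.p[0, 0] == pytest.approx(stats.chi2.sf(6.0, 2))

    def test_identical_conditions_chi2_zero_p_one(self):
        data = np.ones((4, 3, 2, 2))
        sm = ff.pointwise_stats(data, "paired")
        np.testing.assert_allclose(sm.stat, 0.0)
        np.testing.assert_allclose(sm.p, 1.0)

    def test_friedman_matches_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        data = np.round(rng.normal(size=(9, 4, 3, 5)), 1)  # rounding makes ties
        sm = ff.pointwise_stats(data, "paired")
        for c in range(3):
            for t in range(5):
                ref = stats.friedmanchisquare(*[data[:, j, c, t]
                                                for j in range(4)])
                assert sm.stat[c, t] == pytest.approx(ref.statistic, rel=1e-10)
                assert sm.p[c, t] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_kruskal_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        data = np.round(rng.normal(size=(12, 2, 4)), 1)
        groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        sm = ff.pointwise_stats(data, "unpaired", groups=groups)
        assert sm.test == "kruskal"
        for c in range(2):
            for t in range(4):
                ref = stats.kruskal(*[data[groups == g, c, t]
                                      for g in ("a", "b", "c")])
                assert sm.stat[c, t] == pytest.approx(ref.statistic, rel=1e-10)

    def test_ranksum_z_matches_mannwhitney_normal_approx(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(14, 1, 3))
        groups = np.array(["a"] * 6 + ["b"] * 8)
        sm = ff.pointwise_stats(data, "unpaired", groups=groups)
        assert sm.test == "ranksum"
        for t in range(3):
            ref = stats.mannwhitneyu(data[groups == "a", 0, t],
                                     data[groups == "b", 0, t],
                                     alternative="two-sided", method="asymptotic",
                                     use_continuity=False)
            assert sm.p[0, t] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_signed_rank_z_sign_and_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 1.0, size=(10, 1, 1))
        y = rng.normal(0.0, 1.0, size=(10, 1, 1))
        sm_xy = ff.pointwise_stats(np.stack([x, y], axis=1), "paired")
        sm_yx = ff.pointwise_stats(np.stack([y, x], axis=1), "paired")
        assert sm_xy.test == "wilcoxon-paired"
        assert sm_xy.stat[0, 0] == pytest.approx(-sm_yx.stat[0, 0])
        assert sm_xy.stat[0, 0] > 0  # x systematically larger

    def test_pointwise_null_rejection_rate_nominal(self):
        # under a true null each site rejects at ~alpha; Kruskal-Wallis at
        # N=36 is close to its asymptotic law, the discrete Friedman at
        # small n must stay conservative (valid) rather than exact
        rng = np.random.default_rng(4)
        kw_rates, fr_rates = [], []
        for _ in range(300):
            ud = rng.normal(size=(36, 1, 4))
            groups = np.repeat(["a", "b", "c"], 12)
            kw_rates.append((ff.pointwise_stats(ud, "unpaired",
                                                groups=groups).p < 0.05).mean())
            pd_ = rng.normal(size=(10, 4, 1, 4))
            fr_rates.append((ff.pointwise_stats(pd_, "paired").p < 0.05).mean())
        assert np.mean(kw_rates) == pytest.approx(0.05, abs=0.015)
        assert np.mean(fr_rates) <= 0.05 + 0.01


class TestFormClusters:
    def make_map(self, stat, p, test="friedman", signed=False):
        return ff.StatMap(np.asarray(stat, float), np.asarray(p, float),
                          test, signed)

    def test_no_supra_threshold_site_gives_no_cluster(self):
        lay = line_layout(3)
        sm = self.make_map(np.ones((3, 4)), np.full((3, 4), 0.5))
        res = ff.form_clusters(sm, lay, 0.05)
        assert res.clusters == []

    def test_single_site_cluster_mass(self):
        lay = line_layout(3)
        stat = np.zeros((3, 4))
        p = np.ones((3, 4))
        stat[1, 2], p[1, 2] = 7.2, 0.01
        res = ff.form_clusters(sm := self.make_map(stat, p), lay, 0.05)
        assert len(res.clusters) == 1
        assert res.clusters[0].mass == pytest.approx(7.2)
        np.testing.assert_array_equal(res.clusters[0].sites, [[1, 2]])

    def test_two_disjoint_blobs_hand_counted(self):
        # 3 electrodes x 4 bins; blob A spans (E1,t0),(E1,t1),(E2,t1);
        # blob B spans (E3,t3). E1-E2 adjacent, E2-E3 adjacent.
        lay = line_layout(3)
        stat = np.zeros((3, 4))
        p = np.ones((3, 4))
        for site, s in [((0, 0), 5.0), ((0, 1), 6.0), ((1, 1), 4.0),
                        ((2, 3), 8.0)]:
            stat[site], p[site] = s, 0.01
        res = ff.form_clusters(self.make_map(stat, p), lay, 0.05)
        masses = sorted(c.mass for c in res.clusters)
        assert masses == [8.0, 15.0]

    def test_signed_statistics_cluster_within_sign(self):
        lay = line_layout(2)
        stat = np.array([[3.0, -3.0], [3.0, -3.0]])
        p = np.full((2, 2), 0.01)
        res = ff.form_clusters(self.make_map(stat, p, "ranksum", signed=True),
                               lay, 0.05)
        masses = sorted(c.mass for c in res.clusters)
        assert masses == [-6.0, 6.0]

    def test_cluster_mass_invariant_to_electrode_reordering(self):
        rng = np.random.default_rng(5)
        lay = line_layout(4)
        stat = rng.chisquare(3, size=(4, 6))
        p = stats.chi2.sf(stat, 3)
        res = ff.form_clusters(self.make_map(stat, p), lay, 0.4)
        # reverse electrode order (adjacency is a chain, so reversal is an
        # automorphism of the graph)
        res_r = ff.form_clusters(self.make_map(stat[::-1], p[::-1]), lay, 0.4)
        assert sorted(round(c.mass, 9) for c in res.clusters) == \
               sorted(round(c.mass, 9) for c in res_r.clusters)


class TestPermutationPvalues:
    def test_exact_enumeration_matches_independent_oracle(self):
        # paired, 3 participants x 2 conditions: the full space is the
        # 2^3 = 8 sign flips; enumerate it independently here
        rng = np.random.default_rng(6)
        lay = line_layout(3)
        data = rng.normal(size=(3, 2, 3, 4))
        data[:, 0] += 1.0
        res = ff.permutation_pvalues(data, "paired", lay, n_perm=999)
        assert res.exact and res.n_permutations == 8

        # independent oracle: recompute max cluster mass per sign flip
        diff = (data[:, 0] - data[:, 1]).reshape(3, -1)
        graph = _site_graph(lay.adjacency, 4)
        thr = stats.norm.isf(0.025)
        null = []
        for signs in product((1.0, -1.0), repeat=3):
            d = np.asarray(signs)[:, None] * diff
            z, _, _ = signed_rank_stats(d)
            mx = 0.0
            for mask in (z > thr, z < -thr):
                idx = np.flatnonzero(mask)
                if idx.size:
                    from scipy.sparse.csgraph import connected_components
                    sub = graph[idx][:, idx]
                    ncomp, labels = connected_components(sub, directed=False)
                    for comp in range(ncomp):
                        mx = max(mx, abs(z[idx[labels == comp]].sum()))
            null.append(mx)
        null = np.asarray(null)
        for c in res.clusters:
            assert c.p == pytest.approx((null >= abs(c.mass)).mean())

    def test_unpaired_exact_enumeration_small_groups(self):
        rng = np.random.default_rng(7)
        lay = line_layout(2)
        data = rng.normal(size=(6, 2, 3))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = ff.permutation_pvalues(data, "unpaired", lay, groups=groups,
                                     n_perm=50)
        assert res.exact and res.n_permutations == 20  # C(6,3)

    def test_add_one_bound_for_monte_carlo(self):
        # huge effect, Monte Carlo regime: p = 1/(n_perm+1)
        rng = np.random.default_rng(8)
        lay = line_layout(3)
        data = rng.normal(size=(12, 2, 3, 4))
        data[:, 0] += 50.0
        res = ff.permutation_pvalues(data, "paired", lay, n_perm=199, seed=1,
                                     method="montecarlo")
        assert not res.exact
        top = res.clusters[0]
        assert top.p == pytest.approx(1.0 / 200.0)

    def test_permutation_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        lay = line_layout(3)
        data = rng.normal(size=(8, 4, 3, 5))
        r1 = ff.permutation_pvalues(data, "paired", lay, n_perm=100, seed=3,
                                    method="montecarlo")
        r2 = ff.permutation_pvalues(data, "paired", lay, n_perm=100, seed=3,
                                    method="montecarlo")
        np.testing.assert_array_equal(r1.null_max, r2.null_max)

    def test_cluster_p_valid_under_null_paired(self):
        # family-wise error of the corrected test stays near alpha
        rng = np.random.default_rng(10)
        lay = line_layout(4)
        rejections = 0
        n_sim = 120
        for _ in range(n_sim):
            data = rng.normal(size=(10, 4, 4, 10))
            res = ff.permutation_pvalues(data, "paired", lay, n_perm=99,
                                         seed=int(rng.integers(2**31)),
                                         method="montecarlo")
            if res.clusters and res.clusters[0].p <= 0.05:
                rejections += 1
        rate = rejections / n_sim
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_sim) + 1e-9


class TestDispersion:
    def test_equal_condition_means_zero_sd(self, layout16):
        data = np.ones((6, 4, 16, 5))
        groups = np.array(["pTD"] * 3 + ["pASD"] * 3)
        sd, _ = ff.condition_dispersion_map(data, groups, layout16, n_perm=10,
                                            seed=0)
        np.testing.assert_allclose(sd, 0.0)

    def test_sd_hand_value(self, layout16):
        data = np.ones((4, 4, 16, 2))
        data[:, 3] = 3.0  # condition means {1,1,1,3} -> SD = 1
        groups = np.array(["pTD"] * 2 + ["pASD"] * 2)
        sd, _ = ff.condition_dispersion_map(data, groups, layout16, n_perm=10,
                                            seed=0)
        np.testing.assert_allclose(sd, 1.0)

    def test_fewer_than_two_conditions_rejected(self, layout16):
        with pytest.raises(ValueError):
            ff.condition_dispersion_map(np.ones((4, 1, 16, 5)),
                                        np.array(["a"] * 4), layout16)


class TestRoiHelpers:
    def test_roi_window_mean_reduces_correct_axes(self, layout64):
        rng = np.random.default_rng(11)
        times = np.arange(-500.0, 1500.0, 4.0)
        data = rng.normal(size=(5, 4, 64, times.size))
        out = ff.roi_window_mean(data, times, layout64, "right-parietal",
                                 (450.0, 630.0))
        assert out.shape == (5, 4)
        idx = layout64.roi_indices("right-parietal")
        tmask = (times >= 450) & (times <= 630)
        manual = data[:, :, idx][:, :, :, tmask].mean(axis=(2, 3))
        np.testing.assert_allclose(out, manual)
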