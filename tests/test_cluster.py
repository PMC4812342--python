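"""Ward clustering of preference-peak latencies and family summaries."""

import numpy as np
import pytest

import trialspike as ts
from trialspike import cluster as cl
from trialspike import glm, peth


def _records(times, sign=+1):
    return [cl.PeakRecord(unit_id=i, cell_type="RS", variable="difficulty",
                          sign=sign, peak_time=float(t))
            for i, t in enumerate(times)]


class TestWardCluster:
    def test_four_point_merge_order(self):
        """Neighbors within each pair merge first; the top split separates
        the two pairs (verified against pairwise Ward costs)."""
        pts = np.array([-1.5, -1.4, 0.9, 1.0])
        Z = cl.ward_cluster(pts)
        first_two = {frozenset(Z[0, :2].astype(int)),
                     frozenset(Z[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
        # for singletons, Ward height = Euclidean distance: 0.1 for each pair
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.1)
        assert Z[2, 2] > Z[1, 2]

    def test_equal_points_zero_heights(self):
        Z = cl.ward_cluster(np.zeros(5))
        assert np.allclose(Z[:, 2], 0.0)

    def test_pair_height_is_distance(self):
        # Ward linkage height for two singletons reduces to their distance
        for a, b in [(0.0, 1.0), (-2.0, 0.5), (3.0, 3.2)]:
            Z = cl.ward_cluster(np.array([a, b]))
            assert Z[0, 2] == pytest.approx(abs(a - b))

    def test_singleton_group_warns(self):
        with pytest.warns(UserWarning, match="singleton"):
            Z = cl.ward_cluster(np.array([1.0]))
        assert Z.shape == (0, 4)

    def test_order_invariance(self):
        pts = np.array([-1.5, 0.9, -1.4, 1.0, 0.0])
        recs = _records(pts)
        Z1 = cl.ward_cluster(pts)
        perm = [3, 0, 4, 1, 2]
        Z2 = cl.ward_cluster(pts[perm])
        f1 = cl.cut_tree_families(Z1, recs, fraction=0.5)
        f2 = cl.cut_tree_families(Z2, [recs[i] for i in perm], fraction=0.5)
        part1 = {frozenset(f.unit_ids) for f in f1}
        part2 = {frozenset(f.unit_ids) for f in f2}
        assert part1 == part2


class TestCutTree:
    def test_fraction_one_single_family(self):
        recs = _records([-1.5, -1.4, 0.9, 1.0])
        Z = cl.ward_cluster(np.array([r.peak_time for r in recs]))
        fams = cl.cut_tree_families(Z, recs, fraction=1.0)
        assert len(fams) == 1
        assert sorted(fams[0].unit_ids) == [0, 1, 2, 3]

    def test_tiny_fraction_all_singletons(self):
        recs = _records([-1.5, -1.4, 0.9, 1.0])
        Z = cl.ward_cluster(np.array([r.peak_time for r in recs]))
        fams = cl.cut_tree_families(Z, recs, fraction=1e-9)
        assert len(fams) == 4

    def test_two_pairs_at_95_percent(self):
        recs = _records([-1.5, -1.4, 0.9, 1.0])
        Z = cl.ward_cluster(np.array([r.peak_time for r in recs]))
        fams = cl.cut_tree_families(Z, recs, fraction=0.95)
        assert len(fams) == 2
        assert {frozenset(f.unit_ids) for f in fams} == {
            frozenset({0, 1}), frozenset({2, 3})}

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_rejects_bad_fraction(self, bad):
        Z = cl.ward_cluster(np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            cl.cut_tree_families(Z, _records([0.0, 1.0]), fraction=bad)

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-2, 3, 40)
        recs = _records(pts)
        Z = cl.ward_cluster(pts)
        fams = cl.cut_tree_families(Z, recs, fraction=0.95)
        all_ids = sorted(uid for f in fams for uid in f.unit_ids)
        assert all_ids == list(range(40))
        assert all(f.size > 0 for f in fams)

    def test_two_latency_populations_recovered(self):
        """Two injected latency populations >= 1 s apart (SD 0.2 s) split
        into exactly 2 families for the vast majority of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = np.concatenate([rng.normal(-1.0, 0.15, 15),
                                  rng.normal(1.0, 0.15, 15)])
            Z = cl.ward_cluster(pts)
            fams = cl.cut_tree_families(Z, _records(pts), fraction=0.95)
            hits += (len(fams) == 2)
        assert hits >= 19


class TestSummarizeFamily:
    def _setup(self, betas_by_unit, cond):
        centers = -2.0 + 0.2 * (np.arange(25) + 0.5)
        series, zpeths, conds = {}, {}, {}
        for uid, beta_d in betas_by_unit.items():
            beta = np.zeros((3, 25))
            beta[1] = beta_d
            series[uid] = glm.CoefficientSeries(
                beta=beta, F=np.zeros((3, 25)), p=np.ones((3, 25)),
                names=["intercept", "difficulty", "location"],
                bin_centers=centers, dof=50, unit_id=uid)
            z = np.outer(cond, beta_d)    # hard trials +bump, easy -bump
            zpeths[uid] = peth.ZScoredPETH(values=z, bin_centers=centers,
                                           unit_id=uid)
            conds[uid] = cond
        return series, zpeths, conds

    def test_single_member_family_means_equal_unit(self):
        cond = np.array([1, -1] * 10)
        bump = np.exp(-(np.linspace(-2, 3, 25) + 1) ** 2)
        series, zpeths, conds = self._setup({7: bump}, cond)
        fam = cl.ClusterFamily(family_id=0, unit_ids=[7],
                               peak_time_range=(-1.0, -1.0))
        fam = cl.summarize_family(fam, series, zpeths, conds, "difficulty")
        assert np.allclose(fam.mean_coefficients, bump)
        assert np.allclose(fam.mean_peth[+1], bump)
        assert np.allclose(fam.mean_peth[-1], -bump)

    def test_opposite_series_cancel(self):
        cond = np.array([1, -1] * 10)
        bump = np.exp(-(np.linspace(-2, 3, 25)) ** 2)
        series, zpeths, conds = self._setup({0: bump, 1: -bump}, cond)
        fam = cl.ClusterFamily(family_id=0, unit_ids=[0, 1],
                               peak_time_range=(0.0, 0.0))
        fam = cl.summarize_family(fam, series, zpeths, conds, "difficulty")
        assert np.allclose(fam.mean_coefficients, 0.0)

    def test_hard_preferring_family_epoch_contrast(self):
        """Units tuned to the hard condition in the stimulus-viewing epoch
        show mean PETH(hard) > PETH(easy) there and a significant paired
        test."""
        cond = np.array([1, -1] * 14)
        centers = np.linspace(-2, 3, 25)
        rng = np.random.default_rng(3)
        betas = {uid: np.exp(-(centers + 1.2) ** 2 / 0.1)
                 * rng.uniform(0.8, 1.2) for uid in range(8)}
        series, zpeths, conds = self._setup(betas, cond)
        fam = cl.ClusterFamily(family_id=0, unit_ids=list(range(8)),
                               peak_time_range=(-1.3, -1.1))
        fam = cl.summarize_family(fam, series, zpeths, conds, "difficulty")
        sel = (fam.bin_centers >= -2) & (fam.bin_centers < -0.5)
        assert fam.mean_peth[+1][sel].mean() > fam.mean_peth[-1][sel].mean()
        t, p = fam.epoch_tests["stimulus_viewing"]
        assert t > 0 and p < 0.05

    def test_mismatched_grids_rejected(self):
        cond = np.array([1, -1] * 10)
        series, zpeths, conds = self._setup({0: np.zeros(25)}, cond)
        other = glm.CoefficientSeries(
            beta=np.zeros((3, 10)), F=np.zeros((3, 10)), p=np.ones((3, 10)),
            names=["intercept", "difficulty", "location"],
            bin_centers=np.arange(10.0), dof=50, unit_id=1)
        series[1] = other
        zpeths[1] = zpeths[0]
        conds[1] = cond
        fam = cl.ClusterFamily(family_id=0, unit_ids=[0, 1],
                               peak_time_range=(0.0, 0.0))
        with pytest.raises(ValueError, match="grid"):
            cl.summarize_family(fam, series, zpeths, conds, "difficulty")
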