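"""Cohort summaries, masks, parcellation, ROI tables and contrasts."""

import numpy as np
import pandas as pd
import pytest

from gratio.group_stats import (
    GroupStack,
    cov_threshold_mask,
    group_summary,
    mt_density_correlation,
    parcellate_cc,
    roi_statistics,
    tract_contrasts,
    tract_roi,
    wm_histogram,
)


def stack_from_values(values, shape=(3, 3, 3)):
    maps = np.stack([np.full(shape, v, dtype=float) for v in values])
    return GroupStack(maps=maps, subject_ids=[f"s{i}" for i in range(len(values))])


class TestGroupSummary:
    def test_mean_sd_cov(self):
        s = group_summary(stack_from_values([0.63, 0.70, 0.77]))
        assert np.allclose(s.mean_map, 0.7)
        assert np.allclose(s.sd_map, 0.07)
        assert np.allclose(s.cov_map, 0.1)
        assert np.all(s.n_valid_map == 3)

    def test_identical_subjects_zero_sd(self):
        s = group_summary(stack_from_values([0.7, 0.7, 0.7, 0.7]))
        assert np.allclose(s.sd_map, 0.0)
        assert np.allclose(s.cov_map, 0.0)
        assert np.allclose(s.mean_map, 0.7)

    def test_too_few_valid_subjects_invalid(self):
        maps = np.full((3, 2, 2, 2), np.nan)
        maps[0, 0, 0, 0] = 0.7  # one valid subject only at this voxel
        maps[:, 1, 1, 1] = [0.6, 0.7, 0.8]
        s = group_summary(GroupStack(maps=maps, subject_ids=["a", "b", "c"]))
        assert np.isnan(s.mean_map[0, 0, 0])
        assert s.mean_map[1, 1, 1] == pytest.approx(0.7)

    def test_cov_sampling_distribution(self):
        """Per-voxel CoV at known between-subject sigma follows chi2 bounds."""
        rng = np.random.default_rng(0)
        n, sigma, mu = 37, 0.05, 0.7
        maps = mu + sigma * rng.standard_normal((n, 12, 12, 12))
        s = group_summary(GroupStack(maps=maps, subject_ids=[str(i) for i in range(n)]))
        from scipy import stats

        stat = s.sd_map**2 * (n - 1) / sigma**2
        lo, hi = stats.chi2.ppf([0.0005, 0.9995], df=n - 1)
        frac_inside = np.mean((stat > lo) & (stat < hi))
        assert frac_inside > 0.995


class TestMasksAndHistogram:
    def test_cov_threshold_strict_boundary(self):
        s = group_summary(stack_from_values([0.63, 0.70, 0.77]))  # cov exactly 0.1
        assert not cov_threshold_mask(s, threshold=0.1).any()
        assert cov_threshold_mask(s, threshold=0.10001).all()

    def test_zero_threshold_empty_unless_constant(self):
        varying = group_summary(stack_from_values([0.6, 0.8]))
        assert not cov_threshold_mask(varying, 0.0).any()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        maps = 0.7 + rng.normal(0, 0.1, (8, 5, 5, 5))
        s = group_summary(GroupStack(maps=maps, subject_ids=[str(i) for i in range(8)]))
        m_low = cov_threshold_mask(s, 0.1)
        m_high = cov_threshold_mask(s, 0.3)
        assert np.all(m_high | ~m_low)  # raising the threshold never removes voxels

    def test_histogram_constant_map_single_bin(self):
        h = wm_histogram(np.full((4, 4, 4), 0.7), np.ones((4, 4, 4), bool))
        assert (h["count"] > 0).sum() == 1
        assert h["count"].sum() == 64

    def test_histogram_restricted_support_contained(self):
        rng = np.random.default_rng(2)
        mean_map = rng.uniform(0.2, 0.9, (6, 6, 6))
        wm = np.ones((6, 6, 6), bool)
        cov_mask = mean_map > 0.5  # proxy for a reliability restriction
        h_all = wm_histogram(mean_map, wm)
        h_sub = wm_histogram(mean_map, wm, cov_mask)
        occupied_all = h_all["count"].to_numpy() > 0
        occupied_sub = h_sub["count"].to_numpy() > 0
        assert np.all(occupied_all | ~occupied_sub)
        assert h_sub["count"].sum() == cov_mask.sum()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            wm_histogram(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))


class TestParcellation:
    def affine(self, voxel=2.0):
        aff = np.diag([voxel, voxel, voxel, 1.0])
        return aff

    def test_partition_property(self):
        mask = np.zeros((4, 40, 4), bool)
        mask[1:3, 2:38, 1:3] = True
        labels = parcellate_cc(mask, self.affine(), n_intervals=8)
        assert set(np.unique(labels[mask])) == set(range(1, 9))
        assert np.all(labels[~mask] == 0)
        assert np.all(labels[mask] >= 1)

    def test_equal_world_width_assignment_oracle(self):
        mask = np.zeros((3, 32, 3), bool)
        mask[1, 4:28, 1] = True
        aff = self.affine(voxel=2.0)
        labels = parcellate_cc(mask, aff, n_intervals=8)
        y_world = np.arange(32) * 2.0
        ys = y_world[4:28]
        width = (ys.max() - ys.min()) / 8
        expect = np.minimum(((ys - ys.min()) / width).astype(int), 7) + 1
        assert np.array_equal(labels[1, 4:28, 1], expect)

    def test_arc_mask_counts_match_geometric_oracle(self, noiseless_subject):
        cc = noiseless_subject.structure_masks["cc"]
        aff = noiseless_subject.dmri_affine
        labels = parcellate_cc(cc, aff, n_intervals=8)
        idx = np.array(np.where(cc)).T
        y = (aff[:3, :3] @ idx.T).T[:, 1] + aff[1, 3]
        width = (y.max() - y.min()) / 8
        oracle = np.minimum(((y - y.min()) / width).astype(int), 7) + 1
        counts = np.bincount(labels[cc], minlength=9)[1:]
        assert np.array_equal(counts, np.bincount(oracle, minlength=9)[1:])

    def test_thin_mask_rejected(self):
        mask = np.zeros((3, 4, 3), bool)
        mask[1, 1:3, 1] = True
        with pytest.raises(ValueError, match="A-P"):
            parcellate_cc(mask, self.affine(), n_intervals=8)


class TestTractRoi:
    def test_boundary_probability_included(self):
        prob = np.full((3, 3, 3), 0.5)
        mask, _ = tract_roi(prob, np.ones((3, 3, 3), bool))
        assert mask.all()

    def test_all_zero_probability_flagged(self):
        mask, too_small = tract_roi(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool))
        assert not mask.any()
        assert too_small

    def test_conjunction_equals_logical_and(self):
        rng = np.random.default_rng(7)
        prob = rng.uniform(0, 1, (6, 6, 6))
        cov_mask = rng.random((6, 6, 6)) > 0.4
        mask, _ = tract_roi(prob, cov_mask, min_voxels=1)
        assert np.array_equal(mask, (prob >= 0.5) & cov_mask)


class TestRoiStatistics:
    def test_single_voxel_roi(self):
        stack = stack_from_values([0.6, 0.8])
        roi = np.zeros((3, 3, 3), bool)
        roi[0, 0, 0] = True
        table, summary = roi_statistics(stack, {"r": roi})
        assert np.allclose(table["sd"], 0.0)
        assert table.loc[table.subject_id == "s0", "mean"].item() == pytest.approx(0.6)
        assert summary["group_mean"].item() == pytest.approx(0.7)

    def test_invalid_subject_row_dropped(self):
        maps = np.stack([np.full((2, 2, 2), 0.7)] * 3)
        maps[1] = np.nan
        stack = GroupStack(maps=maps, subject_ids=["a", "b", "c"])
        with pytest.warns(UserWarning, match="dropped"):
            table, _ = roi_statistics(stack, {"r": np.ones((2, 2, 2), bool)})
        assert set(table["subject_id"]) == {"a", "c"}

    def test_known_roi_effects_recovered(self):
        rng = np.random.default_rng(11)
        n_sub, shape = 12, (4, 4, 4)
        rois = {
            "left": np.zeros(shape, bool),
            "right": np.zeros(shape, bool),
        }
        rois["left"][:2] = True
        rois["right"][2:] = True
        truth = {"left": 0.6, "right": 0.75}
        maps = np.empty((n_sub,) + shape)
        for s in range(n_sub):
            for k, m in rois.items():
                maps[s][m] = truth[k] + rng.normal(0, 0.02)
        stack = GroupStack(maps=maps, subject_ids=[str(i) for i in range(n_sub)])
        _, summary = roi_statistics(stack, rois)
        for k in rois:
            se = 0.02 / np.sqrt(n_sub)
            got = summary.loc[summary.roi_id == k, "group_mean"].item()
            assert abs(got - truth[k]) < 4 * se


class TestTractContrasts:
    def toy_table(self):
        rows = []
        data = {
            "ct": [0.70, 0.72, 0.71],
            "or": [0.60, 0.59, 0.61],
            "slf": [0.69, 0.71, 0.70],
        }
        for roi, means in data.items():
            for i, m in enumerate(means):
                rows.append({"roi_id": roi, "subject_id": f"s{i}", "mean": m, "sd": 0.01, "n_voxels": 10})
        return pd.DataFrame(rows)

    def test_t_statistic_matches_direct_formula(self):
        table = self.toy_table()
        report = tract_contrasts(table, reference_tract="ct")
        x = np.array([0.60, 0.59, 0.61])
        y = np.array([0.70, 0.72, 0.71])
        sp = np.sqrt(((x.var(ddof=1) + y.var(ddof=1)) / 2))
        t_expect = (x.mean() - y.mean()) / (sp * np.sqrt(2 / 3))
        got = report["posthoc"].set_index("tract").loc["or"]
        assert got["t_stat"] == pytest.approx(t_expect, rel=1e-10)
        assert got["smaller_than_reference"]

    def test_clear_separation_flagged(self):
        table = self.toy_table()
        report = tract_contrasts(table, reference_tract="ct")
        flags = report["posthoc"].set_index("tract")["smaller_than_reference"]
        assert flags["or"]
        assert not flags["slf"]
        assert report["anova_p"] < 0.05

    def test_degenerate_inputs_rejected(self):
        rows = [
            {"roi_id": r, "subject_id": f"s{i}", "mean": 0.7, "sd": 0, "n_voxels": 5}
            for r in ("a", "b") for i in range(3)
        ]
        with pytest.raises(ValueError, match="zero-variance"):
            tract_contrasts(pd.DataFrame(rows), reference_tract="a")

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            tract_contrasts(self.toy_table(), reference_tract="nope")


class TestMtDensityCorrelation:
    def tables(self, mt_values, density_values, roi="cc_1"):
        def tab(vals, _roi=roi):
            return pd.DataFrame(
                [
                    {"roi_id": _roi, "subject_id": f"s{i}", "mean": v, "sd": 0.0, "n_voxels": 5}
                    for i, v in enumerate(vals)
                ]
            )

        return tab(mt_values), tab(density_values)

    def test_proportional_maps_give_unit_correlation(self):
        mt = [1.8, 2.0, 2.2, 2.4]
        out = mt_density_correlation(*self.tables(mt, [2 * v for v in mt]))
        assert out["r"].item() == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_pearson_on_toy_table(self):
        mt = [1.8, 2.1, 2.0, 2.4]
        den = [0.9, 1.2, 0.8, 1.1]
        out = mt_density_correlation(*self.tables(mt, den))
        x, y = np.array(mt), np.array(den)
        r_expect = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out["r"].item() == pytest.approx(r_expect, rel=1e-12)

    def test_independent_draws_center_at_zero(self):
        rng = np.random.default_rng(9)
        rs = []
        for _ in range(200):
            mt = rng.normal(2.0, 0.2, 8)
            den = rng.normal(1.0, 0.1, 8)
            rs.append(mt_density_correlation(*self.tables(mt, den))["r"].item())
        assert abs(np.mean(rs)) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            mt_density_correlation(*self.tables([2.0, 2.0, 2.0], [1.0, 1.1, 0.9]))
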