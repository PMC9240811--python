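"""Group statistics: GLM contrasts, FDR, cluster extraction, ROI tables,
correlations and the dissociation report."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_records
from fcdtools import (
    GroupStatResult,
    InputError,
    SubjectRecord,
    VolumeMap,
    correlation_table,
    dissociation_report,
    extract_clusters,
    fdr_bh,
    glm_group_contrast,
    roi_group_compare,
    roi_means,
)
from fcdtools.stats import GroupContrastGLM


def pooled_t(a, b):
    """Textbook pooled two-sample t (patient minus control)."""
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestGlmGroupContrast:
    @pytest.mark.parametrize("seed", range(5))
    def test_no_covariates_equals_textbook_pooled_t(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        recs = make_records(n, rng)
        maps = rng.standard_normal((2 * n, 6, 1, 1))
        res = glm_group_contrast(maps, recs, covariates=())
        for v in range(6):
            ref = pooled_t(maps[:n, v, 0, 0], maps[n:, v, 0, 0])
            assert res.t_map[v, 0, 0] == pytest.approx(ref, abs=1e-10)

    def test_identical_groups_give_zero_t_unit_p(self, rng):
        recs = make_records(5, rng)
        one = rng.standard_normal((4, 1, 1))
        maps = np.stack([one] * 10)
        res = glm_group_contrast(maps, recs, covariates=())
        assert np.all(res.t_map == 0)
        assert np.all(res.p_map == 1)

    def test_age_confound_is_removed(self, rng):
        # map value driven purely by age: adjusted contrast must be null
        recs = make_records(12, rng)
        ages = np.array([r.age for r in recs])
        maps = (2.0 * ages)[:, None, None, None] + \
            rng.standard_normal((24, 5, 1, 1))
        res = glm_group_contrast(maps, recs)
        assert np.abs(res.t_map).max() < 4.0
        assert res.df == 24 - 4

    def test_too_few_subjects_rejected(self, rng):
        recs = make_records(2, rng)
        with pytest.raises(InputError):
            glm_group_contrast(rng.standard_normal((4, 2, 1, 1)), recs)

    def test_estimator_exposes_fitted_maps(self, rng):
        recs = make_records(6, rng)
        maps = [VolumeMap(rng.standard_normal((4, 4, 2)), np.eye(4))
                for _ in range(12)]
        est = GroupContrastGLM().fit(maps, recs)
        ref = glm_group_contrast(maps, recs)
        np.testing.assert_allclose(est.t_map_, ref.t_map)
        assert est.df_ == ref.df


class TestFdrBh:
    def bh_oracle(self, p, alpha):
        """Brute-force step-up: largest k with p_(k) <= k*alpha/m."""
        p = np.asarray(p, dtype=float)
        order = np.argsort(p, kind="stable")
        m = len(p)
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * alpha / m:
                k_max = k
        reject = np.zeros(m, bool)
        reject[order[:k_max]] = True
        return reject

    def test_worked_example(self):
        reject, q = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.2], alpha=0.05)
        assert reject.tolist() == [True, True, True, True, False]

    def test_all_ones_and_singleton(self):
        reject, q = fdr_bh(np.ones(8))
        assert not reject.any() and np.all(q == 1)
        reject, _ = fdr_bh([0.04], alpha=0.05)
        assert reject.all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 200) ** 2
        reject, _ = fdr_bh(p, alpha=0.1)
        np.testing.assert_array_equal(reject, self.bh_oracle(p, 0.1))

    def test_rejections_monotone_in_alpha(self, rng):
        p = rng.uniform(0, 0.3, 100)
        prev = None
        for alpha in (0.01, 0.05, 0.1, 0.2):
            rej, _ = fdr_bh(p, alpha=alpha)
            if prev is not None:
                assert np.all(prev <= rej)
            prev = rej

    def test_q_values_invariant_to_input_order(self, rng):
        p = rng.uniform(0, 1, 50)
        perm = rng.permutation(50)
        _, q = fdr_bh(p)
        _, q_perm = fdr_bh(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            fdr_bh([])


class TestExtractClusters:
    def test_empty_mask_gives_empty_table(self):
        table = extract_clusters(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4)),
                                 np.eye(4), min_extent=1)
        assert len(table) == 0

    def test_two_planted_blobs_with_known_peaks(self):
        t = np.zeros((10, 10, 10))
        sig = np.zeros((10, 10, 10), bool)
        blob1 = [(1, 1, 1), (1, 1, 2), (1, 2, 1), (2, 1, 1), (2, 2, 2)]
        blob2 = [(7, 7, 7), (7, 7, 8), (7, 8, 7), (8, 7, 7), (8, 8, 8),
                 (8, 8, 7), (7, 8, 8)]
        for v in blob1:
            t[v], sig[v] = 5.0, True
        t[2, 2, 2] = 6.5  # blob-1 peak
        for v in blob2:
            t[v], sig[v] = -4.0, True
        t[8, 8, 8] = -7.5  # blob-2 peak
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        table = extract_clusters(sig, t, affine, min_extent=2)
        assert [r.voxel_size for r in table.rows] == [7, 5]
        assert table.rows[0].sign == "decrease"
        assert table.rows[0].peak_mni == pytest.approx((24.0, 24.0, 24.0))
        assert table.rows[1].peak_mni == pytest.approx((6.0, 6.0, 6.0))

    def test_single_voxel_cluster_world_coordinate(self):
        t = np.zeros((5, 5, 5))
        sig = np.zeros((5, 5, 5), bool)
        t[2, 3, 4] = 3.3
        sig[2, 3, 4] = True
        affine = np.array([[2.0, 0, 0, -4], [0, 2.0, 0, -4], [0, 0, 2.0, -4],
                           [0, 0, 0, 1.0]])
        table = extract_clusters(sig, t, affine, min_extent=1)
        assert len(table) == 1
        assert table.rows[0].voxel_size == 1
        assert table.rows[0].peak_mni == pytest.approx((0.0, 2.0, 4.0))

    def test_min_extent_filters(self):
        t = np.zeros((6, 6, 6))
        sig = np.zeros((6, 6, 6), bool)
        t[0, 0, 0] = sig[0, 0, 0] = 1
        table = extract_clusters(sig, t, np.eye(4), min_extent=2)
        assert len(table) == 0

    def test_tied_peak_breaks_to_lowest_linear_index(self):
        t = np.zeros((4, 4, 4))
        sig = np.zeros((4, 4, 4), bool)
        for v in [(1, 1, 1), (1, 1, 2), (1, 2, 1)]:
            t[v], sig[v] = 2.0, True
        table = extract_clusters(sig, t, np.eye(4), min_extent=1)
        assert table.rows[0].peak_mni == pytest.approx((1.0, 1.0, 1.0))


class TestRoiTables:
    def test_roi_means_constant_and_degenerate(self, rng):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[0, 0, 0] = 1
        labels[2:, 2:, 2:] = 2
        maps = [VolumeMap(np.full((4, 4, 4), 5.0), np.eye(4)),
                VolumeMap(rng.standard_normal((4, 4, 4)), np.eye(4))]
        tab = roi_means(maps, labels)
        assert tab.loc[0, "roi_01"] == 5.0 and tab.loc[0, "roi_02"] == 5.0
        assert tab.loc[1, "roi_01"] == maps[1].data[0, 0, 0]

    def test_checkerboard_mean(self):
        labels = np.zeros((2, 2, 2), np.int32)
        labels[...] = 1
        data = np.indices((2, 2, 2)).sum(axis=0) % 2
        tab = roi_means([VolumeMap(data.astype(float), np.eye(4))], labels)
        assert tab.iloc[0, 0] == 0.5

    def test_roi_group_compare_matches_voxelwise_glm(self, rng):
        recs = make_records(8, rng)
        vals = rng.standard_normal(16)
        tab = pd.DataFrame({"roi_01": vals})
        res = roi_group_compare(tab, recs)
        ref = glm_group_contrast(vals.reshape(16, 1, 1, 1), recs)
        assert res.loc["roi_01", "t"] == pytest.approx(ref.t_map[0, 0, 0])

    def test_empty_label_map_rejected(self, rng):
        with pytest.raises(InputError):
            roi_means([VolumeMap(np.zeros((2, 2, 2)), np.eye(4))],
                      np.zeros((2, 2, 2), np.int32))


class TestCorrelationTable:
    def _tables(self, rng, n=6, perfect=None):
        recs = make_records(n, rng)
        g = rng.standard_normal(2 * n)
        if perfect == "pos":
            v = g.copy()
        elif perfect == "neg":
            v = -g
        else:
            v = rng.standard_normal(2 * n)
        gfcd = pd.DataFrame({"roi_01": g})
        gmv = pd.DataFrame({"roi_01": v})
        return gfcd, gmv, recs

    @pytest.mark.parametrize("kind,expected", [("pos", 1.0), ("neg", -1.0)])
    def test_perfect_correlations(self, rng, kind, expected):
        gfcd, gmv, recs = self._tables(rng, perfect=kind)
        tab = correlation_table(gfcd, gmv, recs)
        got = tab[(tab["pair"] == "gFCD-GMV")]["r_value"]
        assert got.to_numpy() == pytest.approx([expected, expected])

    def test_hand_computed_pearson(self):
        from scipy.stats import pearsonr

        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        assert pearsonr(x, y)[0] == pytest.approx(0.6)
        recs = [SubjectRecord(f"p{i}", "patient", 50.0 + i, "MF"[i % 2],
                              joa=10.0, duration_months=20.0) for i in range(4)]
        recs += [SubjectRecord(f"c{i}", "control", 50.0 + i, "MF"[i % 2])
                 for i in range(4)]
        gfcd = pd.DataFrame({"roi_01": np.concatenate([x, x])})
        gmv = pd.DataFrame({"roi_01": np.concatenate([y, y])})
        tab = correlation_table(gfcd, gmv, recs)
        cell = tab[(tab["pair"] == "gFCD-GMV") & (tab["group"] == "patient")]
        assert cell["r_value"].iloc[0] == pytest.approx(0.6)

    def test_zero_variance_flagged_not_raised(self, rng):
        gfcd, gmv, recs = self._tables(rng)
        gmv["roi_01"] = 3.0
        tab = correlation_table(gfcd, gmv, recs)
        assert tab[tab["pair"] == "gFCD-GMV"]["r_value"].isna().all()

    def test_adjusted_p_reported_alongside_raw(self, rng):
        gfcd, gmv, recs = self._tables(rng)
        tab = correlation_table(gfcd, gmv, recs)
        assert {"p_raw", "p_adjusted"} <= set(tab.columns)
        ok = tab["p_raw"].notna()
        assert np.all(tab.loc[ok, "p_adjusted"] >= tab.loc[ok, "p_raw"] - 1e-12)


def _stat_result(t_map, sig_mask, effect=None, affine=None):
    t_map = np.asarray(t_map, dtype=float)
    return GroupStatResult(
        t_map=t_map,
        p_map=np.where(sig_mask, 0.01, 0.5),
        q_map=np.where(sig_mask, 0.01, 0.5),
        sig_mask=np.asarray(sig_mask, bool),
        df=20,
        affine=np.eye(4) if affine is None else affine,
        mask=np.ones(t_map.shape, bool),
        effect_map=t_map if effect is None else np.asarray(effect, dtype=float),
    )


class TestDissociationReport:
    def test_planted_concordant_and_discordant_labels(self):
        shape = (12, 12, 4)
        t_g = np.zeros(shape)
        sig = np.zeros(shape, bool)
        t_m = np.zeros(shape)
        t_g[1:4, 1:4, 1:3], sig[1:4, 1:4, 1:3] = -5.0, True   # A: gFCD down
        t_m[1:4, 1:4, 1:3] = -3.0                             # A: GMV down
        t_g[8:11, 8:11, 1:3], sig[8:11, 8:11, 1:3] = 5.0, True  # B: gFCD up
        t_m[8:11, 8:11, 1:3] = -3.0                           # B: GMV down
        rep = dissociation_report(_stat_result(t_g, sig),
                                  _stat_result(t_m, np.zeros(shape, bool)),
                                  min_extent=5)
        assert len(rep.table) == 2
        by_sign = {int(r["gfcd_sign"]): r for _, r in rep.table.iterrows()}
        assert bool(by_sign[-1]["concordant"]) is True
        assert bool(by_sign[1]["concordant"]) is False
        assert rep.n_concordant == 1 and rep.n_discordant == 1

    def test_identical_results_all_concordant(self, rng):
        shape = (8, 8, 8)
        t = np.zeros(shape)
        sig = np.zeros(shape, bool)
        t[2:5, 2:5, 2:5], sig[2:5, 2:5, 2:5] = 4.0, True
        res = _stat_result(t, sig)
        rep = dissociation_report(res, res, min_extent=5)
        assert len(rep.table) == 1 and rep.n_discordant == 0

    def test_empty_inputs_give_empty_report(self):
        shape = (6, 6, 6)
        res = _stat_result(np.zeros(shape), np.zeros(shape, bool))
        rep = dissociation_report(res, res)
        assert len(rep.table) == 0
        assert "no FDR-significant" in rep.message
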