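"""F/F0 normalization, SNR filtering, R² matrices, synchrony, subsampling."""

import numpy as np
import pytest

import spherocal as sc
from spherocal.synchrony import ROITraceSet, RoiError

from conftest import make_roi_set


def _roi(data, fs=1.6, ids=None):
    data = np.asarray(data, dtype=float)
    ids = ids or [f"R{i}" for i in range(data.shape[1])]
    return ROITraceSet(data=data, frame_rate_hz=fs, roi_ids=ids)


class TestNormalize:
    def test_constant_column_becomes_ones(self):
        rs = _roi(np.full((100, 1), 500.0))
        out = sc.normalize_f_over_f0(rs)
        np.testing.assert_allclose(out.data, 1.0)

    def test_minimum_is_exactly_one(self):
        rs = make_roi_set(seed=3, n_rois=8).roi_set
        out = sc.normalize_f_over_f0(rs)
        for i in range(out.n_rois):
            assert out.data[:, i].min() == 1.0

    def test_scale_invariance(self):
        rs = make_roi_set(seed=5, n_rois=3).roi_set
        out1 = sc.normalize_f_over_f0(rs)
        scaled = _roi(rs.data * 3.0, fs=rs.frame_rate_hz, ids=rs.roi_ids)
        out2 = sc.normalize_f_over_f0(scaled)
        np.testing.assert_allclose(out1.data, out2.data, rtol=1e-12)

    def test_non_positive_input_names_roi(self):
        data = np.ones((50, 2)) * 100.0
        data[10, 1] = 0.0
        with pytest.raises(RoiError, match="R1"):
            sc.normalize_f_over_f0(_roi(data))


class TestSnrFilter:
    def test_strong_signal_retained_pure_noise_dropped(self):
        rng = np.random.default_rng(0)
        sig = make_roi_set(seed=1, n_rois=1, noise_sd=5.0).roi_set.data[:, 0]
        noise = 100.0 + rng.normal(0, 5, 480)
        rs = _roi(np.column_stack([sig, noise]), ids=["active", "silent"])
        kept, report = sc.filter_active_rois(rs, snr_threshold=3.0)
        assert kept.roi_ids == ["active"]
        assert report.loc[report.roi == "silent", "retained"].item() is False

    def test_noise_false_retention_rate_low(self):
        rng = np.random.default_rng(7)
        data = 100.0 + rng.normal(0, 5, size=(480, 200))
        kept, _report = sc.filter_active_rois(_roi(data), snr_threshold=3.0)
        assert kept.n_rois / 200 < 0.05

    def test_zero_threshold_is_vacuous(self):
        rs = make_roi_set(seed=2, n_rois=6).roi_set
        kept, _ = sc.filter_active_rois(rs, snr_threshold=0.0)
        assert kept.n_rois == 6

    def test_empty_result_warns(self):
        rs = _roi(np.full((50, 2), 100.0))
        with pytest.warns(UserWarning, match="no ROI"):
            kept, _ = sc.filter_active_rois(rs, snr_threshold=3.0)
        assert kept.n_rois == 0


class TestCorrelationMatrix:
    def test_matches_brute_force_pearson(self):
        # three short fixed traces; oracle computes r from the definition
        cols = np.array([
            [1.0, 2.0, 3.0, 4.0, 5.0, 4.0],
            [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],
            [5.0, 4.0, 4.0, 2.0, 2.0, 1.0],
        ]).T
        cm = sc.correlation_matrix(_roi(cols, fs=1.0))
        for i in range(3):
            for j in range(3):
                a, b = cols[:, i], cols[:, j]
                num = np.sum((a - a.mean()) * (b - b.mean()))
                den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
                assert cm.r2[i, j] == pytest.approx((num / den) ** 2, rel=1e-12)
        assert np.allclose(cm.r2, cm.r2.T)
        assert np.allclose(np.diag(cm.r2), 1.0)

    def test_duplicated_columns_all_ones(self):
        col = make_roi_set(seed=4, n_rois=1).roi_set.data[:, 0]
        cm = sc.correlation_matrix(_roi(np.column_stack([col, col, col])))
        np.testing.assert_allclose(cm.r2, 1.0)

    def test_anticorrelated_pair_scores_one(self):
        x = np.linspace(0, 1, 50)
        cm = sc.correlation_matrix(_roi(np.column_stack([x, -x]), fs=1.0))
        assert cm.r2[0, 1] == pytest.approx(1.0)
        assert cm.r[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_roi_excluded_with_warning(self):
        x = np.linspace(0, 1, 50)
        data = np.column_stack([x, np.full(50, 3.0), x**2])
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = sc.correlation_matrix(_roi(data, fs=1.0))
        assert cm.n_rois == 2

    def test_affine_rescaling_invariance(self):
        rs = make_roi_set(seed=6, n_rois=5).roi_set
        cm1 = sc.correlation_matrix(rs)
        rescaled = _roi(rs.data * 2.5 + 40.0, fs=rs.frame_rate_hz, ids=rs.roi_ids)
        cm2 = sc.correlation_matrix(rescaled)
        np.testing.assert_allclose(cm1.r2, cm2.r2, atol=1e-12)


class TestSynchronyScore:
    def test_identical_rois_score_one(self):
        col = make_roi_set(seed=4, n_rois=1).roi_set.data[:, 0]
        cm = sc.correlation_matrix(_roi(np.column_stack([col] * 4)))
        assert sc.synchrony_score(cm).score == pytest.approx(1.0)

    def test_single_pair_score_is_the_entry(self):
        from spherocal.synchrony import CorrelationMatrix
        r2 = np.array([[1.0, 0.49], [0.49, 1.0]])
        cm = CorrelationMatrix(r2=r2, r=np.sqrt(r2), roi_ids=["a", "b"])
        assert sc.synchrony_score(cm).score == pytest.approx(0.49)

    def test_diagonal_inclusion_flag(self):
        from spherocal.synchrony import CorrelationMatrix
        r2 = np.array([[1.0, 0.4], [0.4, 1.0]])
        cm = CorrelationMatrix(r2=r2, r=np.sqrt(r2), roi_ids=["a", "b"])
        assert sc.synchrony_score(cm, include_diagonal=True).score == pytest.approx(0.7)

    def test_single_roi_is_an_error(self):
        from spherocal.synchrony import CorrelationMatrix
        cm = CorrelationMatrix(r2=np.ones((1, 1)), r=np.ones((1, 1)), roi_ids=["a"])
        with pytest.raises(RoiError):
            sc.synchrony_score(cm)


class TestSubsample:
    def test_fewer_than_k_returns_all(self):
        rs = make_roi_set(seed=1, n_rois=10).roi_set
        res = sc.subsample_rois(rs, k=12, seed=0)
        assert res.roi_set.n_rois == 10
        assert res.attempts == 0

    def test_homogeneous_set_first_draw_qualifies(self):
        col = make_roi_set(seed=4, n_rois=1, noise_sd=0.0,
                           independent_rate=0.0, participation_p=1.0).roi_set.data[:, 0]
        rs = _roi(np.column_stack([col * (1 + 0.1 * i) for i in range(20)]))
        res = sc.subsample_rois(rs, k=12, seed=3)
        assert res.attempts == 1
        assert res.score == pytest.approx(1.0)

    def test_heterogeneous_subset_meets_tolerance(self):
        rs = make_roi_set(seed=8, n_rois=40, participation_p=0.7).roi_set
        res = sc.subsample_rois(rs, k=12, tolerance=0.05, seed=5)
        assert res.roi_set.n_rois == 12
        assert abs(res.score - res.population_score) / res.population_score <= 0.05

    def test_deterministic_under_seed(self):
        rs = make_roi_set(seed=8, n_rois=40, participation_p=0.7).roi_set
        a = sc.subsample_rois(rs, seed=5)
        b = sc.subsample_rois(rs, seed=5)
        assert a.indices == b.indices

    def test_unreachable_tolerance_reports_best_deviation(self):
        rs = make_roi_set(seed=8, n_rois=40, participation_p=0.7).roi_set
        with pytest.raises(RoiError, match="best relative deviation"):
            sc.subsample_rois(rs, tolerance=1e-9, seed=5, max_attempts=20)


class TestRoiFeatures:
    def test_identical_columns_give_identical_features(self):
        col = make_roi_set(seed=4, n_rois=1, noise_sd=0.0).roi_set.data[:, 0]
        rs = _roi(np.column_stack([col] * 3))
        norm = sc.normalize_f_over_f0(rs)
        table, summary = sc.roi_feature_table(norm)
        assert table["peak_count"].nunique() == 1
        assert table["mean_peak_amplitude"].std() == pytest.approx(0.0, abs=1e-12)
        assert summary["mean_peak_count"] == table["peak_count"].iloc[0]

    def test_empty_subset_is_an_error(self):
        rs = make_roi_set(seed=1, n_rois=3).roi_set
        with pytest.raises(RoiError, match="empty"):
            sc.roi_feature_table(rs.select([]))

    def test_genotype_contrast_in_count_and_synchrony(self):
        """The APOE4 preset is less active and less synchronous than wild type."""
        hits_count, hits_sync = 0, 0
        n_rep = 8
        for seed in range(n_rep):
            out = {}
            for name in ("PFC_wt", "PFC_APOE4"):
                cfg = sc.phenotype_preset(name, kind="roi", seed=seed)
                rs = sc.simulate_roi_set(cfg).roi_set
                norm = sc.normalize_f_over_f0(rs)
                cm = sc.correlation_matrix(norm)
                score = sc.synchrony_score(cm)
                sub = sc.subsample_rois(norm, cm, seed=seed)
                _table, summary = sc.roi_feature_table(sub.roi_set, score)
                out[name] = summary
            hits_count += out["PFC_APOE4"]["mean_peak_count"] < out["PFC_wt"]["mean_peak_count"]
            hits_sync += out["PFC_APOE4"]["synchrony_score"] < out["PFC_wt"]["synchrony_score"]
        assert hits_count >= n_rep - 1
        assert hits_sync >= n_rep - 1


def test_mean_trace_ci_geometry():
    from spherocal.synchrony import mean_trace_with_ci

    rs = make_roi_set(seed=2, n_rois=10).roi_set
    df = mean_trace_with_ci(rs)
    assert len(df) == rs.n_frames
    assert (df["ci_high"] >= df["mean"]).all()
    assert (df["ci_low"] <= df["mean"]).all()
    np.testing.assert_allclose(df["mean"], rs.data.mean(axis=1))
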