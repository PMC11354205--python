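"""ROI placement, trimmed-median representative HU, and vBMD measurement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import qctscreen as q
from qctscreen.errors import (
    MeasurementFailureError,
    ProtocolMismatchError,
    ROIInfeasibleError,
)
from conftest import trimmed_median_oracle


class TestWindowNormalize:
    @pytest.mark.parametrize(
        "hu,expected",
        [(300.0, 0.5), (-125.0, 0.0), (725.0, 1.0), (87.5, 0.25), (-500.0, 0.0), (1000.0, 1.0)],
    )
    def test_known_points(self, hu, expected):
        assert q.window_normalize(np.array([hu]))[0] == pytest.approx(expected)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            q.window_normalize(np.zeros(3), width=0.0)

    @given(st.lists(st.floats(-2000, 3000), min_size=2, max_size=50))
    def test_monotone_non_decreasing(self, values):
        arr = np.sort(np.asarray(values))
        out = q.window_normalize(arr)
        assert np.all(np.diff(out) >= 0)


class TestTrimmedMedian:
    def test_constant_distribution(self):
        r = q.trimmed_median(np.full(100, 100.0), trim_fraction=0.01)
        assert r.value == 100.0
        assert r.n_raw == 100
        assert r.n_used == 100  # floor(0.005*100) = 0 per tail

    def test_sequence_0_to_999_trim_1pct(self):
        r = q.trimmed_median(np.arange(1000.0), trim_fraction=0.01)
        assert r.n_used == 990  # 5 removed per tail
        assert r.value == 499.5

    def test_outliers_ignored(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([rng.normal(100, 10, 500), np.full(5, 800.0)])
        r = q.trimmed_median(values, trim_fraction=0.01)
        assert 97.0 <= r.value <= 103.0

    def test_upper_tail_mode(self):
        values = np.arange(100.0)
        r = q.trimmed_median(values, trim_fraction=0.1, tail="upper")
        assert r.n_used == 90
        assert r.value == np.median(np.arange(90.0))

    def test_trim_robustness_to_high_hu_contamination(self):
        rng = np.random.default_rng(13)
        base = rng.normal(100, 10, 2000)
        clean = q.trimmed_median(base, trim_fraction=0.01).value
        k = int(0.005 * base.size)
        contaminated = np.concatenate([base, np.full(k, 2000.0)])
        dirty = q.trimmed_median(contaminated, trim_fraction=0.01).value
        assert abs(dirty - clean) < 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            q.trimmed_median(np.array([]))

    @given(
        st.lists(st.floats(-1000, 3000, allow_nan=False), min_size=1, max_size=500),
        st.sampled_from([0.0, 0.01, 0.1]),
    )
    def test_matches_sort_trim_oracle(self, values, trim):
        r = q.trimmed_median(np.array(values), trim_fraction=trim)
        expected, n_raw, n_used = trimmed_median_oracle(values, trim)
        assert r.value == expected
        assert (r.n_raw, r.n_used) == (n_raw, n_used)
        assert min(values) <= r.value <= max(values)


class TestPlaceRoi:
    def test_roi_avoids_cortical_shell(self, two_vertebra_clean):
        ct, gt = two_vertebra_clean
        instances = q.instance_label(q.segment_lumbar(ct, ground_truth=gt, method="oracle"))
        for v in instances:
            roi = q.place_roi(v, ct.spacing, ct.orientation)
            assert (roi.as_mask(ct.shape) & gt.shell_mask()).sum() == 0

    def test_roi_avoids_vein_channel(self, two_vertebra_clean):
        ct, gt = two_vertebra_clean
        instances = q.instance_label(q.segment_lumbar(ct, ground_truth=gt, method="oracle"))
        for v in instances:
            roi = q.place_roi(v, ct.spacing, ct.orientation)
            assert (roi.as_mask(ct.shape) & gt.vein_mask()).sum() == 0

    def test_roi_inside_eroded_body(self, two_vertebra_clean):
        ct, gt = two_vertebra_clean
        instances = q.instance_label(q.segment_lumbar(ct, ground_truth=gt, method="oracle"))
        v = instances[0]
        roi = q.place_roi(v, ct.spacing, ct.orientation)
        # ROI subset of the instance's own voxels (hence of the body mask)
        assert (~v.mask[tuple(roi.indices.T)]).sum() == 0

    def test_tiny_body_infeasible(self):
        ct, gt = q.generate_vertebra_volume(
            [q.VertebraSpec(trabecular_density=100.0, body_radius_mm=3.0,
                            cortical_thickness_mm=1.0, vein_channel=False)],
            noise_sigma=0.0, seed=0, in_plane_shape=(48, 48),
        )
        instances = q.instance_label(q.segment_lumbar(ct, ground_truth=gt, method="oracle"))
        with pytest.raises(ROIInfeasibleError):
            q.place_roi(instances[0], ct.spacing, ct.orientation)

    def test_roi_spacing_invariance_of_erosion(self):
        # 0.5 mm in-plane voxels: erosion radius doubles in voxels, ROI still safe
        ct, gt = q.generate_vertebra_volume(
            [q.VertebraSpec(trabecular_density=100.0)],
            noise_sigma=0.0, seed=0, spacing=(0.5, 0.5, 1.0), in_plane_shape=(256, 256),
        )
        instances = q.instance_label(q.segment_lumbar(ct, ground_truth=gt, method="oracle"))
        roi = q.place_roi(instances[0], ct.spacing, ct.orientation)
        assert (roi.as_mask(ct.shape) & gt.shell_mask()).sum() == 0
        assert (roi.as_mask(ct.shape) & gt.vein_mask()).sum() == 0


class TestMeasureVbmd:
    def test_clean_volume_recovers_density(self, two_vertebra_clean, identity_model):
        ct, gt = two_vertebra_clean
        instances = q.instance_label(q.segment_lumbar(ct, ground_truth=gt, method="oracle"))
        result = q.measure_vbmd(ct, instances, identity_model)
        assert result.combined_l1_2 == pytest.approx(100.0, abs=0.5)
        assert not result.single_vertebra

    def test_combined_is_unweighted_mean(self, identity_model):
        specs = [
            q.VertebraSpec(level="L1", trabecular_density=90.0),
            q.VertebraSpec(level="L2", trabecular_density=110.0),
        ]
        ct, gt = q.generate_vertebra_volume(specs, noise_sigma=0.0, seed=0)
        instances = q.instance_label(q.segment_lumbar(ct, ground_truth=gt, method="oracle"))
        result = q.measure_vbmd(ct, instances, identity_model)
        assert result.combined_l1_2 == pytest.approx(
            (result.per_vertebra["L1"] + result.per_vertebra["L2"]) / 2
        )
        assert result.per_vertebra["L1"] == pytest.approx(90.0, abs=0.5)
        assert result.per_vertebra["L2"] == pytest.approx(110.0, abs=0.5)

    def test_single_vertebra_scan_flags_and_uses_l1(self, identity_model):
        ct, gt = q.generate_vertebra_volume(
            [q.VertebraSpec(level="L1", trabecular_density=95.0)], noise_sigma=0.0, seed=0
        )
        instances = q.instance_label(q.segment_lumbar(ct, ground_truth=gt, method="oracle"))
        result = q.measure_vbmd(ct, instances, identity_model)
        assert result.single_vertebra
        assert result.combined_l1_2 == pytest.approx(result.per_vertebra["L1"])
        assert "L2" in result.failures

    def test_no_measurable_vertebra_raises(self, identity_model):
        ct, gt = q.generate_vertebra_volume(
            [q.VertebraSpec(trabecular_density=100.0, body_radius_mm=4.0,
                            cortical_thickness_mm=1.0, vein_channel=False)],
            noise_sigma=0.0, seed=0, in_plane_shape=(48, 48),
        )
        instances = q.instance_label(q.segment_lumbar(ct, ground_truth=gt, method="oracle"))
        with pytest.raises(MeasurementFailureError):
            q.measure_vbmd(ct, instances, identity_model)

    def test_protocol_mismatch_is_an_error(self, two_vertebra_clean, identity_model):
        ct, gt = two_vertebra_clean
        instances = q.instance_label(q.segment_lumbar(ct, ground_truth=gt, method="oracle"))
        import dataclasses
        other = dataclasses.replace(identity_model, protocol="siemens_120kvp_sharp")
        with pytest.raises(ProtocolMismatchError):
            q.measure_vbmd(ct, instances, other)

    def test_end_to_end_recovery_under_noise(self, identity_model):
        # rule-based segmentation + noisy volumes, densities spanning the
        # diagnostic range: recovered within +/- 5 mg/cm3
        specs = [
            q.VertebraSpec(level="L1", trabecular_density=60.0),
            q.VertebraSpec(level="L2", trabecular_density=160.0),
        ]
        ct, gt = q.generate_vertebra_volume(specs, noise_sigma=10.0, seed=31)
        instances = q.instance_label(q.segment_lumbar(ct, method="rule_based"))
        result = q.measure_vbmd(ct, instances, identity_model)
        assert result.rois["L1"].n_voxels >= 500
        assert result.per_vertebra["L1"] == pytest.approx(60.0, abs=5.0)
        assert result.per_vertebra["L2"] == pytest.approx(160.0, abs=5.0)
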