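"""dR/R computation, mask-filtered pooling, depth resolution, OISI signal."""

import numpy as np
import pytest

from insfoct import AcquisitionProtocol, compute_baseline, default_scene
from insfoct.dataio import BScanSeries
from insfoct.response import (FractionalChangeStack, activation_map,
                              aggregate_foct, center_roi, depth_resolved,
                              fractional_change, oisi_signal)
from insfoct.significance import BaselineStats, detect_significant
from insfoct.synthetic import simulate_bm_series, simulate_oisi_series


def make_stack(drr, time_s=None, valid=None):
    drr = np.asarray(drr, dtype=float)
    if time_s is None:
        time_s = np.arange(drr.shape[2]) * 0.01 - 0.2
    if valid is None:
        valid = np.ones(drr.shape[:2], dtype=bool)
    return FractionalChangeStack(drr=drr, valid=valid, time_s=np.asarray(time_s))


class TestFractionalChange:
    def test_identity_gives_zero(self, small_protocol):
        n = small_protocol.n_frames(100.0)
        s = BScanSeries(data=np.full((4, 4, n), 9.0), protocol=small_protocol,
                        fps=100.0)
        out = fractional_change(s, compute_baseline(s))
        assert np.allclose(out.drr, 0.0)

    def test_programmed_ratio(self, small_protocol):
        """I = 1.025 Ib yields dR/R = 0.025 exactly."""
        n = small_protocol.n_frames(100.0)
        n_pre = small_protocol.n_prestim_frames(100.0)
        data = np.full((2, 2, n), 8.0)
        data[:, :, n_pre:] = 8.0 * 1.025
        s = BScanSeries(data=data, protocol=small_protocol, fps=100.0)
        out = fractional_change(s, compute_baseline(s))
        assert np.allclose(out.drr[:, :, n_pre:], 0.025)

    def test_matches_elementwise_oracle(self, small_protocol, rng):
        n = small_protocol.n_frames(100.0)
        data = rng.uniform(1.0, 10.0, (5, 6, n))
        s = BScanSeries(data=data, protocol=small_protocol, fps=100.0)
        b = compute_baseline(s)
        out = fractional_change(s, b)
        for _ in range(200):
            i, j, k = rng.integers(5), rng.integers(6), rng.integers(n)
            assert out.drr[i, j, k] == pytest.approx(
                (data[i, j, k] - b.Ib[i, j]) / b.Ib[i, j])

    def test_zero_baseline_excluded_not_nan(self, small_protocol):
        n = small_protocol.n_frames(100.0)
        data = np.ones((2, 2, n))
        data[0, 0, :] = 0.0
        s = BScanSeries(data=data, protocol=small_protocol, fps=100.0)
        out = fractional_change(s, compute_baseline(s))
        assert not out.valid[0, 0]
        assert np.isfinite(out.drr).all()


class TestAggregation:
    def _uniform_labels(self, shape, sign=1):
        labels = np.zeros(shape, dtype=np.int8)
        labels[:, :, shape[2] // 2] = sign
        return labels

    def test_all_positive_constant_gives_constant(self):
        stack = make_stack(np.full((3, 3, 40), 0.02))
        labels = self._uniform_labels((3, 3, 40))
        tc = aggregate_foct([stack], [labels], response_window_s=(0.0, 0.3))
        assert np.allclose(tc.value, 0.02)

    def test_negative_responses_inverted_before_averaging(self):
        """Half the pixels at -c labeled negative, half at +c labeled positive:
        the pooled course is +c (sign normalization)."""
        drr = np.empty((2, 2, 40))
        drr[0] = 0.03
        drr[1] = -0.03
        stack = make_stack(drr)
        labels = np.zeros((2, 2, 40), dtype=np.int8)
        labels[0, :, 20] = 1
        labels[1, :, 20] = -1
        tc = aggregate_foct([stack], [labels], response_window_s=(0.0, 0.3))
        assert np.allclose(tc.value, 0.03)

    def test_inversion_uses_label_sign_not_sample_sign(self):
        drr = np.full((1, 1, 40), -0.01)
        drr[0, 0, 25] = +0.02            # noisy positive excursion
        stack = make_stack(drr)
        labels = np.zeros((1, 1, 40), dtype=np.int8)
        labels[0, 0, 20] = -1
        tc = aggregate_foct([stack], [labels], response_window_s=(0.0, 0.3))
        assert tc.value[25] == pytest.approx(-0.02)
        assert tc.value[24] == pytest.approx(0.01)

    def test_masks_restrict_pooling(self):
        drr = np.zeros((2, 2, 40))
        drr[0, 0] = 0.05
        drr[1, 1] = 0.99
        stack = make_stack(drr)
        labels = np.zeros((2, 2, 40), dtype=np.int8)
        labels[0, 0, 20] = 1
        labels[1, 1, 20] = 1
        vascular = np.array([[True, True], [True, False]])   # exclude (1,1)
        tc = aggregate_foct([stack], [labels], vascular_mask=vascular,
                            response_window_s=(0.0, 0.3))
        assert np.allclose(tc.value, 0.05)

    def test_no_eligible_pixels_flagged_not_zero(self):
        stack = make_stack(np.zeros((2, 2, 40)))
        labels = np.zeros((2, 2, 40), dtype=np.int8)
        tc = aggregate_foct([stack], [labels])
        assert np.isnan(tc.value).all()
        assert np.all(tc.n_pixels == 0)

    def test_per_frame_mode_nan_outside_coverage(self):
        drr = np.full((1, 1, 40), 0.04)
        stack = make_stack(drr)
        labels = np.zeros((1, 1, 40), dtype=np.int8)
        labels[0, 0, 30] = 1
        tc = aggregate_foct([stack], [labels], pooling="per_frame",
                            run_length=5)
        covered = slice(30, 35)
        assert np.allclose(tc.value[covered], 0.04)
        assert np.isnan(tc.value[:30]).all()

    def test_gain_invariance_of_pooled_course(self, small_protocol, small_scene):
        """dR/R ratio form: a global intensity gain leaves the course unchanged."""
        trials, _ = simulate_bm_series(small_protocol, small_scene, 1.0, seed=5,
                                       n_trials=1)
        s = trials[0]
        b = compute_baseline(s)
        labels = detect_significant(s, b)
        tc1 = aggregate_foct([fractional_change(s, b)], [labels],
                             response_window_s=(0.0, 0.8))
        s2 = BScanSeries(data=s.data * 3.0, protocol=s.protocol, fps=s.fps)
        b2 = compute_baseline(s2)
        labels2 = detect_significant(s2, b2)
        tc2 = aggregate_foct([fractional_change(s2, b2)], [labels2],
                             response_window_s=(0.0, 0.8))
        assert np.allclose(tc1.value, tc2.value, atol=1e-6, equal_nan=True)


class TestDepthResolved:
    def test_single_full_depth_bin_equals_whole_frame_course(self):
        rng = np.random.default_rng(0)
        drr = rng.normal(0, 0.01, (10, 4, 40))
        stack = make_stack(drr)
        labels = np.zeros((10, 4, 40), dtype=np.int8)
        labels[2:8, :, 20] = 1
        whole = aggregate_foct([stack], [labels], response_window_s=(0.0, 0.3))
        bins = depth_resolved([stack], [labels], z_pitch_um=10.0,
                              bin_um=100.0, n_bins=1,
                              response_window_s=(0.0, 0.3))
        assert np.allclose(bins[0].value, whole.value, equal_nan=True)

    def test_activation_confined_to_programmed_depth(self, small_protocol):
        """Activation to 150 um: the first bin responds, the deepest does not."""
        scene = default_scene(small_protocol, activation_depth_um=150.0,
                              noise_fraction=0.0)
        scene.vessels = []
        scene.amplitude_cv = 0.0
        trials, _ = simulate_bm_series(small_protocol, scene, 1.0, seed=6,
                                       n_trials=1)
        s = trials[0]
        b = compute_baseline(s)
        labels = detect_significant(s, b)
        stacks = [fractional_change(s, b)]
        bins = depth_resolved(stacks, [labels],
                              z_pitch_um=small_protocol.z_pitch_um,
                              bin_um=80.0, n_bins=3,
                              response_window_s=(0.0, 0.8))
        assert np.nanmax(bins[0].value) > 0.01
        assert np.isnan(bins[2].value).all()     # no significant pixel there

    def test_bins_beyond_imaged_depth_rejected(self):
        stack = make_stack(np.zeros((5, 4, 40)))
        with pytest.raises(ValueError):
            depth_resolved([stack], [np.zeros((5, 4, 40), dtype=np.int8)],
                           z_pitch_um=10.0, bin_um=100.0, n_bins=6)


class TestOISISignal:
    def test_constant_frames_give_zero_course(self, small_protocol):
        n = small_protocol.n_frames(20.0)
        s = BScanSeries(data=np.full((10, 10, n), 50.0),
                        protocol=small_protocol, fps=20.0, modality="oisi")
        roi = center_roi((10, 10), (5, 5), 4)
        tc = oisi_signal([s], roi)
        assert np.allclose(tc.value, 0.0)

    def test_roi_outside_activation_stays_at_baseline(self, small_protocol,
                                                      quiet_scene):
        trials, gt = simulate_oisi_series(small_protocol, quiet_scene, 1.0,
                                          seed=7, n_trials=2)
        shape = trials[0].data.shape[:2]
        inside = center_roi(shape, (shape[0] // 2, shape[1] // 2), 6)
        outside = center_roi(shape, (2, 2), 4)
        tc_in = oisi_signal(trials, inside)
        tc_out = oisi_signal(trials, outside)
        assert np.abs(tc_out.value).max() < 1e-9
        assert np.abs(tc_in.value).max() == pytest.approx(
            quiet_scene.oisi_template.peak_amplitude, rel=0.05)

    def test_empty_roi_rejected(self, small_protocol):
        n = small_protocol.n_frames(20.0)
        s = BScanSeries(data=np.ones((4, 4, n)), protocol=small_protocol,
                        fps=20.0, modality="oisi")
        with pytest.raises(ValueError):
            oisi_signal([s], np.zeros((4, 4), dtype=bool))


class TestActivationMap:
    def test_no_significant_pixels_empty_map(self):
        stack = make_stack(np.zeros((4, 4, 40)))
        labels = np.zeros((4, 4, 40), dtype=np.int8)
        amap, count = activation_map([stack], [labels])
        assert count == 0 and np.isnan(amap).all()

    def test_noise_free_count_equals_programmed_area(self, small_protocol,
                                                     quiet_scene):
        trials, gt = simulate_bm_series(small_protocol, quiet_scene, 1.0,
                                        seed=8, n_trials=1)
        s = trials[0]
        b = compute_baseline(s)
        labels = detect_significant(s, b)
        amap, count = activation_map([fractional_change(s, b)], [labels],
                                     time_window_s=(0.0, 1.0))
        programmed = int(gt.activation_region.sum())
        assert count == programmed
        assert np.isfinite(amap[gt.activation_region]).all()

    def test_count_monotone_in_k_sigma(self, small_protocol):
        scene = default_scene(small_protocol)
        trials, _ = simulate_bm_series(small_protocol, scene, 1.0, seed=9,
                                       n_trials=1)
        s = trials[0]
        b = compute_baseline(s)
        counts = []
        for k in (1.0, 3.0, 6.0):
            labels = detect_significant(s, b, k_sigma=k)
            _, count = activation_map([fractional_change(s, b)], [labels])
            counts.append(count)
        assert counts[0] >= counts[1] >= counts[2]
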