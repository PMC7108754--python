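"""Generator ground-truth recovery and reproducibility."""

import numpy as np
import pytest

from insfoct import AcquisitionProtocol, SceneSpec
from insfoct import synthetic
from insfoct.synthetic import (simulate_bm_series, simulate_oisi_series,
                               simulate_flow_phantom, simulate_spike_trains)


class TestBMSeries:
    def test_static_scene_frames_identical(self, small_protocol, quiet_scene):
        scene = quiet_scene
        scene.activation_region = np.zeros_like(scene.activation_region)
        trials, _ = simulate_bm_series(small_protocol, scene, exposure=1.0,
                                       seed=0, n_trials=1)
        data = trials[0].data
        assert np.array_equal(data[:, :, 0:1].repeat(data.shape[2], axis=2), data)

    def test_programmed_elevation_recovered_at_peak(self, small_protocol, quiet_scene):
        """Noise-free activation pixels carry exactly the programmed factor."""
        tpl = quiet_scene.response_template
        trials, gt = simulate_bm_series(small_protocol, quiet_scene,
                                        exposure=1.0, seed=1, n_trials=2)
        t = trials[0].time_s
        k_peak = int(np.argmin(np.abs(t - tpl.peak_delay_s)))
        for s in trials:
            act = s.data[gt.activation_region, :]
            ratio = act[:, k_peak] / act[:, 0]
            expected = 1 + tpl.peak_amplitude * tpl.shape(t[k_peak])
            assert ratio == pytest.approx(expected, rel=1e-5)

    def test_monte_carlo_mean_elevation_with_noise(self, small_protocol, quiet_scene):
        """With speckle + noise the mean elevation is 1.025 +/- sampling error."""
        scene = quiet_scene
        scene.noise_floor = 0.2
        trials, gt = simulate_bm_series(small_protocol, scene, exposure=1.0,
                                        seed=2, n_trials=10)
        tpl = scene.response_template
        t = trials[0].time_s
        k_peak = int(np.argmin(np.abs(t - tpl.peak_delay_s)))
        n_pre = small_protocol.n_prestim_frames(trials[0].fps)
        ratios = []
        for s in trials:
            act = s.data[gt.activation_region, :]
            ratios.append(act[:, k_peak] / act[:, :n_pre].mean(axis=1))
        ratios = np.concatenate(ratios)
        assert ratios.size >= 1e4 / 10          # plenty of samples pooled
        expected = 1 + tpl.peak_amplitude * tpl.shape(t[k_peak])
        assert ratios.mean() == pytest.approx(expected, abs=3e-3)

    def test_default_frame_count_at_100fps(self, small_scene):
        proto = AcquisitionProtocol()
        trials, _ = simulate_bm_series(proto, default_scene_for(proto),
                                       exposure=0.0, seed=0, n_trials=1,
                                       fps=100.0)
        assert trials[0].data.shape[2] == 2000

    def test_vessel_pixels_decorrelate_tissue_does_not(self, small_protocol):
        from insfoct import default_scene
        scene = default_scene(small_protocol)
        trials, gt = simulate_bm_series(small_protocol, scene, exposure=0.0,
                                        seed=3, n_trials=1)
        data = trials[0].data.astype(float)
        vm = scene.vessel_mask()
        corr = lambda m: np.corrcoef(data[m, 0], data[m, -1])[0, 1]
        tissue = ~vm & ~scene.tail_mask()
        assert corr(tissue) > 0.98
        assert corr(vm) < 0.5

    def test_bit_reproducible_with_fixed_seed(self, small_protocol, small_scene):
        a, _ = simulate_bm_series(small_protocol, small_scene, 1.0, seed=7,
                                  n_trials=2)
        b, _ = simulate_bm_series(small_protocol, small_scene, 1.0, seed=7,
                                  n_trials=2)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.data, sb.data)

    def test_empty_scene_rejected(self, small_protocol):
        with pytest.raises(ValueError):
            SceneSpec(reflectivity_map=np.zeros((0, 0)),
                      activation_region=np.zeros((0, 0), dtype=bool))

    def test_negative_exposure_rejected(self, small_protocol, small_scene):
        with pytest.raises(ValueError):
            simulate_bm_series(small_protocol, small_scene, exposure=-1.0, seed=0)


def default_scene_for(proto):
    from insfoct import default_scene
    return default_scene(proto)


class TestOISISeries:
    def test_zero_amplitude_frames_statistically_identical(self, small_protocol,
                                                           quiet_scene):
        trials, _ = simulate_oisi_series(small_protocol, quiet_scene,
                                         exposure=0.0, seed=0, n_trials=1)
        data = trials[0].data
        assert np.array_equal(data[:, :, 0:1].repeat(data.shape[2], axis=2), data)

    def test_programmed_darkening_recovered(self, small_protocol, quiet_scene):
        tpl = quiet_scene.oisi_template
        trials, gt = simulate_oisi_series(small_protocol, quiet_scene,
                                          exposure=1.0, seed=1, n_trials=1)
        t = trials[0].time_s
        k = int(np.argmin(np.abs(t - tpl.peak_delay_s)))
        frac = trials[0].data[gt.activation_region, k] / \
            trials[0].data[gt.activation_region, 0]
        expected = 1 - tpl.peak_amplitude * tpl.shape(t[k])
        assert frac.mean() == pytest.approx(expected, abs=1e-5)

    def test_20fps_trial_has_400_frames(self):
        proto = AcquisitionProtocol()
        trials, _ = simulate_oisi_series(proto, default_scene_for(proto),
                                         exposure=0.0, seed=0, n_trials=1,
                                         fps=20.0)
        assert trials[0].data.shape[2] == 400


class TestFlowPhantom:
    def test_zero_velocity_is_static_up_to_noise(self):
        ph = simulate_flow_phantom([0.0, 0.6], seed=0, n_frames=60,
                                   noise_floor=0.0)
        d = ph[0.0].data
        assert np.array_equal(d[:, :, 0:1].repeat(d.shape[2], axis=2), d)

    def test_decorrelation_saturates_at_full_refresh(self):
        """Velocities beyond one beam width per frame give the same statistics."""
        from insfoct.angiography import decorrelation_velocity_curve
        ph = simulate_flow_phantom([5.0, 500.0], seed=1, n_frames=240)
        curve = decorrelation_velocity_curve(ph)
        d = curve["decorrelation"].to_numpy()
        assert d[1] == pytest.approx(d[0], rel=0.02)

    def test_strictly_increasing_over_programmed_range(self):
        from insfoct.angiography import decorrelation_velocity_curve
        ph = simulate_flow_phantom([0.0, 0.3, 0.6, 0.9, 1.2], seed=2)
        d = decorrelation_velocity_curve(ph)["decorrelation"].to_numpy()
        assert np.all(np.diff(d) > 0)

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            simulate_flow_phantom([-0.1], seed=0)


class TestSpikeTrains:
    def test_default_emits_30_trials(self):
        assert len(simulate_spike_trains(seed=0)) == 30

    def test_prestim_count_matches_poisson_mean(self):
        """5 Hz baseline, 30 trials, 0.5-s window: expect 75 +/- Poisson error."""
        trials = simulate_spike_trains(baseline_rate_hz=5.0, stim_rate_hz=5.0,
                                       n_trials=30, seed=1)
        count = sum(int(np.sum((t >= -0.5) & (t < 0.0))) for t in trials)
        assert abs(count - 75) < 4 * np.sqrt(75)

    def test_rate_matched_train_gives_flat_psth(self):
        from insfoct.ephys import SpikeData, build_psth
        trials = simulate_spike_trains(baseline_rate_hz=20.0, stim_rate_hz=20.0,
                                       n_trials=50, seed=2)
        psth = build_psth(SpikeData(trials=trials), bin_ms=100.0)
        rate = psth.rate_hz
        assert rate.mean() == pytest.approx(20.0, rel=0.05)
        # no bin deviates beyond 5x the Poisson STD of a 100-ms, 50-trial bin
        sd = np.sqrt(20.0 / (0.1 * 50))
        assert np.all(np.abs(rate - 20.0) < 5 * sd)

    def test_timestamps_sorted_and_within_trial(self):
        proto = AcquisitionProtocol()
        for t in simulate_spike_trains(seed=3, protocol=proto):
            assert np.all(np.diff(t) >= 0)
            assert t.min() >= -proto.prestim_s and t.max() <= 19.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_spike_trains(baseline_rate_hz=-1.0)
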