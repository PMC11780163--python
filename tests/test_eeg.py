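"""EEG pipeline: FIR filtering, referencing, epoching, PSD, IAF, workload."""

import numpy as np
import pytest
from scipy import signal

from multisense.eeg import (
    bandpass_fir,
    band_power,
    condition_workload,
    detect_iaf,
    epoch,
    rereference_common_average,
    welch_psd,
    workload,
)
from multisense.synthetic import (
    EEGParams,
    EEGRecording,
    ObserverSpec,
    SMARTING_24_CHANNELS,
    simulate_eeg,
)

FS = 500.0


def _sine_recording(freqs_per_channel, duration=40.0, channels=None):
    channels = channels or SMARTING_24_CHANNELS[: len(freqs_per_channel)]
    t = np.arange(int(duration * FS)) / FS
    data = np.stack([np.sin(2 * np.pi * f * t) for f in freqs_per_channel])
    return EEGRecording(list(channels), FS, data, [])


class TestFilter:
    def test_passband_sinusoid_preserved_within_one_percent(self):
        rec = _sine_recording([10.0])
        out = bandpass_fir(rec)
        mid = slice(8000, 12000)  # away from convolution edges
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("f_stop", [0.1, 60.0], ids=["drift", "line"])
    def test_stopband_attenuated_beyond_20db(self, f_stop):
        """Oracle: the designed taps' frequency response at the stop frequency."""
        taps = signal.firwin(8001, [0.5, 42.0], window="hamming",
                             pass_zero=False, fs=FS)
        _, h = signal.freqz(taps, worN=[f_stop], fs=FS)
        assert 20 * np.log10(np.abs(h[0])) < -20.0

    def test_group_delay_is_compensated(self):
        """A burst stays centred where it was: linear phase applied centred."""
        n = 12000
        data = np.zeros((1, n))
        data[0, 6000:6050] = np.sin(2 * np.pi * 10 * np.arange(50) / FS)
        rec = EEGRecording(["Cz"], FS, data, [])
        out = bandpass_fir(rec)
        assert abs(int(np.argmax(np.abs(out.data[0]))) - int(np.argmax(np.abs(data[0])))) < 60

    def test_recording_shorter_than_filter_rejected(self):
        rec = EEGRecording(["Cz"], FS, np.zeros((1, 4000)), [])
        with pytest.raises(ValueError, match="shorter"):
            bandpass_fir(rec)


class TestReference:
    def test_antisymmetric_pair_unchanged(self):
        rec = EEGRecording(["a", "b"], FS, np.array([[1.0, 2.0], [-1.0, -2.0]]), [])
        out = rereference_common_average(rec)
        np.testing.assert_allclose(out.data, rec.data)

    def test_identical_channels_become_zero(self):
        rec = EEGRecording(["a", "b"], FS, np.ones((2, 10)), [])
        assert np.allclose(rereference_common_average(rec).data, 0.0)

    def test_channel_sum_is_zero_at_every_sample(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(list("abcd"), FS, rng.normal(size=(4, 100)), [])
        out = rereference_common_average(rec)
        np.testing.assert_allclose(out.data.sum(axis=0), 0.0, atol=1e-12)


class TestEpoching:
    def test_half_open_window_of_875_samples(self):
        rec = EEGRecording(["Cz"], FS, np.arange(2000.0)[None, :], [(0, "L1", "T")])
        eps = epoch(rec)
        assert eps[0].data.shape == (1, 875)
        assert eps[0].data[0, 0] == 0.0 and eps[0].data[0, -1] == 874.0

    def test_one_epoch_per_event_with_labels(self):
        events = [(i * 900, "L1", "VTB") for i in range(100)]
        rec = EEGRecording(["Cz"], FS, np.zeros((1, 100 * 900 + 875)), events)
        eps = epoch(rec)
        assert len(eps) == 100
        assert all(e.condition == "VTB" for e in eps)

    def test_truncated_event_skipped_with_warning(self):
        rec = EEGRecording(["Cz"], FS, np.zeros((1, 1000)), [(0, "L1", "T"), (500, "L1", "T")])
        with pytest.warns(UserWarning, match="truncated"):
            eps = epoch(rec)
        assert len(eps) == 1

    def test_overlapping_events_allowed(self):
        rec = EEGRecording(["Cz"], FS, np.zeros((1, 2000)), [(0, "L1", "T"), (100, "L1", "V")])
        assert len(epoch(rec)) == 2


class TestWelch:
    def _epoch(self, x):
        rec = EEGRecording(["Cz"], FS, x[None, :], [(0, "L1", "T")])
        return epoch(rec)[0]

    def test_peak_at_sinusoid_frequency(self):
        t = np.arange(875) / FS
        freqs, psd = welch_psd(self._epoch(np.sin(2 * np.pi * 10 * t)))
        assert abs(freqs[np.argmax(psd[0])] - 10.0) <= FS / 1024 + 1e-9

    def test_parseval_total_power_matches_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2.0, 875)
        freqs, psd = welch_psd(self._epoch(x))
        total = np.trapezoid(psd[0], freqs)
        assert total == pytest.approx(x.var(), rel=0.15)

    def test_zero_signal_gives_zero_psd(self):
        _, psd = welch_psd(self._epoch(np.zeros(875)))
        assert np.allclose(psd, 0.0)

    def test_frequency_resolution_is_fs_over_nfft(self):
        freqs, _ = welch_psd(self._epoch(np.zeros(875)))
        assert np.diff(freqs)[0] == pytest.approx(FS / 1024)


class TestIAF:
    @pytest.mark.parametrize("f", [8.0, 10.0, 12.0])
    def test_planted_peak_detected_within_one_bin(self, f):
        t = np.arange(20 * 875) / FS
        x = np.sin(2 * np.pi * f * t) + 0.01 * np.random.default_rng(2).normal(size=t.size)
        rec = EEGRecording(["Pz"], FS, x[None, :], [(i * 875, "L1", "T") for i in range(20)])
        psds = [welch_psd(e)[1] for e in epoch(rec)]
        freqs = welch_psd(epoch(rec)[0])[0]
        assert abs(detect_iaf(freqs, np.stack(psds)) - f) <= FS / 1024 + 1e-9

    def test_flat_spectrum_rejected(self):
        freqs = np.linspace(0, 40, 200)
        with pytest.raises(ValueError, match="flat"):
            detect_iaf(freqs, np.ones_like(freqs))

    def test_out_of_range_peak_clamps_to_edge_with_warning(self):
        t = np.arange(875 * 10) / FS
        x = np.sin(2 * np.pi * 13.0 * t)
        rec = EEGRecording(["Pz"], FS, x[None, :], [(0, "L1", "T")])
        ep = epoch(rec)[0]
        freqs, psd = welch_psd(ep)
        with pytest.warns(UserWarning, match="edge"):
            iaf = detect_iaf(freqs, psd)
        assert 7.5 <= iaf <= 12.5


class TestWorkload:
    def _planted_epoch(self, scale=1.0, shuffle=False):
        spec = ObserverSpec(
            conditions={"T": (0.25, 0.2)},
            eeg_params=EEGParams(iaf=10.0, frontal_theta_power=2.0,
                                 parietal_alpha_power=1.0, noise_level=1e-4),
        )
        rec = simulate_eeg(spec, [(500, "L1", "VTB")], duration=5.0, seed=4)
        rec.data *= scale
        if shuffle:
            order = list(np.random.default_rng(5).permutation(len(rec.channel_names)))
            rec = EEGRecording(
                [rec.channel_names[i] for i in order], rec.sampling_rate,
                rec.data[order], rec.events,
            )
        return epoch(rec)[0]

    def test_planted_two_to_one_ratio_recovered(self):
        res = workload(self._planted_epoch(), iaf=10.0)
        assert res.workload == pytest.approx(2.0, rel=0.05)

    def test_ratio_invariant_to_global_amplitude(self):
        a = workload(self._planted_epoch(), iaf=10.0).workload
        b = workload(self._planted_epoch(scale=3.7), iaf=10.0).workload
        assert a == pytest.approx(b, rel=1e-9)

    def test_ratio_invariant_to_channel_order(self):
        a = workload(self._planted_epoch(), iaf=10.0).workload
        b = workload(self._planted_epoch(shuffle=True), iaf=10.0).workload
        assert a == pytest.approx(b, rel=1e-12)

    def test_bands_anchor_at_iaf(self):
        res = workload(self._planted_epoch(), iaf=10.0)
        assert res.theta_band == (4.0, 8.0)
        assert res.alpha_band == (8.0, 12.0)

    def test_missing_electrode_named_in_error(self):
        rec = EEGRecording(["Cz", "Pz"], FS, np.zeros((2, 1000)), [(0, "L1", "T")])
        with pytest.raises(ValueError, match="Fz"):
            workload(epoch(rec)[0], iaf=10.0)

    def test_zero_alpha_power_rejected(self):
        rec = EEGRecording(list(SMARTING_24_CHANNELS), FS,
                           np.zeros((24, 1000)), [(0, "L1", "T")])
        with pytest.raises(ValueError, match="alpha"):
            workload(epoch(rec)[0], iaf=10.0)

    def test_condition_average_drops_3sd_outlier_epochs(self):
        from multisense.eeg import WorkloadResult

        vals = [1.0] * 50 + [1.4] * 50 + [60.0]
        results = [
            WorkloadResult(10.0, (4, 8), (8, 12), v, 1.0, v) for v in vals
        ]
        assert condition_workload(results) == pytest.approx(1.2, abs=0.01)

    def test_band_power_integrates_density(self):
        freqs = np.arange(0, 50, 0.5)
        psd = np.ones_like(freqs)
        assert band_power(freqs, psd, (8.0, 12.0)) == pytest.approx(4.0)
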