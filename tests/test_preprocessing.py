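"""Signal conditioning: filter attenuation, baseline removal, rejection, SNR."""

import numpy as np
import pytest
from scipy import signal as sps

from dtfconn import MultichannelRecording, compute_snr, condition, gate_channels
from dtfconn.errors import ConfigurationError, EmptyDataError
from dtfconn.preprocessing import reject_artifacts


def _rec(data, fs=512.0, **kw):
    return MultichannelRecording(np.atleast_2d(data), fs=fs, **kw)


class TestCondition:
    def test_notch_kills_mains_sinusoid(self):
        fs = 512.0
        t = np.arange(int(10 * fs)) / fs
        rec = _rec(np.sin(2 * np.pi * 50 * t), fs=fs)
        out = condition(rec, lowpass_hz=100, notch_band=(49, 51), baseline_poly_order=0)
        # ignore filter edge transients
        core = slice(int(fs), -int(fs))
        rms_in = np.sqrt(np.mean(rec.data[0, core] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, core] ** 2))
        assert rms_out <= 0.03 * rms_in

    def test_notch_attenuation_exceeds_30db(self):
        # frequency response of the zero-phase cascade at the notch centre
        b, a = sps.butter(2, [49 / 256, 51 / 256], btype="bandstop")
        _, h = sps.freqz(b, a, worN=[50.0], fs=512.0)
        assert 20 * np.log10(np.abs(h) ** 2) < -30  # filtfilt doubles dB

    def test_linear_ramp_removed_by_poly_order_one(self):
        ramp = np.linspace(-5, 7, 2000)
        rec = _rec(ramp, fs=512.0)
        from dtfconn.preprocessing import _polynomial_detrend

        out = _polynomial_detrend(rec.data, 1)
        assert np.abs(out).max() < 1e-9

    def test_lowpass_attenuates_high_frequencies(self):
        rng = np.random.default_rng(0)
        fs = 512.0
        rec = _rec(rng.standard_normal(int(60 * fs)), fs=fs)
        out = condition(rec, lowpass_hz=100, notch_band=(49, 51), baseline_poly_order=0)
        f, p_in = sps.welch(rec.data[0], fs=fs, nperseg=2048)
        _, p_out = sps.welch(out.data[0], fs=fs, nperseg=2048)
        hi = f > 110
        drop_db = 10 * np.log10(p_in[hi].mean() / p_out[hi].mean())
        assert drop_db >= 20

    def test_conditioning_idempotent_in_passband(self):
        rng = np.random.default_rng(1)
        fs = 512.0
        rec = _rec(rng.standard_normal(int(60 * fs)), fs=fs)
        once = condition(rec, 100, (49, 51), 3)
        twice = condition(once, 100, (49, 51), 3)
        f, p1 = sps.welch(once.data[0], fs=fs, nperseg=2048)
        _, p2 = sps.welch(twice.data[0], fs=fs, nperseg=2048)
        band = (f > 2) & (f < 45)
        ratio = p2[band].sum() / p1[band].sum()
        assert abs(ratio - 1) < 0.01

    def test_infeasible_bands_rejected(self):
        rec = _rec(np.zeros(1000), fs=128.0)
        with pytest.raises(ConfigurationError):
            condition(rec, lowpass_hz=100, notch_band=(49, 51))  # lowpass > Nyquist
        with pytest.raises(ConfigurationError):
            condition(rec, lowpass_hz=40, notch_band=(60, 70))


class TestRejectArtifacts:
    def _epoched(self, n_epochs=10, spe=100, fs=100.0, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((2, n_epochs * spe)) * 10
        return MultichannelRecording(data, fs=fs).epoch(spe / fs)

    def test_spiked_epoch_dropped(self):
        rec = self._epoched()
        rec.data[1, 350] = 1000.0  # epoch 3
        out, log = reject_artifacts(rec, amplitude_limit=100.0)
        assert log.dropped == [3]
        assert out.n_epochs == 9

    def test_clean_recording_untouched(self):
        rec = self._epoched()
        out, log = reject_artifacts(rec, amplitude_limit=1e6)
        assert log.dropped == []
        np.testing.assert_array_equal(out.data, rec.data)

    def test_two_of_ten_spiked_leaves_eight(self):
        rec = self._epoched()
        rec.data[0, 50] = 1e4
        rec.data[0, 950] = -1e4
        out, log = reject_artifacts(rec, amplitude_limit=100.0)
        assert sorted(log.dropped) == [0, 9]
        assert out.n_epochs == 8

    def test_all_rejected_raises(self):
        rec = self._epoched()
        with pytest.raises(EmptyDataError):
            reject_artifacts(rec, amplitude_limit=1e-6)


class TestSNR:
    def test_variance_ratio_formula(self):
        fs = 100.0
        rng = np.random.default_rng(2)
        noise = rng.standard_normal(int(fs)) * 1.0
        sig = rng.standard_normal(int(9 * fs)) * 3.0
        rec = _rec(np.concatenate([noise, sig]), fs=fs)
        rep = compute_snr(rec, noise_interval=(0.0, 1.0))
        # sd_signal ~ 3 over the whole record (dominated by the 9 s segment)
        expected = rec.data.var() / noise.var()
        assert rep.per_channel_snr[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(9.0, rel=0.3)

    def test_signal_equal_to_noise_gives_unity(self):
        rng = np.random.default_rng(3)
        rec = _rec(rng.standard_normal(1000), fs=100.0)
        rep = compute_snr(rec, noise_interval=(0.0, 10.0))  # whole record
        assert rep.per_channel_snr[0] == pytest.approx(1.0)

    def test_known_component_sds(self):
        # signal of sd 2.5 overlaid on noise of sd 0.9 in the pre interval:
        # SNR = (2.5^2 + 0.9^2) / 0.9^2 ~ 8.716; with the pre interval holding
        # noise only, SNR = sd_total^2 / 0.9^2
        fs = 250.0
        rng = np.random.default_rng(4)
        noise = rng.standard_normal(int(2 * fs)) * 0.9
        sig = rng.standard_normal(int(40 * fs)) * np.sqrt(2.5**2 + 0.9**2)
        rec = _rec(np.concatenate([noise, sig]), fs=fs)
        rep = compute_snr(rec, noise_interval=(0.0, 2.0))
        expected = (2.5**2 + 0.9**2) / 0.9**2
        assert rep.per_channel_snr[0] == pytest.approx(expected, rel=0.15)

    def test_zero_variance_noise_interval_guarded(self):
        data = np.ones((1, 1000))
        data[0, 500:] = np.random.default_rng(5).standard_normal(500)
        rec = _rec(data, fs=100.0)
        with pytest.raises(EmptyDataError):
            compute_snr(rec, noise_interval=(0.0, 1.0))

    def test_interval_outside_recording_rejected(self):
        rec = _rec(np.zeros(100), fs=100.0)
        with pytest.raises(ConfigurationError):
            compute_snr(rec, noise_interval=(0.0, 2.0))

    def test_gate_keeps_channels_in_working_range(self):
        fs = 100.0
        rng = np.random.default_rng(6)
        n = int(20 * fs)
        rows = []
        for target in (3.0, 8.0, 9.5, 40.0):  # SNR targets
            noise = rng.standard_normal(int(fs))
            sig = rng.standard_normal(n - int(fs)) * np.sqrt(target)
            rows.append(np.concatenate([noise * np.sqrt(sig.var() / target / noise.var()), sig]))
        rec = MultichannelRecording(
            np.array(rows), fs=fs, labels=["low", "ok1", "ok2", "high"]
        )
        rep = compute_snr(rec, noise_interval=(0.0, 1.0))
        gated, passed = gate_channels(rec, rep, min_snr=7.0, max_snr=10.0)
        assert passed == ["ok1", "ok2"]
        assert gated.labels == ["ok1", "ok2"]
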