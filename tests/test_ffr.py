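"""Brainstem phase-locking analysis: spectra, composite amplitude, noise
floor, Hotelling significance, polarity handling, and group delay."""

import warnings

import numpy as np
import pytest

import temporalpitch as tp
from temporalpitch import ffr, stimgen
from temporalpitch.acc import ContinuousRecording, EpochSet
from temporalpitch.synthetic_data import ScalpModel, simulate_recording

from conftest import zeros_recording

FS = 12207.0


def _epochs_from(wave, n=31):
    return EpochSet(epochs=np.tile(wave, (n, 1)), sample_rate=FS,
                    span_ms=(0.0, 1000.0))


def _tone(freq, amp=1.0, phase=0.0):
    t = np.arange(int(FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestFilter:
    def test_500hz_gain_unity_zero_phase(self):
        t = np.arange(int(3 * FS)) / FS
        x = np.sin(2 * np.pi * 500 * t)
        rec = ContinuousRecording(channels=x[None, :], sample_rate=FS)
        y = ffr.filter_ffr(rec).channels[0]
        core = slice(int(FS), int(2 * FS))
        assert np.std(y[core]) / np.std(x[core]) == pytest.approx(1.0, abs=0.05)
        lag = np.argmax(np.correlate(y[core], x[core], "full")) - (len(x[core]) - 1)
        assert lag == 0

    def test_slow_drift_attenuated(self):
        t = np.arange(int(3 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        rec = ContinuousRecording(channels=x[None, :], sample_rate=FS)
        y = ffr.filter_ffr(rec).channels[0]
        assert np.std(y[int(FS):int(2 * FS)]) < 0.05


class TestSegmentation:
    def test_epoch_count_per_rate(self):
        base, higher = tp.condition_specs("base188_pct66")
        sched = tp.make_alternating_schedule(base, higher, n_blocks=3, seed=0)
        esets = ffr.segment_ffr(zeros_recording(sched), seed=1)
        assert set(esets) == {188.0, 312.0}
        for es in esets.values():
            assert len(es.epochs) == 3 * 6  # every sweep contributes

    def test_polarity_balancing_trims_excess(self):
        rng = np.random.default_rng(0)
        pols = np.array([+1] * 74 + [-1] * 68)
        mask = ffr._balance_polarity(np.ones(142, bool), pols, rng)
        assert np.sum(mask & (pols > 0)) == 68
        assert np.sum(mask & (pols < 0)) == 68

    def test_balancing_seeded_and_reproducible(self):
        pols = np.array([+1] * 20 + [-1] * 17)
        m1 = ffr._balance_polarity(np.ones(37, bool), pols,
                                   np.random.default_rng(5))
        m2 = ffr._balance_polarity(np.ones(37, bool), pols,
                                   np.random.default_rng(5))
        assert np.array_equal(m1, m2)

    def test_single_polarity_errors(self):
        with pytest.raises(ValueError, match="polarit"):
            ffr._balance_polarity(np.ones(10, bool), np.ones(10, int),
                                  np.random.default_rng(0))


class TestSpectrum:
    def test_pure_tone_single_bin(self):
        sp = ffr.spectrum(_epochs_from(_tone(500.0)), 500.0)
        amp = sp.amplitude
        assert np.argmax(amp) == 500
        # 50-ms Hann ramps cost ~5 % of the full-scale amplitude
        assert amp[500] == pytest.approx(1.0, abs=0.06)
        assert amp[490] < 0.1 and amp[510] < 0.1

    def test_one_hz_bin_spacing(self):
        # a 1-s epoch at an integer sample count gives exact 1-Hz bins
        sp = ffr.spectrum(_epochs_from(_tone(300.0)), 300.0)
        assert sp.df_hz == 1.0
        assert sp.complex_amplitude.size == int(FS) // 2 + 1

    def test_polarity_locked_artifact_cancels(self):
        art = _tone(800.0, amp=2.0)
        sig = _tone(400.0, amp=1.0)
        epochs = np.concatenate([np.tile(sig + art, (16, 1)),
                                 np.tile(sig - art, (16, 1))])
        es = EpochSet(epochs=epochs, sample_rate=FS, span_ms=(0.0, 1000.0))
        sp = ffr.spectrum(es, 400.0)
        assert sp.amplitude[800] < 0.01 * 2.0
        assert sp.amplitude[400] == pytest.approx(1.0, abs=0.06)

    def test_wrong_epoch_length_errors(self):
        es = EpochSet(epochs=np.zeros((31, 6000)), sample_rate=FS,
                      span_ms=(0.0, 491.6))
        with pytest.raises(ValueError, match="1000 ms"):
            ffr.spectrum(es, 300.0)


class TestComposite:
    def test_five_harmonic_sum(self):
        t = np.arange(int(FS)) / FS
        wave = sum(a * np.sin(2 * np.pi * (k + 1) * 200.0 * t)
                   for k, a in enumerate([5.0, 4.0, 3.0, 2.0, 1.0]))
        sp = ffr.spectrum(_epochs_from(wave), 200.0)
        assert ffr.composite_amplitude(sp) == pytest.approx(15.0, rel=0.06)

    def test_pure_tone_composite_is_its_amplitude(self):
        sp = ffr.spectrum(_epochs_from(_tone(300.0, amp=2.0)), 300.0)
        assert ffr.composite_amplitude(sp) == pytest.approx(2.0, rel=0.06)

    def test_zero_signal(self):
        sp = ffr.spectrum(_epochs_from(np.zeros(int(FS))), 300.0)
        assert ffr.composite_amplitude(sp) == 0.0

    def test_rate_beyond_band_errors(self):
        sp = ffr.spectrum(_epochs_from(_tone(300.0)), 300.0)
        sp.rate_pps = 1500.0
        with pytest.raises(ValueError, match="exceeds"):
            ffr.composite_amplitude(sp)


class TestNoiseFloor:
    def test_white_noise_floor_tracks_composite(self):
        rng = np.random.default_rng(1)
        ratios = []
        for _ in range(15):
            es = EpochSet(epochs=rng.standard_normal((31, int(FS))),
                          sample_rate=FS, span_ms=(0.0, 1000.0))
            sp = ffr.spectrum(es, 300.0)
            ratios.append(ffr.composite_amplitude(sp)
                          / ffr.spectral_noise_floor(sp))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_noise_free_tone_floor_near_zero(self):
        sp = ffr.spectrum(_epochs_from(_tone(300.0)), 300.0)
        assert ffr.spectral_noise_floor(sp) < 0.1 * ffr.composite_amplitude(sp)

    def test_floor_linear_in_noise_scale(self):
        rng = np.random.default_rng(2)
        noise = rng.standard_normal((31, int(FS)))
        f1 = ffr.spectral_noise_floor(
            ffr.spectrum(EpochSet(epochs=noise, sample_rate=FS,
                                  span_ms=(0.0, 1000.0)), 300.0))
        f2 = ffr.spectral_noise_floor(
            ffr.spectrum(EpochSet(epochs=2 * noise, sample_rate=FS,
                                  span_ms=(0.0, 1000.0)), 300.0))
        assert f2 == pytest.approx(2 * f1, rel=1e-9)


class TestHotelling:
    def test_strong_coherent_signal_tiny_p(self):
        rng = np.random.default_rng(3)
        z = 5.0 + 0.0j + (rng.standard_normal(100)
                          + 1j * rng.standard_normal(100))
        t2, p = ffr.hotelling_t2(z)
        assert p < 1e-6

    def test_two_epochs_error(self):
        with pytest.raises(ValueError):
            ffr.hotelling_t2(np.array([1 + 1j, 2 + 2j]))

    def test_singular_covariance_regularised(self):
        z = np.full(10, 1.0 + 1.0j)
        with pytest.warns(UserWarning, match="singular"):
            t2, p = ffr.hotelling_t2(z)
        assert np.isfinite(t2) and 0 < p <= 1


class TestGroupDelay:
    RATES = [94, 128, 156, 188, 256, 280, 312, 376, 380, 464, 472, 512,
             560, 624, 640]

    def test_exact_linear_recovery(self):
        tau = 0.005
        phases = -2 * np.pi * np.array(self.RATES) * tau + 0.7
        gd = ffr.group_delay(self.RATES, phases)
        assert gd.delay_ms == pytest.approx(5.0, abs=1e-9)
        assert gd.reliable and not gd.excluded_rates

    def test_zero_delay(self):
        gd = ffr.group_delay(self.RATES, np.full(len(self.RATES), 0.3))
        assert gd.delay_ms == pytest.approx(0.0, abs=1e-9)

    def test_wide_spacing_flagged_unreliable(self):
        rates = [100, 250, 400, 520, 640]
        phases = -2 * np.pi * np.array(rates) * 0.008
        with pytest.warns(UserWarning, match="unreliable"):
            gd = ffr.group_delay(rates, phases)
        assert not gd.reliable

    def test_noisy_phases_recovered_with_bounded_exclusions(self):
        tau = 0.005
        rng = np.random.default_rng(9)
        phases = (-2 * np.pi * np.array(self.RATES, float) * tau
                  + rng.normal(0.0, 0.25, len(self.RATES)))
        gd = ffr.group_delay(self.RATES, phases)
        assert len(gd.excluded_rates) <= 2
        assert gd.delay_ms == pytest.approx(5.0, abs=0.3)

    def test_too_few_rates_error(self):
        with pytest.raises(ValueError):
            ffr.group_delay([100, 200, 300], [0.0, -1.0, -2.0])


class TestEnvelopeDominance:
    def test_alt_stimulus_drives_rate_not_f0(self):
        """For ALT-phase stimulation the response is locked to the pulse
        rate (2*F0): the rate-bin amplitude must dominate the F0 bin."""
        base, higher = stimgen.condition_specs("base376_pct66")  # ALT, F0 188
        sched = stimgen.make_alternating_schedule(base, higher, n_blocks=2,
                                                  seed=30)
        model = ScalpModel(noise_rms_uv=0.5, acc_gain_increase=0.0,
                           acc_gain_decrease=0.0)
        rec = simulate_recording(model, sched, seed=31)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            esets = ffr.segment_ffr(ffr.filter_ffr(rec), seed=32)
        sp = ffr.spectrum(esets[376.0], 376.0, min_epochs=3)
        assert sp.amplitude[376] > 4 * sp.amplitude[188]

    def test_composite_linear_in_kernel_gain(self):
        base, higher = stimgen.condition_specs("base280_pct66")
        sched = stimgen.make_alternating_schedule(base, higher, n_blocks=1,
                                                  seed=33)
        comps = []
        for gain in (1.0, 2.0):
            model = ScalpModel(noise_rms_uv=0.0, acc_gain_increase=0.0,
                               acc_gain_decrease=0.0, ffr_gain_uv=gain)
            rec = simulate_recording(model, sched, seed=34)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                esets = ffr.segment_ffr(ffr.filter_ffr(rec), seed=35)
            sp = ffr.spectrum(esets[280.0], 280.0, min_epochs=3)
            comps.append(ffr.composite_amplitude(sp))
        assert comps[1] == pytest.approx(2 * comps[0], rel=0.05)

    def test_artifact_only_recording_cancels(self):
        """With the neural kernel silenced, the polarity-locked transducer
        artifact must cancel in the polarity-balanced average."""
        base, higher = stimgen.condition_specs("base280_pct66")
        sched = stimgen.make_alternating_schedule(base, higher, n_blocks=1,
                                                  seed=36)
        model = ScalpModel(noise_rms_uv=0.0, acc_gain_increase=0.0,
                           acc_gain_decrease=0.0, ffr_gain_uv=0.0,
                           artifact_amp_uv=2.0)
        rec = simulate_recording(model, sched, seed=37)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            esets = ffr.segment_ffr(ffr.filter_ffr(rec), seed=38)
        es = esets[280.0]
        balanced = ffr.spectrum(es, 280.0, min_epochs=3)
        # reference: artifact strength in the + polarity epochs alone
        pos = EpochSet(epochs=es.epochs[es.polarity > 0], sample_rate=FS,
                       span_ms=(0.0, 1000.0))
        unbalanced = ffr.spectrum(pos, 280.0, min_epochs=3)
        assert (ffr.composite_amplitude(balanced)
                < 0.05 * ffr.composite_amplitude(unbalanced))
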