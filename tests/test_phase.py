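"""Band-pass filtering, Hilbert phase, and beat sampling."""
import numpy as np
import pytest

import beatsync as bs
from beatsync import phase
from beatsync.core import (
    DegenerateSignalError,
    InvalidParameterError,
    TooFewBeatsError,
    wrap_angle,
)

FS = 100.0


def tone(freq, fs=FS, duration=60.0, amp=1.0, phi0=0.0):
    t = np.arange(int(duration * fs)) / fs
    return t, amp * np.cos(2 * np.pi * freq * t + phi0)


def filtered_gain(freq, center=2.0):
    """Empirical steady-state amplitude gain of the band-pass at `freq`."""
    t, x = tone(freq)
    y = phase.bandpass_filter(x, FS, center).samples
    core = slice(int(10 * FS), int(50 * FS))  # avoid edges
    return np.sqrt(np.mean(y[core] ** 2)) / np.sqrt(np.mean(x[core] ** 2))


class TestBandpass:
    def test_passband_is_twenty_percent_of_center(self):
        assert phase.passband_edges(2.0, 0.20) == pytest.approx((1.8, 2.2))
        filt = phase.bandpass_filter(tone(2.0)[1], FS, 2.0)
        assert filt.passband == pytest.approx((1.8, 2.2))

    def test_center_tone_preserved(self):
        assert filtered_gain(2.0) == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_tone_attenuated_20db(self):
        g_pass = filtered_gain(2.0)
        g_stop = filtered_gain(4.0)
        assert 20 * np.log10(g_pass / g_stop) >= 20.0

    def test_zero_phase_at_center(self):
        """Cross-correlation between tone and filtered tone peaks at lag 0."""
        _, x = tone(2.0)
        y = phase.bandpass_filter(x, FS, 2.0).samples
        core = slice(int(10 * FS), int(50 * FS))
        xc, yc = x[core], y[core]
        lags = np.arange(-20, 21)
        corr = [np.dot(np.roll(xc, k), yc) for k in lags]
        assert lags[int(np.argmax(corr))] == 0

    def test_linearity(self, rng):
        a = rng.standard_normal(6000)
        b = rng.standard_normal(6000)
        fa = phase.bandpass_filter(a, FS, 2.0).samples
        fb = phase.bandpass_filter(b, FS, 2.0).samples
        fab = phase.bandpass_filter(a + b, FS, 2.0).samples
        assert np.max(np.abs(fab - (fa + fb))) < 1e-9 * max(1.0, np.max(np.abs(fab)))

    def test_mean_removed(self, rng):
        x = 500.0 + rng.standard_normal(6000)
        y = phase.bandpass_filter(x, FS, 2.0).samples
        assert abs(y.mean()) < 1e-3 * np.std(x)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(InvalidParameterError):
            phase.bandpass_filter(tone(2.0)[1], fs_hz=4.0, center_freq_hz=2.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(InvalidParameterError, match="10 beat periods"):
            phase.bandpass_filter(np.ones(100), FS, 2.0)


class TestComponentSelection:
    def _trial(self, ml, ap, vert):
        pos = np.stack([ml, ap, vert], axis=1)[:, None, :]
        return bs.TrialRecording(positions=pos, fs_hz=FS, marker_names=("knee_R",))

    def test_dominant_anteroposterior_selected(self, full_body_trial, short_stim):
        filt = phase.select_max_amplitude_component(
            full_body_trial, "knee_R", short_stim.beat_freq_hz
        )
        assert filt.axis_label == "anteroposterior"

    def test_constructed_vertical_dominance(self, rng):
        t, sig = tone(2.0, amp=30.0)
        noise = rng.standard_normal((sig.size, 2))
        trial = self._trial(noise[:, 0], noise[:, 1], sig)
        filt = phase.select_max_amplitude_component(trial, "knee_R", 2.0)
        assert filt.axis_label == "vertical"

    def test_exact_tie_breaks_by_priority(self):
        _, sig = tone(2.0, amp=10.0)
        trial = self._trial(sig.copy(), sig.copy(), sig.copy())
        filt = phase.select_max_amplitude_component(trial, "knee_R", 2.0)
        assert filt.axis_label == "vertical"  # vertical > anteroposterior > mediolateral

    def test_all_constant_trial_is_degenerate(self):
        n = 6000
        trial = self._trial(np.ones(n), np.full(n, 2.0), np.zeros(n))
        with pytest.raises(DegenerateSignalError):
            phase.select_max_amplitude_component(trial, "knee_R", 2.0)


class TestInstantaneousPhase:
    def test_cosine_phase_matches_analytic(self):
        t, x = tone(2.0, phi0=0.3)
        ps = phase.instantaneous_phase(x, fs_hz=FS)
        expected = wrap_angle(2 * np.pi * 2.0 * t + 0.3)
        core = slice(int(5 * FS), -int(5 * FS))
        err = np.abs(wrap_angle(ps.phase_rad[core] - expected[core]))
        assert np.max(err) < 0.02

    def test_phase_rate_matches_frequency(self):
        _, x = tone(2.0)
        ps = phase.instantaneous_phase(x, fs_hz=FS)
        core = slice(int(5 * FS), -int(5 * FS))
        step = np.diff(ps.unwrapped_rad[core])
        assert np.allclose(step, 2 * np.pi * 2.0 / FS, atol=0.01)

    def test_wrap_consistency(self):
        _, x = tone(1.9)
        ps = phase.instantaneous_phase(x, fs_hz=FS)
        assert np.allclose(wrap_angle(ps.unwrapped_rad), ps.phase_rad, atol=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            phase.instantaneous_phase(np.zeros(1000), fs_hz=FS)


class TestBeatSampling:
    def _phase_series(self, duration=65.0, freq=2.0):
        t = np.arange(int(duration * FS) + 1) / FS
        unwrapped = 2 * np.pi * freq * t
        return phase.PhaseSeries(
            phase_rad=wrap_angle(unwrapped), unwrapped_rad=unwrapped, fs_hz=FS
        )

    @pytest.mark.parametrize("n_beats,expected", [(128, 115), (20, 7), (14, 1)])
    def test_retained_counts(self, n_beats, expected):
        stim = bs.generate_beat_onsets(120.0, n_beats)
        beats = phase.sample_phase_at_beats(self._phase_series(), stim)
        assert beats.n_retained == expected
        assert beats.retained_beat_indices[0] == 10
        assert beats.retained_beat_indices[-1] == n_beats - 4

    def test_too_few_beats_rejected(self):
        stim = bs.generate_beat_onsets(120.0, 13)
        with pytest.raises(TooFewBeatsError):
            phase.sample_phase_at_beats(self._phase_series(), stim)

    def test_onset_beyond_recording_rejected(self):
        stim = bs.generate_beat_onsets(120.0, 128)
        with pytest.raises(InvalidParameterError, match="recording lasts"):
            phase.sample_phase_at_beats(self._phase_series(duration=30.0), stim)

    def test_sampling_matches_nearest_frame_oracle(self, locked_trial, stim120):
        """Linear interpolation vs nearest-frame lookup on a band-limited trial."""
        filt = phase.select_max_amplitude_component(
            locked_trial, "knee_R", stim120.beat_freq_hz
        )
        ps = phase.instantaneous_phase(filt)
        beats = phase.sample_phase_at_beats(ps, stim120)
        t_onsets = stim120.onsets[beats.retained_beat_indices]
        nearest = np.round(t_onsets * FS).astype(int)
        oracle = wrap_angle(ps.unwrapped_rad[nearest])
        err = np.abs(wrap_angle(beats.phases_rad - oracle))
        # nearest frame is up to 5 ms off; at 2 Hz that is <= 0.063 rad of
        # phase advance, and interpolation halves it; both land within 0.01 rad
        # only when onsets sit on the frame grid, as they do at 120 BPM/100 Hz
        assert np.max(err) < 0.01

    def test_locked_trial_phase_range_is_tight(self, locked_trial, stim120):
        filt = phase.select_max_amplitude_component(
            locked_trial, "knee_R", stim120.beat_freq_hz
        )
        ps = phase.instantaneous_phase(filt)
        beats = phase.sample_phase_at_beats(ps, stim120)
        rng_ = np.ptp(beats.phases_rad)
        assert rng_ < 0.1
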