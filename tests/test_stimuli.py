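"""Stream synthesis: deflections, formants, mixing, visual timecourse."""

import numpy as np
import pytest
from scipy.signal import hilbert

from avcoherence.envelopes import flat_envelope, make_trial_envelopes
from avcoherence.stimuli import (
    CARRIER_HEADROOM,
    VOWELS,
    CarrierSpec,
    SchedulingError,
    VowelSpec,
    formant_cascade_response,
    formant_trajectory,
    mix_trial,
    pitch_deflection_profile,
    render_visual_timecourse,
    synthesize_pitch_stream,
    synthesize_timbre_stream,
)
from avcoherence.envelopes import subsample_for_video

RATE = 24414.0


class TestDeflectionProfile:
    def test_full_period_endpoints_zero(self):
        assert pitch_deflection_profile(0.0) == pytest.approx(0.0)
        assert pitch_deflection_profile(0.1) == pytest.approx(0.0, abs=1e-12)

    def test_extrema(self):
        assert pitch_deflection_profile(0.025) == pytest.approx(1.5)
        assert pitch_deflection_profile(0.075) == pytest.approx(-1.5)

    def test_outside_event_is_zero(self):
        assert pitch_deflection_profile(-0.01) == 0.0
        assert pitch_deflection_profile(0.2) == 0.0


class TestPitchStream:
    def test_pure_tone_without_events(self):
        env = flat_envelope(1.0, RATE)
        st = synthesize_pitch_stream(CarrierSpec(440.0), env)
        spec = np.abs(np.fft.rfft(st.samples))
        freqs = np.fft.rfftfreq(len(st.samples), 1 / RATE)
        assert abs(freqs[np.argmax(spec)] - 440.0) <= freqs[1]

    def test_event_peak_instantaneous_frequency(self):
        env = flat_envelope(2.0, RATE)
        st = synthesize_pitch_stream(CarrierSpec(440.0), env, [0.9])
        phase = np.unwrap(np.angle(hilbert(st.samples)))
        inst = np.diff(phase) * RATE / (2 * np.pi)
        win = inst[int(0.9 * RATE): int(1.0 * RATE)]
        expected_peak = 440.0 * 2 ** (1.5 / 12)  # ~479.8 Hz
        assert win.max() == pytest.approx(expected_peak, rel=1e-3)
        assert win.min() == pytest.approx(440.0 * 2 ** (-1.5 / 12), rel=1e-3)

    def test_phase_continuity(self):
        env = flat_envelope(1.0, RATE)
        st = synthesize_pitch_stream(CarrierSpec(440.0), env, [0.5])
        phase = np.unwrap(np.angle(hilbert(st.samples)))
        assert np.all(np.abs(np.diff(phase)) < np.pi)

    def test_event_locality_exact(self):
        env = flat_envelope(2.0, RATE)
        with_ev = synthesize_pitch_stream(CarrierSpec(440.0), env, [0.9])
        without = synthesize_pitch_stream(CarrierSpec(440.0), env)
        diff = with_ev.samples != without.samples
        idx = np.nonzero(diff)[0]
        assert idx[0] >= int(0.9 * RATE)
        # phase-integrated frequency leaves a constant phase offset after
        # the event, so samples differ from event onset onward; before the
        # event they are bit-identical
        assert not diff[: int(0.9 * RATE) - 1].any()

    def test_ramp_profile(self):
        env = flat_envelope(1.0, RATE)
        st = synthesize_pitch_stream(CarrierSpec(440.0), env)
        k = int(round(0.010 * RATE))
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(k) / k)
        raw = np.sin(np.cumsum(np.full(len(st.samples), 2 * np.pi * 440.0 / RATE)))
        assert np.allclose(st.samples[:k], ramp * raw[:k], atol=1e-9)
        assert np.allclose(st.samples[-k:], ramp[::-1] * raw[-k:], atol=1e-9)

    def test_level_offset_rms(self):
        env = flat_envelope(1.0, RATE)
        lo = synthesize_pitch_stream(CarrierSpec(440.0), env)
        hi = synthesize_pitch_stream(CarrierSpec(565.0, level_offset_db=-3.0), env)
        rms = lambda x: np.sqrt(np.mean(x**2))
        db = 20 * np.log10(rms(hi.samples) / rms(lo.samples))
        assert db == pytest.approx(-3.0, abs=1e-3)

    def test_event_past_trial_end_raises(self):
        env = flat_envelope(1.0, RATE)
        with pytest.raises(SchedulingError):
            synthesize_pitch_stream(CarrierSpec(440.0), env, [0.95])

    def test_peak_amplitude_bounded(self):
        env = make_trial_envelopes(1.0, RATE, 7.0, np.random.default_rng(0))[0]
        st = synthesize_pitch_stream(CarrierSpec(440.0), env, [0.5])
        assert np.max(np.abs(st.samples)) <= 1.0


class TestFormantTrajectory:
    def test_zero_fraction_constant(self):
        v = VOWELS["u"]
        t = np.linspace(0, 3, 301)
        traj = formant_trajectory(v, [1.0], 0.0, t)
        assert np.allclose(traj, np.asarray(v.formants))

    def test_full_fraction_midpoint_hits_deviant(self):
        v = VOWELS["u"]
        traj = formant_trajectory(v, [1.0], 1.0, 1.1)
        assert traj[0] == pytest.approx(730.0)
        assert traj[1] == pytest.approx(2058.0)
        assert traj[2] == pytest.approx(2857.0)  # F3/F4 fixed
        assert traj[3] == pytest.approx(4205.0)

    def test_partial_fraction_linear_interpolation(self):
        v = VOWELS["a"]
        frac = 0.1225
        mid = formant_trajectory(v, [2.0], frac, 2.1)
        assert mid[0] == pytest.approx(936.0 + frac * (437.0 - 936.0))
        assert mid[1] == pytest.approx(1551.0 + frac * (2761.0 - 1551.0))
        quarter = formant_trajectory(v, [2.0], frac, 2.05)
        assert quarter[0] == pytest.approx(936.0 + 0.5 * frac * (437.0 - 936.0))

    def test_returns_to_steady_at_event_end(self):
        v = VOWELS["u"]
        assert np.allclose(
            formant_trajectory(v, [1.0], 1.0, 1.2), np.asarray(v.formants)
        )

    def test_deviant_restricted_to_f1_f2(self):
        with pytest.raises(ValueError):
            VowelSpec(
                label="x", f0=100.0,
                formants=(400.0, 1000.0, 2000.0, 3000.0),
                deviant_formants=(500.0, 1100.0, 2100.0, 3000.0),
            )


class TestTimbreStream:
    def test_fundamental_by_autocorrelation(self):
        env = flat_envelope(1.0, RATE)
        st = synthesize_timbre_stream(VOWELS["u"], env)
        x = st.samples[int(0.2 * RATE): int(0.9 * RATE)]
        ac = np.correlate(x, x, "full")[len(x) - 1:]
        lo, hi = int(RATE / 300), int(RATE / 100)
        lag = lo + np.argmax(ac[lo:hi])
        assert abs(RATE / lag - 175.0) <= RATE / lag - RATE / (lag + 1) + 1e-9

    def test_cascade_lowest_peak_near_f1(self):
        freqs = np.linspace(10, 6000, 30000)
        mag = formant_cascade_response(VOWELS["u"], freqs, RATE)
        maxima = np.nonzero(np.diff(np.sign(np.diff(mag))) < 0)[0] + 1
        assert freqs[maxima[0]] == pytest.approx(460.0, abs=5.0)

    def test_zero_fraction_event_equals_no_event(self):
        env = flat_envelope(2.0, RATE)
        a = synthesize_timbre_stream(VOWELS["a"], env, [1.0], fraction=0.0)
        b = synthesize_timbre_stream(VOWELS["a"], env)
        assert np.array_equal(a.samples, b.samples)

    def test_event_locality_with_ring_out(self):
        env = flat_envelope(3.0, RATE)
        a = synthesize_timbre_stream(VOWELS["u"], env, [1.0], fraction=0.1225)
        b = synthesize_timbre_stream(VOWELS["u"], env)
        diff = np.abs(a.samples - b.samples) > 1e-9 * np.abs(b.samples).max()
        idx = np.nonzero(diff)[0]
        assert idx[0] >= int(1.0 * RATE)
        assert idx[-1] <= int((1.0 + 0.2 + 0.1) * RATE)  # 100 ms ring-out allowance

    def test_peak_bounded_even_at_full_fraction(self):
        env = make_trial_envelopes(3.0, RATE, 7.0, np.random.default_rng(3))[0]
        st = synthesize_timbre_stream(VOWELS["u"], env, [1.5], fraction=1.0)
        assert np.max(np.abs(st.samples)) <= 1.0

    def test_invalid_specs_rejected(self):
        env = flat_envelope(0.5, 6000.0)
        with pytest.raises(ValueError):
            synthesize_timbre_stream(VOWELS["u"], env)  # F4 above Nyquist
        bad = VowelSpec(
            label="bad", f0=500.0,
            formants=(460.0, 1105.0, 2857.0, 4205.0),
            deviant_formants=(730.0, 2058.0, 2857.0, 4205.0),
        )
        with pytest.raises(ValueError):
            synthesize_timbre_stream(bad, flat_envelope(0.5, RATE))  # F0 >= F1


class TestMixTrial:
    def _streams(self, dur=3.0):
        env = flat_envelope(dur, RATE)
        t = synthesize_pitch_stream(CarrierSpec(440.0), env)
        m = synthesize_pitch_stream(CarrierSpec(565.0, level_offset_db=-3.0), env)
        return t, m

    def test_first_second_is_target_alone(self):
        t, m = self._streams()
        mix = mix_trial(t, m)
        n0 = int(1.0 * RATE)
        assert np.array_equal(mix.mixture[:n0], t.samples[:n0] * mix.scale)

    def test_muted_masker_gives_target(self):
        t, m = self._streams()
        silent = type(m)(
            samples=np.zeros_like(m.samples), rate=m.rate, spec=m.spec,
            envelope=m.envelope, events=(),
        )
        mix = mix_trial(t, silent)
        assert np.allclose(mix.mixture, t.samples * mix.scale)

    def test_masker_ramps_in_at_delay(self):
        t, m = self._streams()
        mix = mix_trial(t, m)
        n0 = int(1.0 * RATE)
        k = int(round(0.010 * RATE))
        # beyond the onset ramp the masker is fully present
        masker_part = mix.mixture / mix.scale - t.samples
        assert np.allclose(masker_part[:n0], 0.0)
        assert np.allclose(masker_part[n0 + k:], m.samples[n0 + k:], atol=1e-12)

    def test_noise_requires_rng_and_scales(self):
        t, m = self._streams(1.5)
        with pytest.raises(ValueError):
            mix_trial(t, m, noise_level_db=-24.0)
        mix = mix_trial(t, m, noise_level_db=-24.0, rng=np.random.default_rng(0))
        assert np.max(np.abs(mix.mixture)) <= 1.0
        # noise RMS ~ -24 dB re target RMS, measured in the masker-free first second
        n0 = int(1.0 * RATE)
        resid = mix.mixture[:n0] / mix.scale - t.samples[:n0]
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert 20 * np.log10(rms(resid) / rms(t.samples)) == pytest.approx(-24.0, abs=0.5)


class TestVisualTimecourse:
    def _venv(self, dur=2.0):
        env = make_trial_envelopes(dur, 2000.0, 7.0, np.random.default_rng(1))[0]
        return subsample_for_video(env, 60.0)

    def test_radius_affine_map(self):
        v = self._venv()
        tc = render_visual_timecourse(v)
        assert np.allclose(tc.radii_deg, 1.0 + v.frame_values * 1.5)
        assert tc.radii_deg.min() >= 1.0 and tc.radii_deg.max() <= 2.5

    def test_no_flashes(self):
        tc = render_visual_timecourse(self._venv())
        assert not tc.flash_frames.any()

    @pytest.mark.parametrize("onset", [0.5, 0.5083, 1.2004])
    def test_flash_spans_six_frames(self, onset):
        tc = render_visual_timecourse(self._venv(), [onset])
        assert tc.flash_frames.sum() == 6

    def test_flash_past_end_raises(self):
        with pytest.raises(SchedulingError):
            render_visual_timecourse(self._venv(1.0), [0.95])
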