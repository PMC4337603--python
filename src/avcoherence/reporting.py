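"""Design-level summary measurements, recomputed from the generators.

Each function runs part of the pipeline and measures a quantity that the
design fixes — expected event counts, the pitch-event excursion, the
vowel-stream fundamental, formant-cascade resonances, envelope band
limits, inter-stream level differences, and the timbre-morph span.  They
back the ``reproduce`` CLI subcommand and the repository's acceptance
script.  Every function returns ``(value, n)`` where ``n`` is the
problem size the estimate used.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from scipy.signal import hilbert

from . import envelopes as env_mod
from . import scheduler as sched_mod
from . import stimuli as stim_mod

__all__ = [
    "mean_event_counts",
    "session_event_totals",
    "pitch_event_peak_semitones",
    "u_stream_fundamental_hz",
    "u_cascade_first_peak_hz",
    "raw_envelope_max_frequency_hz",
    "pitch_stream_level_difference_db",
    "timbre_event_span_ms",
    "design_report",
]


def mean_event_counts(seed: int, n_draws: int = 10_000) -> Tuple[Dict[str, float], int]:
    """Mean per-trial target/masker/flash counts over ``n_draws`` draws."""
    rng = np.random.default_rng(seed)
    draws = np.array([sched_mod.draw_event_counts(rng) for _ in range(n_draws)])
    means = dict(zip(("target", "masker", "flash"), draws.mean(axis=0)))
    return means, n_draws


def session_event_totals(
    seed: int,
    n_sessions: int = 200,
    *,
    n_trials: int = sched_mod.TRIALS_PER_CONDITION,
    task: str = "timbre",
    envelope_rate: float = 2000.0,
) -> Tuple[Dict[str, float], int]:
    """Mean per-session totals of scheduled target events and flashes.

    Simulates one condition's worth of trials (``n_trials`` per session)
    through the full draw-counts -> envelopes -> schedule chain, with
    envelope regeneration on unschedulable trials, and averages the
    totals over sessions.
    """
    rng = np.random.default_rng(seed)
    event_dur = sched_mod.EVENT_DURATIONS[task]
    tot_target = np.zeros(n_sessions)
    tot_flash = np.zeros(n_sessions)
    for s in range(n_sessions):
        for _ in range(n_trials):
            counts = sched_mod.draw_event_counts(rng)
            while True:
                tgt, msk, _ = env_mod.make_trial_envelopes(
                    sched_mod.TRIAL_DURATION, envelope_rate, 7.0,
                    np.random.default_rng(int(rng.integers(2**31))),
                )
                try:
                    sched = sched_mod.schedule_events(tgt, msk, counts, event_dur, rng)
                    break
                except sched_mod.UnschedulableTrialError:
                    continue
            tot_target[s] += len(sched.target_onsets)
            tot_flash[s] += len(sched.flash_onsets)
    return {"target": float(tot_target.mean()), "flash": float(tot_flash.mean())}, n_sessions


def pitch_event_peak_semitones(
    rate: float = stim_mod.AUDIO_RATE, f0: float = 440.0
) -> Tuple[float, int]:
    """Measured peak carrier excursion (semitones) of one pitch event.

    Synthesizes a constant-envelope stream with a single event, extracts
    the instantaneous frequency by differentiating the analytic-signal
    phase, and converts the peak excursion to semitones re the carrier.
    """
    duration = 2.0
    env = env_mod.flat_envelope(duration, rate)
    stream = stim_mod.synthesize_pitch_stream(
        stim_mod.CarrierSpec(f0=f0), env, [0.9]
    )
    phase = np.unwrap(np.angle(hilbert(stream.samples)))
    inst = np.diff(phase) * rate / (2.0 * np.pi)
    window = inst[int(0.9 * rate): int(1.0 * rate)]
    return float(12.0 * np.log2(window.max() / f0)), len(stream.samples)


def u_stream_fundamental_hz(rate: float = stim_mod.AUDIO_RATE) -> Tuple[float, int]:
    """F0 of the steady /u/ stream via the autocorrelation peak.

    The peak lag is refined by parabolic interpolation of the
    autocorrelation around the maximum in the 100-300 Hz range.
    """
    vowel = stim_mod.VOWELS["u"]
    env = env_mod.flat_envelope(1.0, rate)
    stream = stim_mod.synthesize_timbre_stream(vowel, env)
    x = stream.samples[int(0.2 * rate): int(0.9 * rate)]
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    lo, hi = int(rate / 300.0), int(rate / 100.0)
    lag = lo + int(np.argmax(ac[lo:hi]))
    y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
    lag_refined = lag + 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
    return float(rate / lag_refined), len(x)


def u_cascade_first_peak_hz(
    rate: float = stim_mod.AUDIO_RATE, n_grid: int = 60_000
) -> Tuple[float, int]:
    """Frequency of the lowest local maximum of the /u/ filter cascade."""
    freqs = np.linspace(10.0, rate / 2 - 10.0, n_grid)
    mag = stim_mod.formant_cascade_response(stim_mod.VOWELS["u"], freqs, rate)
    maxima = np.nonzero(np.diff(np.sign(np.diff(mag))) < 0)[0] + 1
    return float(freqs[maxima[0]]), n_grid


def raw_envelope_max_frequency_hz(
    seed: int, rate: float = stim_mod.AUDIO_RATE, duration: float = 14.0,
    cutoff: float = 7.0, rel_threshold: float = 1e-9,
) -> Tuple[float, int]:
    """Highest frequency with spectral magnitude above threshold x in-band peak."""
    env = env_mod.make_raw_envelope(
        duration, rate, cutoff, np.random.default_rng(seed)
    )
    spec = np.abs(np.fft.rfft(env.samples))
    freqs = np.fft.rfftfreq(len(env), 1.0 / rate)
    peak = spec[freqs < cutoff].max()
    above = freqs[spec > rel_threshold * peak]
    return float(above.max()), len(env)


def pitch_stream_level_difference_db(
    rate: float = stim_mod.AUDIO_RATE,
) -> Tuple[float, int]:
    """|dB| RMS difference between the 565 and 440 Hz streams, same envelope."""
    env = env_mod.flat_envelope(1.0, rate)
    lo = stim_mod.synthesize_pitch_stream(stim_mod.CarrierSpec(440.0), env)
    hi = stim_mod.synthesize_pitch_stream(
        stim_mod.CarrierSpec(565.0, level_offset_db=stim_mod.HIGH_STREAM_LEVEL_OFFSET_DB),
        env,
    )
    rms = lambda x: float(np.sqrt(np.mean(x**2)))
    diff = 20.0 * np.log10(rms(hi.samples) / rms(lo.samples))
    return float(abs(diff)), len(env)


def timbre_event_span_ms(fraction: float = 0.1225) -> Tuple[float, int]:
    """Duration (ms) over which F1 departs from steady state in one event.

    The trajectory is evaluated at 1 ms cell midpoints, so the measured
    span is the number of grid cells where F1 differs times the cell
    width — the measure of the support of the departure.
    """
    vowel = stim_mod.VOWELS["u"]
    dt = 0.001
    onset = 1.0
    t = np.arange(0.0, 3.0, dt) + dt / 2.0
    traj = stim_mod.formant_trajectory(vowel, [onset], fraction, t)
    differs = traj[:, 0] != vowel.formants[0]
    return float(differs.sum() * dt * 1000.0), len(t)


def design_report(seed: int, *, n_sessions: int = 200, n_draws: int = 10_000) -> dict:
    """All design-level measurements, keyed by descriptive names."""
    totals, n_sess = session_event_totals(seed, n_sessions)
    counts, n_cnt = mean_event_counts(seed + 1, n_draws)
    semis, n_semi = pitch_event_peak_semitones()
    f0, n_f0 = u_stream_fundamental_hz()
    peak1, n_grid = u_cascade_first_peak_hz()
    fmax, n_env = raw_envelope_max_frequency_hz(seed + 2)
    lvl, n_lvl = pitch_stream_level_difference_db()
    span, n_span = timbre_event_span_ms()
    return {
        "target_events_per_condition": {"value": totals["target"], "n": n_sess},
        "flashes_per_condition": {"value": totals["flash"], "n": n_sess},
        "mean_target_events_per_trial": {"value": counts["target"], "n": n_cnt},
        "pitch_event_peak_semitones": {"value": semis, "n": n_semi},
        "u_stream_fundamental_hz": {"value": f0, "n": n_f0},
        "u_cascade_first_peak_hz": {"value": peak1, "n": n_grid},
        "envelope_max_frequency_hz": {"value": fmax, "n": n_env},
        "pitch_level_difference_db": {"value": lvl, "n": n_lvl},
        "timbre_event_span_ms": {"value": span, "n": n_span},
    }
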