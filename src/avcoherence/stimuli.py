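"""Auditory stream and visual timecourse synthesis.

Two stream families implement the two task variants:

* **Pitch task** — each stream is an amplitude-modulated sinusoid (440 or
  565 Hz; the more salient 565 Hz stream attenuated 3 dB).  A perturbation
  event is one full period of a sinusoidal carrier-frequency deflection,
  peaking at +/-1.5 semitones over 100 ms.  The waveform is synthesized by
  integrating the instantaneous frequency into a cumulative phase, so the
  carrier is phase-continuous through every event.

* **Timbre task** — each stream is a periodic impulse train (F0 = 175 Hz
  for /u/, 195 Hz for /a/) filtered through a cascade of four second-order
  resonators, one per formant F1-F4.  A perturbation event morphs F1 and
  F2 linearly toward a deviant vowel for 100 ms and back for 100 ms, by a
  configurable fraction of the steady-to-deviant distance in the F1-F2
  plane; F3 and F4 never move.

Both stream types are amplitude-modulated by an accentuated noise
envelope, begin and end with a 10 ms raised-cosine ramp, and are mixed
diotically: target from t = 0, masker gated on at 1 s, optional stationary
background noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.signal import lfilter, lfiltic

from .envelopes import NoiseEnvelope, VisualEnvelope

__all__ = [
    "CarrierSpec",
    "VowelSpec",
    "AudioStream",
    "TrialAudio",
    "VisualTimecourse",
    "SchedulingError",
    "PITCH_F0S",
    "HIGH_STREAM_LEVEL_OFFSET_DB",
    "PITCH_EVENT_DURATION",
    "PITCH_EVENT_PEAK_SEMITONES",
    "TIMBRE_EVENT_DURATION",
    "DEFAULT_FORMANT_BANDWIDTHS",
    "RAMP_DURATION",
    "VOWELS",
    "pitch_deflection_profile",
    "synthesize_pitch_stream",
    "formant_trajectory",
    "synthesize_timbre_stream",
    "formant_cascade_response",
    "mix_trial",
    "render_visual_timecourse",
]

AUDIO_RATE = 24414.0
PITCH_F0S = (440.0, 565.0)
HIGH_STREAM_LEVEL_OFFSET_DB = -3.0  # 565 Hz stream was more salient
PITCH_EVENT_DURATION = 0.1
PITCH_EVENT_PEAK_SEMITONES = 1.5
TIMBRE_EVENT_DURATION = 0.2  # 100 ms toward the deviant, 100 ms back
RAMP_DURATION = 0.010
# Resonator 3-dB bandwidths for F1-F4; conventional vowel-synthesis values
# (the cascade's peak positions, which carry the timbre, are set by the
# formant tables below, not by these).
DEFAULT_FORMANT_BANDWIDTHS = (60.0, 90.0, 150.0, 200.0)
# Worst-case cascade gain rise during a full-fraction morph is ~1.21x the
# steady-state peak; 0.8 keeps |samples| <= 1 with margin.
CARRIER_HEADROOM = 0.8

RADIUS_MIN_DEG = 1.0
RADIUS_MAX_DEG = 2.5
RING_WIDTH_DEG = 0.125
FLASH_DURATION = 0.1
FLASH_COLOR_RGB = (0.0, 1.0, 1.0)  # cyan: 0% red, 100% green, 100% blue


class SchedulingError(ValueError):
    """An event falls outside the trial or overlaps another event."""


@dataclass(frozen=True)
class CarrierSpec:
    """Pitch-task carrier: AM sinusoid at ``f0`` with a level offset in dB
    relative to the 440 Hz reference stream."""

    f0: float
    level_offset_db: float = 0.0
    task: str = "pitch"

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")


@dataclass(frozen=True)
class VowelSpec:
    """Timbre-task vowel: impulse-train F0 plus steady and deviant formant
    frequencies.  The deviant may differ from steady state only in F1/F2."""

    label: str
    f0: float
    formants: Tuple[float, float, float, float]
    deviant_formants: Tuple[float, float, float, float]
    bandwidths: Tuple[float, float, float, float] = DEFAULT_FORMANT_BANDWIDTHS
    level_offset_db: float = 0.0
    task: str = "timbre"

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.formants, self.formants[1:])):
            raise ValueError("formants must be strictly increasing")
        if self.formants[2:] != self.deviant_formants[2:]:
            raise ValueError("deviant must differ from steady state only in F1/F2")


#: The two vowel streams: /u/ drifts toward /E/ during events, /a/ toward /i/.
VOWELS = {
    "u": VowelSpec(
        label="u", f0=175.0,
        formants=(460.0, 1105.0, 2857.0, 4205.0),
        deviant_formants=(730.0, 2058.0, 2857.0, 4205.0),
    ),
    "a": VowelSpec(
        label="a", f0=195.0,
        formants=(936.0, 1551.0, 2975.0, 4263.0),
        deviant_formants=(437.0, 2761.0, 2975.0, 4263.0),
    ),
}


@dataclass(frozen=True)
class AudioStream:
    """One synthesized auditory stream (pre-mixing)."""

    samples: np.ndarray
    rate: float
    spec: CarrierSpec | VowelSpec
    envelope: NoiseEnvelope
    events: Tuple[float, ...]


@dataclass(frozen=True)
class TrialAudio:
    """The diotic trial mixture: target from 0 s, masker gated on later."""

    mixture: np.ndarray
    rate: float
    masker_delay: float
    noise_level_db: float
    scale: float  # gain applied so that peak |mixture| <= 1


@dataclass(frozen=True)
class VisualTimecourse:
    """Parametric per-frame description of the visual stream."""

    radii_deg: np.ndarray
    flash_frames: np.ndarray  # boolean per frame
    frame_rate: float
    ring_width_deg: float = RING_WIDTH_DEG
    flash_color: Tuple[float, float, float] = FLASH_COLOR_RGB


def _raised_cosine_ramps(n: int, rate: float, ramp: float = RAMP_DURATION) -> np.ndarray:
    """Unit gain with raised-cosine on/off ramps of ``ramp`` seconds."""
    g = np.ones(n)
    k = int(round(ramp * rate))
    if k > 0:
        r = 0.5 - 0.5 * np.cos(np.pi * np.arange(k) / k)
        g[:k] *= r
        g[n - k:] *= r[::-1]
    return g


def _check_events(events: Sequence[float], duration: float, event_dur: float) -> Tuple[float, ...]:
    ev = tuple(sorted(float(e) for e in events))
    for a, b in zip(ev, ev[1:]):
        if b - a < event_dur:
            raise SchedulingError(f"events at {a} s and {b} s overlap")
    for e in ev:
        if e < 0 or e + event_dur > duration:
            raise SchedulingError(f"event at {e} s extends past the trial")
    return ev


def pitch_deflection_profile(
    t_rel: float | np.ndarray,
    duration: float = PITCH_EVENT_DURATION,
    peak: float = PITCH_EVENT_PEAK_SEMITONES,
) -> np.ndarray:
    """Semitone offset of one pitch event at time ``t_rel`` after onset.

    One full sinusoid period: ``peak * sin(2*pi*t/duration)``, zero at both
    endpoints, reaching +peak at a quarter period and -peak at three
    quarters.  Zero outside [0, duration].
    """
    t = np.asarray(t_rel, dtype=float)
    inside = (t >= 0) & (t <= duration)
    out = np.where(inside, peak * np.sin(2.0 * np.pi * t / duration), 0.0)
    return out if out.ndim else float(out)


def synthesize_pitch_stream(
    spec: CarrierSpec,
    env: NoiseEnvelope,
    events: Sequence[float] = (),
    *,
    event_duration: float = PITCH_EVENT_DURATION,
    event_peak: float = PITCH_EVENT_PEAK_SEMITONES,
) -> AudioStream:
    """AM sinusoid whose carrier frequency deflects during events.

    The instantaneous frequency is f0 * 2**(offset(t)/12); its cumulative
    integral (at the sample rate) is the phase, so there are no phase
    discontinuities at event boundaries.
    """
    rate = env.rate
    n = len(env)
    ev = _check_events(events, n / rate, event_duration)
    t = np.arange(n) / rate
    offset = np.zeros(n)
    for onset in ev:
        i0 = int(math.ceil(onset * rate))
        i1 = min(n, int(math.floor((onset + event_duration) * rate)) + 1)
        offset[i0:i1] = pitch_deflection_profile(
            t[i0:i1] - onset, event_duration, event_peak
        )
    freq = spec.f0 * np.exp2(offset / 12.0)
    phase = 2.0 * np.pi * np.cumsum(freq) / rate
    scale = 10.0 ** (spec.level_offset_db / 20.0)
    samples = env.samples * scale * np.sin(phase)
    samples *= _raised_cosine_ramps(n, rate)
    return AudioStream(samples=samples, rate=rate, spec=spec, envelope=env, events=ev)


def formant_trajectory(
    vowel: VowelSpec,
    events: Sequence[float],
    fraction: float,
    t: float | np.ndarray,
    *,
    event_duration: float = TIMBRE_EVENT_DURATION,
) -> np.ndarray:
    """Formant frequencies F1-F4 at time(s) ``t``.

    Outside events the formants sit at the steady-state values.  Inside an
    event, F1 and F2 interpolate linearly to
    ``steady + fraction * (deviant - steady)`` at the event midpoint and
    linearly back by the event's end; F3/F4 are constant throughout.
    Returns shape ``t.shape + (4,)``.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    half = event_duration / 2.0
    depth = np.zeros(tt.shape)  # triangular morph depth in [0, 1]
    for onset in sorted(events):
        rel = tt - onset
        inside = (rel > 0) & (rel < event_duration)
        depth = np.where(inside, 1.0 - np.abs(rel - half) / half, depth)
    steady = np.asarray(vowel.formants)
    deviant = np.asarray(vowel.deviant_formants)
    out = steady + fraction * depth[..., None] * (deviant - steady)
    return out if np.ndim(t) else out[0]


def _resonator_coefficients(f: np.ndarray, bw: float, rate: float):
    """Two-pole resonator: y[n] = A x[n] + B y[n-1] + C y[n-2].

    Pole radius r = exp(-pi*bw/rate), angle theta = 2*pi*f/rate.  A is
    chosen so the gain at the center frequency is exactly 1, which keeps
    the stream level stable while a formant moves during an event.
    """
    r = math.exp(-math.pi * bw / rate)
    theta = 2.0 * np.pi * np.asarray(f) / rate
    b = 2.0 * r * np.cos(theta)
    c = -r * r
    z1 = np.exp(-1j * theta)
    a = np.abs(1.0 - b * z1 - c * z1**2)
    return a, b, c


def formant_cascade_response(
    vowel: VowelSpec, freqs: np.ndarray, rate: float = AUDIO_RATE
) -> np.ndarray:
    """Magnitude response of the steady-state four-resonator cascade."""
    w = 2.0 * np.pi * np.asarray(freqs) / rate
    z1 = np.exp(-1j * w)
    h = np.ones_like(z1)
    for f, bw in zip(vowel.formants, vowel.bandwidths):
        a, b, c = _resonator_coefficients(np.asarray(f), bw, rate)
        h = h * (a / (1.0 - b * z1 - c * z1**2))
    return np.abs(h)


def _filter_cascade_time_varying(
    x: np.ndarray,
    vowel: VowelSpec,
    events: Tuple[float, ...],
    fraction: float,
    rate: float,
    event_duration: float,
) -> np.ndarray:
    """Run the impulse train through the cascade, coefficients recomputed
    per sample inside event windows, scipy's lfilter (with carried state)
    on the steady spans between them."""
    n = len(x)
    sig = x
    # Sample index spans covered by events (coefficients vary there).
    spans = []
    for onset in events:
        i0 = int(math.floor(onset * rate))
        i1 = min(n, int(math.ceil((onset + event_duration) * rate)) + 1)
        spans.append((i0, i1))
    t = np.arange(n) / rate
    for fi, (f_steady, bw) in enumerate(zip(vowel.formants, vowel.bandwidths)):
        a_st, b_st, c_st = _resonator_coefficients(np.asarray(f_steady), bw, rate)
        b_vec, a_vec = [float(a_st)], [1.0, -float(b_st), -float(c_st)]
        out = np.empty(n)
        y1 = y2 = 0.0  # single-tap numerator: state is the past two outputs
        pos = 0
        for (i0, i1) in spans + [(n, n)]:
            if i0 > pos:  # steady span: vectorized IIR with carried state
                zi = lfiltic(b_vec, a_vec, y=[y1, y2])
                seg, _ = lfilter(b_vec, a_vec, sig[pos:i0], zi=zi)
                out[pos:i0] = seg
                y1 = seg[-1]
                y2 = seg[-2] if seg.size >= 2 else y1
            if i0 >= n:
                break
            traj = formant_trajectory(
                vowel, events, fraction, t[i0:i1], event_duration=event_duration
            )[:, fi]
            a_v, b_v, c_v = _resonator_coefficients(traj, bw, rate)
            for k in range(i0, i1):
                j = k - i0
                yk = a_v[j] * sig[k] + b_v[j] * y1 + c_v * y2
                out[k] = yk
                y2, y1 = y1, yk
            pos = i1
        sig = out
    return sig


def synthesize_timbre_stream(
    vowel: VowelSpec,
    env: NoiseEnvelope,
    events: Sequence[float] = (),
    fraction: float = 0.0,
    *,
    event_duration: float = TIMBRE_EVENT_DURATION,
) -> AudioStream:
    """Impulse train at F0 filtered through the formant cascade.

    The carrier level is referenced to the steady-state-filtered train's
    peak — the same normalization whether or not events are present, so a
    stream with events differs from its no-event twin only inside the
    event windows (plus resonator ring-out).  A fixed headroom factor
    keeps the peak below 1 even while a moving formant transiently raises
    the cascade gain.
    """
    rate = env.rate
    if rate <= 2 * vowel.formants[-1]:
        raise ValueError("sampling rate must exceed twice the highest formant")
    if vowel.f0 >= vowel.formants[0]:
        raise ValueError("F0 must lie below F1")
    n = len(env)
    ev = _check_events(events, n / rate, event_duration)
    idx = np.round(np.arange(0, n * vowel.f0 / rate) * rate / vowel.f0).astype(np.intp)
    train = np.zeros(n)
    train[idx[idx < n]] = 1.0
    steady = train
    for f, bw in zip(vowel.formants, vowel.bandwidths):
        a, b, c = _resonator_coefficients(np.asarray(f), bw, rate)
        steady = lfilter([float(a)], [1.0, -float(b), -float(c)], steady)
    if ev and fraction > 0:
        carrier = _filter_cascade_time_varying(
            train, vowel, ev, fraction, rate, event_duration
        )
    else:
        carrier = steady
    carrier = carrier * (CARRIER_HEADROOM / np.max(np.abs(steady)))
    scale = 10.0 ** (vowel.level_offset_db / 20.0)
    samples = env.samples * scale * carrier
    samples *= _raised_cosine_ramps(n, rate)
    peak = float(np.max(np.abs(samples)))
    if peak > 1.0:  # cannot trigger for the shipped vowel tables
        samples = samples / peak
    return AudioStream(samples=samples, rate=rate, spec=vowel, envelope=env, events=ev)


def mix_trial(
    target: AudioStream,
    masker: AudioStream,
    masker_delay: float = 1.0,
    noise_level_db: float = -np.inf,
    rng: np.random.Generator | None = None,
) -> TrialAudio:
    """Sum target and delayed masker diotically, plus background noise.

    The masker contributes exactly zero before ``masker_delay``; its onset
    there is a fresh 10 ms raised-cosine ramp.  Background noise is white
    Gaussian at ``noise_level_db`` relative to the target stream's RMS
    (``-inf`` disables it).  The mixture is rescaled to peak magnitude 1
    if it would clip; the applied gain is recorded.
    """
    if target.rate != masker.rate:
        raise ValueError("streams must share a sampling rate")
    n = len(target.samples)
    if len(masker.samples) != n:
        raise ValueError("streams must have equal length")
    rate = target.rate
    if not 0 <= masker_delay < n / rate:
        raise ValueError("masker_delay must lie inside the trial")
    gate = np.zeros(n)
    i0 = int(round(masker_delay * rate))
    k = int(round(RAMP_DURATION * rate))
    gate[i0:] = 1.0
    gate[i0:i0 + k] = 0.5 - 0.5 * np.cos(np.pi * np.arange(min(k, n - i0)) / k)
    mixture = target.samples + gate * masker.samples
    if np.isfinite(noise_level_db):
        if rng is None:
            raise ValueError("rng required when background noise is enabled")
        ref_rms = float(np.sqrt(np.mean(target.samples**2)))
        mixture = mixture + rng.normal(
            0.0, ref_rms * 10.0 ** (noise_level_db / 20.0), n
        )
    peak = float(np.max(np.abs(mixture)))
    scale = 1.0 if peak <= 1.0 else 1.0 / peak
    return TrialAudio(
        mixture=mixture * scale, rate=rate, masker_delay=masker_delay,
        noise_level_db=float(noise_level_db), scale=scale,
    )


def render_visual_timecourse(
    venv: VisualEnvelope, flashes: Sequence[float] = ()
) -> VisualTimecourse:
    """Map envelope values to disc radii and mark flash frames.

    Radius is affine in the envelope value: 1 degree at 0, 2.5 degrees at
    1.  A flash turns the outer ring cyan for 100 ms: frame ``k`` flashes
    iff its start time lies in [onset, onset + 0.1) — exactly six frames
    at 60 frames/s.
    """
    vals = venv.frame_values
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("visual envelope values must lie in [0, 1]")
    radii = RADIUS_MIN_DEG + vals * (RADIUS_MAX_DEG - RADIUS_MIN_DEG)
    t = np.arange(len(vals)) / venv.frame_rate
    flash_frames = np.zeros(len(vals), dtype=bool)
    duration = len(vals) / venv.frame_rate
    for onset in flashes:
        if onset + FLASH_DURATION > duration:
            raise SchedulingError(f"flash at {onset} s extends past the trial")
        flash_frames |= (t >= onset) & (t < onset + FLASH_DURATION)
    return VisualTimecourse(
        radii_deg=radii, flash_frames=flash_frames, frame_rate=venv.frame_rate
    )
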