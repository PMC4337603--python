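"""Band-limited stochastic amplitude envelopes.

The slowly varying temporal structure of every stream in the paradigm —
the amplitude of each of the two competing auditory streams and the radius
of the visual disc — is a low-pass noise envelope, synthesized in the
frequency domain: unit magnitude on every FFT bin strictly between 0 Hz
and the cutoff (7 Hz by default), uniformly random phases, Hermitian
symmetry, inverse transform.  Three such envelopes are drawn per trial and
made mutually orthogonal by a Gram-Schmidt pass so that no residual
correlation links target, masker, and the "neither" visual envelope.  Each
is then rescaled to span [0, 1] and pushed through the accentuating
nonlinearity y = sin^2(pi*x/2), which steepens the approach to the
extremes while fixing 0, 1/2, and 1.

An envelope carries its synthesis stage (``raw`` -> ``orthogonalized`` ->
``normalized`` -> ``accentuated``) so that downstream code can assert it
received the stage it expects; the band limit holds exactly through the
first three stages and is deliberately not asserted after accentuation,
since the pointwise nonlinearity spreads energy above the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "NoiseEnvelope",
    "VisualEnvelope",
    "DegenerateBandError",
    "DegenerateTripletError",
    "make_raw_envelope",
    "orthogonalize_triplet",
    "normalize_unit_interval",
    "accentuate",
    "make_orthogonal_raw_triplet",
    "make_trial_envelopes",
    "subsample_for_video",
    "flat_envelope",
    "export_envelope_csv",
]

STAGES = ("raw", "orthogonalized", "normalized", "accentuated")


class DegenerateBandError(ValueError):
    """No frequency bin lies strictly inside (0, cutoff)."""


class DegenerateTripletError(ValueError):
    """Gram-Schmidt residual vanished: inputs are linearly dependent."""


@dataclass(frozen=True)
class NoiseEnvelope:
    """A sampled amplitude timecourse with synthesis-stage provenance.

    Attributes
    ----------
    samples : np.ndarray
        Real-valued amplitude sequence, length ``round(duration * rate)``.
    rate : float
        Sampling rate in samples/s.
    cutoff : float
        Band-limit cutoff in Hz (holds for stages before accentuation).
    stage : str
        One of ``raw``, ``orthogonalized``, ``normalized``, ``accentuated``.
    """

    samples: np.ndarray
    rate: float
    cutoff: float
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class VisualEnvelope:
    """Per-frame envelope values driving the visual disc radius.

    Frame ``k`` holds the auditory envelope sample at the frame's start,
    so the disc radius agrees with the auditory amplitude at the beginning
    of every monitor frame.
    """

    frame_values: np.ndarray
    frame_rate: float

    def __len__(self) -> int:
        return len(self.frame_values)


def make_raw_envelope(
    duration: float, rate: float, cutoff: float, rng: np.random.Generator
) -> NoiseEnvelope:
    """Synthesize one flat-spectrum low-pass noise envelope.

    Every rFFT bin with frequency strictly between 0 and ``cutoff`` gets
    unit magnitude and an independent uniform phase in [0, 2*pi); the DC
    bin, the Nyquist bin, and everything at or above the cutoff are zero.
    The inverse real FFT enforces Hermitian symmetry, so the output is
    exactly real.

    Raises
    ------
    DegenerateBandError
        If no bin lies strictly inside (0, cutoff).
    ValueError
        For non-positive duration/rate or cutoff outside (0, rate/2).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not (0 < cutoff < rate / 2):
        raise ValueError("cutoff must lie in (0, rate/2)")
    n = int(round(duration * rate))
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    in_band = (freqs > 0) & (freqs < cutoff)
    if not in_band.any():
        raise DegenerateBandError(
            f"no frequency bin strictly inside (0, {cutoff} Hz) "
            f"at n={n}, rate={rate}"
        )
    spectrum = np.zeros(freqs.size, dtype=complex)
    phases = rng.uniform(0.0, 2.0 * np.pi, int(in_band.sum()))
    spectrum[in_band] = np.exp(1j * phases)
    samples = np.fft.irfft(spectrum, n)
    return NoiseEnvelope(samples=samples, rate=float(rate), cutoff=float(cutoff), stage="raw")


def _project_out(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    return v - (np.dot(v, u) / np.dot(u, u)) * u


def orthogonalize_triplet(
    e1: NoiseEnvelope, e2: NoiseEnvelope, e3: NoiseEnvelope, rel_tol: float = 1e-10
) -> Tuple[NoiseEnvelope, NoiseEnvelope, NoiseEnvelope]:
    """Gram-Schmidt: leave ``e1`` untouched, orthogonalize ``e2`` and ``e3``.

    The second envelope has its projection on the first removed; the third
    has its projections on the first and on the already-orthogonalized
    second removed.  Inner products are plain unweighted dot products over
    the full sample sequences.  Linear combinations of band-limited
    signals stay band-limited, so the outputs keep the cutoff.
    """
    if not (len(e1) == len(e2) == len(e3)):
        raise ValueError("envelopes must have equal length")
    if not (e1.rate == e2.rate == e3.rate):
        raise ValueError("envelopes must share a sampling rate")
    v1 = e1.samples
    n1 = np.linalg.norm(v1)
    if n1 == 0:
        raise DegenerateTripletError("first envelope has zero norm")
    u2 = _project_out(e2.samples, v1)
    if np.linalg.norm(u2) <= rel_tol * np.linalg.norm(e2.samples):
        raise DegenerateTripletError("second envelope is parallel to the first")
    u3 = _project_out(_project_out(e3.samples, v1), u2)
    if np.linalg.norm(u3) <= rel_tol * np.linalg.norm(e3.samples):
        raise DegenerateTripletError("third envelope lies in the span of the first two")
    out = []
    for env, s in ((e1, v1), (e2, u2), (e3, u3)):
        out.append(replace(env, samples=s, stage="orthogonalized"))
    return tuple(out)


def normalize_unit_interval(env: NoiseEnvelope) -> NoiseEnvelope:
    """Affinely rescale samples so min = 0 and max = 1."""
    lo = float(env.samples.min())
    hi = float(env.samples.max())
    if hi <= lo:
        raise ValueError("constant envelope cannot be normalized to [0, 1]")
    return replace(env, samples=(env.samples - lo) / (hi - lo), stage="normalized")


def accentuate(env: NoiseEnvelope) -> NoiseEnvelope:
    """Apply the extremes-accentuating map y = sin^2(pi*x/2) pointwise.

    The map fixes 0, 1/2, and 1, is monotone nondecreasing on [0, 1], and
    flattens the envelope near its extremes.  Requires a ``normalized``
    input so the domain is exactly [0, 1].
    """
    if env.stage != "normalized":
        raise ValueError("accentuate expects a normalized envelope")
    x = env.samples
    if x.min() < 0 or x.max() > 1:
        raise ValueError("normalized envelope must lie in [0, 1]")
    y = np.sin(np.pi * x / 2.0) ** 2
    return replace(env, samples=y, stage="accentuated")


def make_orthogonal_raw_triplet(
    duration: float, rate: float, cutoff: float, rng: np.random.Generator
) -> Tuple[NoiseEnvelope, NoiseEnvelope, NoiseEnvelope]:
    """Three independent raw envelopes, Gram-Schmidt orthogonalized."""
    e1 = make_raw_envelope(duration, rate, cutoff, rng)
    e2 = make_raw_envelope(duration, rate, cutoff, rng)
    e3 = make_raw_envelope(duration, rate, cutoff, rng)
    return orthogonalize_triplet(e1, e2, e3)


def make_trial_envelopes(
    duration: float, rate: float, cutoff: float, rng: np.random.Generator
) -> Tuple[NoiseEnvelope, NoiseEnvelope, NoiseEnvelope]:
    """The three per-trial envelopes (target, masker, third), accentuated.

    Orthogonalization happens on the raw envelopes; each output is then
    independently rescaled to [0, 1] and accentuated, so the three
    returned envelopes all span the unit interval while their
    pre-accentuation versions are pairwise orthogonal.
    """
    triplet = make_orthogonal_raw_triplet(duration, rate, cutoff, rng)
    return tuple(accentuate(normalize_unit_interval(e)) for e in triplet)


def subsample_for_video(env: NoiseEnvelope, frame_rate: float = 60.0) -> VisualEnvelope:
    """Subsample an auditory envelope at the monitor frame rate.

    Frame ``k`` takes the auditory sample at index
    ``floor(k * rate / frame_rate)`` — frame 0 is audio sample 0 — and the
    frame count is ``floor(duration * frame_rate)``.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if frame_rate > env.rate:
        raise ValueError("frame_rate must not exceed the envelope rate")
    n_frames = int(math.floor(len(env) / env.rate * frame_rate))
    idx = np.floor(np.arange(n_frames) * env.rate / frame_rate).astype(np.intp)
    return VisualEnvelope(frame_values=env.samples[idx], frame_rate=float(frame_rate))


def flat_envelope(duration: float, rate: float, value: float = 1.0) -> NoiseEnvelope:
    """Constant diagnostic envelope (stage ``accentuated`` by convention).

    Used to probe carriers in isolation (e.g., instantaneous-frequency or
    spectral measurements) without amplitude modulation.
    """
    n = int(round(duration * rate))
    return NoiseEnvelope(
        samples=np.full(n, float(value)), rate=float(rate), cutoff=float(rate) / 2,
        stage="accentuated",
    )


def export_envelope_csv(env: NoiseEnvelope, path, seed: int | None = None) -> None:
    """Write one sample per line with a small commented header."""
    header = f"rate={env.rate},cutoff={env.cutoff},stage={env.stage}"
    if seed is not None:
        header += f",seed={seed}"
    np.savetxt(path, env.samples, fmt="%.12g", header=header)
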