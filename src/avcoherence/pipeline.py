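"""Glue from scheduled trials to rendered stimuli and files."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .config import RunConfig
from .envelopes import subsample_for_video
from .scheduler import TrialSpec
from .stimuli import (
    VOWELS,
    AudioStream,
    CarrierSpec,
    TrialAudio,
    VisualTimecourse,
    mix_trial,
    render_visual_timecourse,
    synthesize_pitch_stream,
    synthesize_timbre_stream,
)

__all__ = ["synthesize_trial", "write_trial"]


def synthesize_trial(
    trial: TrialSpec, cfg: RunConfig, rng: np.random.Generator
) -> Tuple[TrialAudio, VisualTimecourse, AudioStream, AudioStream]:
    """Render one trial: target + masker streams, mixture, visual frames.

    Carrier-to-role assignment is counterbalanced by the trial's envelope
    seed parity (which stream family plays target alternates across
    trials, as the carriers were counterbalanced across the session).
    The condition selects which of the trial's three orthogonal envelopes
    drives the visual radius.
    """
    target_env, masker_env, third_env = trial.envelopes()
    swap = trial.envelope_seed % 2 == 1
    if trial.task == "pitch":
        lo = CarrierSpec(f0=cfg.pitch_f0s[0])
        hi = CarrierSpec(f0=cfg.pitch_f0s[1], level_offset_db=cfg.high_stream_level_offset_db)
        t_spec, m_spec = (hi, lo) if swap else (lo, hi)
        target = synthesize_pitch_stream(
            t_spec, target_env, trial.schedule.target_onsets,
            event_duration=cfg.pitch_event_duration,
            event_peak=cfg.pitch_event_peak_semitones,
        )
        masker = synthesize_pitch_stream(
            m_spec, masker_env, trial.schedule.masker_onsets,
            event_duration=cfg.pitch_event_duration,
            event_peak=cfg.pitch_event_peak_semitones,
        )
    else:
        u, a = VOWELS["u"], VOWELS["a"]
        t_spec, m_spec = (a, u) if swap else (u, a)
        target = synthesize_timbre_stream(
            t_spec, target_env, trial.schedule.target_onsets,
            fraction=cfg.timbre_fraction, event_duration=cfg.timbre_event_duration,
        )
        masker = synthesize_timbre_stream(
            m_spec, masker_env, trial.schedule.masker_onsets,
            fraction=cfg.timbre_fraction, event_duration=cfg.timbre_event_duration,
        )
    audio = mix_trial(
        target, masker, masker_delay=trial.masker_delay,
        noise_level_db=cfg.noise_level_db[trial.task], rng=rng,
    )
    visual_env = (target_env, masker_env, third_env)[trial.visual_envelope_index()]
    venv = subsample_for_video(visual_env, cfg.frame_rate)
    visual = render_visual_timecourse(venv, trial.schedule.flash_onsets)
    return audio, visual, target, masker


def write_trial(
    outdir: str | Path,
    trial_id: int,
    trial: TrialSpec,
    audio: TrialAudio,
    visual: VisualTimecourse,
) -> dict:
    """Write WAV + visual CSV + schedule JSON; returns the manifest entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"trial_{trial_id:03d}"
    wavfile.write(
        outdir / f"{stem}.wav", int(round(audio.rate)),
        audio.mixture.astype(np.float32),
    )
    pd.DataFrame(
        {
            "frame": np.arange(len(visual.radii_deg)),
            "radius_deg": visual.radii_deg,
            "flash_flag": visual.flash_frames.astype(int),
        }
    ).to_csv(outdir / f"{stem}_visual.csv", index=False)
    entry = {
        "trial_id": trial_id,
        "condition": trial.condition,
        "task": trial.task,
        "envelope_seed": trial.envelope_seed,
        "target_onsets": list(trial.schedule.target_onsets),
        "masker_onsets": list(trial.schedule.masker_onsets),
        "flash_onsets": list(trial.schedule.flash_onsets),
        "auditory_event_duration": trial.schedule.auditory_event_duration,
        "mixture_scale": audio.scale,
    }
    (outdir / f"{stem}_schedule.json").write_text(json.dumps(entry, indent=2))
    return entry
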