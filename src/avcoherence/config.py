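"""Run configuration: every tunable constant of the pipeline in one place.

Defaults reproduce the study design (trial structure, synthesis rates,
carrier and formant tables, scheduling constraints, cohort shape); any
field can be overridden from a YAML file or keyword arguments, and a
config round-trips losslessly through serialization.  The
``CONSTANTS_REGISTRY`` maps each numeric field to the module-level
default it governs, so completeness is testable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import yaml

from . import observer, scheduler, sdt, stimuli

__all__ = ["RunConfig", "CONSTANTS_REGISTRY"]


@dataclass
class RunConfig:
    """Configuration for synthesis, simulation, scoring, and analysis."""

    task: str = "pitch"
    seed: int = 0
    output_dir: str = "avcoherence_out"

    # rates and trial structure
    audio_rate: float = 24414.0
    frame_rate: float = 60.0
    trial_duration: float = 14.0
    masker_delay: float = 1.0
    envelope_cutoff: float = 7.0

    # scheduling constraints
    n_per_condition: int = 32
    event_start_min: float = 2.0
    event_end_max: float = 13.0
    min_onset_separation: float = 1.2
    envelope_gate: float = 0.75
    response_window: float = 1.0
    target_event_range: Tuple[int, int] = (1, 3)
    flash_range: Tuple[int, int] = (0, 2)

    # synthesis constants
    pitch_f0s: Tuple[float, float] = (440.0, 565.0)
    high_stream_level_offset_db: float = -3.0
    pitch_event_duration: float = 0.1
    pitch_event_peak_semitones: float = 1.5
    timbre_event_duration: float = 0.2
    timbre_fraction: float = 0.1225  # average perceptual threshold shift
    formant_bandwidths: Tuple[float, float, float, float] = (60.0, 90.0, 150.0, 200.0)
    ramp_duration: float = 0.010
    noise_level_db: Dict[str, float] = field(
        default_factory=lambda: {"pitch": -24.0, "timbre": -11.0}
    )
    radius_range_deg: Tuple[float, float] = (1.0, 2.5)
    ring_width_deg: float = 0.125
    flash_duration: float = 0.1
    viewing_distance_cm: float = 50.0  # metadata only; nothing is rendered

    # cohort / observer
    n_per_group: int = 16
    observer_profile: str = "reference"  # or "null"
    p_visual_hit: float = 0.877
    dprime_floor: float = 0.7

    def __post_init__(self) -> None:
        if self.task not in ("pitch", "timbre"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.observer_profile not in ("reference", "null"):
            raise ValueError(f"unknown observer profile {self.observer_profile!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(names)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for k, v in data.items():
            if isinstance(v, list):
                v = tuple(v)
            coerced[k] = v
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def profile(self) -> observer.EffectProfile:
        prof = (
            observer.reference_profile()
            if self.observer_profile == "reference"
            else observer.null_profile()
        )
        return dataclasses.replace(prof, p_visual_hit=self.p_visual_hit)


#: config field -> the module default it overrides (None: config-only knob).
CONSTANTS_REGISTRY: Dict[str, object] = {
    "audio_rate": stimuli.AUDIO_RATE,
    "frame_rate": 60.0,
    "trial_duration": scheduler.TRIAL_DURATION,
    "masker_delay": scheduler.MASKER_DELAY,
    "envelope_cutoff": 7.0,
    "n_per_condition": scheduler.TRIALS_PER_CONDITION,
    "event_start_min": scheduler.EVENT_START_MIN,
    "event_end_max": scheduler.EVENT_END_MAX,
    "min_onset_separation": scheduler.MIN_ONSET_SEPARATION,
    "envelope_gate": scheduler.ENVELOPE_GATE,
    "response_window": sdt.RESPONSE_WINDOW,
    "target_event_range": scheduler.TARGET_EVENT_RANGE,
    "flash_range": scheduler.FLASH_RANGE,
    "pitch_f0s": stimuli.PITCH_F0S,
    "high_stream_level_offset_db": stimuli.HIGH_STREAM_LEVEL_OFFSET_DB,
    "pitch_event_duration": stimuli.PITCH_EVENT_DURATION,
    "pitch_event_peak_semitones": stimuli.PITCH_EVENT_PEAK_SEMITONES,
    "timbre_event_duration": stimuli.TIMBRE_EVENT_DURATION,
    "formant_bandwidths": stimuli.DEFAULT_FORMANT_BANDWIDTHS,
    "ramp_duration": stimuli.RAMP_DURATION,
    "radius_range_deg": (stimuli.RADIUS_MIN_DEG, stimuli.RADIUS_MAX_DEG),
    "ring_width_deg": stimuli.RING_WIDTH_DEG,
    "flash_duration": stimuli.FLASH_DURATION,
    "n_per_group": 16,
    "p_visual_hit": 0.877,
    "dprime_floor": sdt.DPRIME_EXCLUSION_FLOOR,
}
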