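"""Session construction and constraint-satisfying event scheduling.

Each 14 s trial carries 1-3 target perturbation events, 1-3 masker
events, and 0-2 visual flashes (counts uniform over those ranges, so the
means are 2, 2, and 1).  Onsets are drawn uniformly from the feasible
set on a 1 ms grid, subject to the constraints:

* no event in the first 2 s (1 s after the masker begins) or ending in
  the last 1 s of the trial;
* every pair of onsets — across target, masker, and visual events — is
  separated by at least 1.2 s, which also guarantees that the 1 s
  response-attribution windows never overlap;
* an event may only begin when *both* auditory envelopes are at or above
  75% of their own maxima, ensuring audibility and equivalent
  target-to-masker ratios without cueing the subject.

A session is 32 trials of each of the three audio-visual coherence
conditions (96 total) in uniformly random order; the condition determines
which of the trial's three mutually orthogonal envelopes drives the
visual stream.  Every trial records its own seed so it can be replayed
bit-for-bit (envelopes included) without storing the sample data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .envelopes import NoiseEnvelope, make_trial_envelopes, subsample_for_video
from .stimuli import FLASH_DURATION, PITCH_EVENT_DURATION, TIMBRE_EVENT_DURATION

__all__ = [
    "CONDITIONS",
    "EVENT_DURATIONS",
    "EventSchedule",
    "TrialSpec",
    "UnschedulableTrialError",
    "draw_event_counts",
    "schedule_events",
    "build_session",
    "check_schedule",
    "session_to_frame",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("match_target", "match_masker", "match_neither")

TRIAL_DURATION = 14.0
MASKER_DELAY = 1.0
EVENT_START_MIN = 2.0  # no events in the first 2 s ...
EVENT_END_MAX = 13.0  # ... or the last 1 s
MIN_ONSET_SEPARATION = 1.2
ENVELOPE_GATE = 0.75  # both auditory envelopes >= 75% of their maxima
SCHEDULING_GRID_DT = 0.001
MAX_SCHEDULING_ATTEMPTS = 10_000
RESPONSE_WINDOW = 1.0

EVENT_DURATIONS = {"pitch": PITCH_EVENT_DURATION, "timbre": TIMBRE_EVENT_DURATION}

TARGET_EVENT_RANGE = (1, 3)
FLASH_RANGE = (0, 2)
TRIALS_PER_CONDITION = 32


class UnschedulableTrialError(RuntimeError):
    """Rejection sampling exhausted its attempt budget for this trial."""


@dataclass(frozen=True)
class EventSchedule:
    """Typed, timed events for one trial."""

    target_onsets: Tuple[float, ...]
    masker_onsets: Tuple[float, ...]
    flash_onsets: Tuple[float, ...]
    auditory_event_duration: float
    flash_duration: float = FLASH_DURATION

    def all_onsets(self) -> Tuple[float, ...]:
        return tuple(sorted(self.target_onsets + self.masker_onsets + self.flash_onsets))


@dataclass(frozen=True)
class TrialSpec:
    """One trial: condition, schedule, and the recipe for its envelopes.

    Envelopes are regenerated on demand from ``envelope_seed`` rather than
    stored, so a full session stays small; ``envelopes()`` returns the
    accentuated (target, masker, third) triplet and the condition picks
    which of the three drives the visual radius.
    """

    condition: str
    task: str
    schedule: EventSchedule
    envelope_seed: int
    duration: float = TRIAL_DURATION
    masker_delay: float = MASKER_DELAY
    envelope_rate: float = 24414.0
    envelope_cutoff: float = 7.0
    n_envelope_regens: int = 0

    def envelopes(self) -> Tuple[NoiseEnvelope, NoiseEnvelope, NoiseEnvelope]:
        rng = np.random.default_rng(self.envelope_seed)
        return make_trial_envelopes(
            self.duration, self.envelope_rate, self.envelope_cutoff, rng
        )

    def visual_envelope_index(self) -> int:
        return CONDITIONS.index(self.condition)  # target, masker, third


def draw_event_counts(rng: np.random.Generator) -> Tuple[int, int, int]:
    """Counts of (target events, masker events, visual flashes) for one trial.

    Uniform over {1, 2, 3} for each auditory stream (mean 2) and uniform
    over {0, 1, 2} for flashes (mean 1) — the maximum-entropy distributions
    matching the stated ranges and means.
    """
    n_target = int(rng.integers(TARGET_EVENT_RANGE[0], TARGET_EVENT_RANGE[1] + 1))
    n_masker = int(rng.integers(TARGET_EVENT_RANGE[0], TARGET_EVENT_RANGE[1] + 1))
    n_flash = int(rng.integers(FLASH_RANGE[0], FLASH_RANGE[1] + 1))
    return n_target, n_masker, n_flash


def _gate_mask(env: NoiseEnvelope, grid: np.ndarray, gate: float) -> np.ndarray:
    idx = np.minimum((grid * env.rate).astype(np.intp), len(env) - 1)
    return env.samples[idx] >= gate * env.samples.max()


def _max_packable(cands: np.ndarray, sep: float) -> int:
    """Largest number of onsets from ``cands`` with pairwise gaps >= sep."""
    count = 0
    pos = 0
    while pos < cands.size:
        t = cands[pos]
        count += 1
        pos = int(np.searchsorted(cands, t + sep))
    return count


def schedule_events(
    target_env: NoiseEnvelope,
    masker_env: NoiseEnvelope,
    counts: Tuple[int, int, int],
    auditory_event_duration: float,
    rng: np.random.Generator,
    *,
    flash_duration: float = FLASH_DURATION,
    gate: float = ENVELOPE_GATE,
    min_separation: float = MIN_ONSET_SEPARATION,
    grid_dt: float = SCHEDULING_GRID_DT,
    max_attempts: int = MAX_SCHEDULING_ATTEMPTS,
) -> EventSchedule:
    """Draw a constraint-satisfying schedule by rejection sampling.

    Candidate onsets live on a ``grid_dt`` grid restricted to times where
    the edge-exclusion and the 75%-of-maximum gate (evaluated on *both*
    auditory envelopes at the onset sample) hold; events are placed one at
    a time in random type order, rejecting any draw within
    ``min_separation`` of an already-placed onset.

    Raises
    ------
    UnschedulableTrialError
        After ``max_attempts`` rejected draws; the caller is expected to
        regenerate the trial's envelopes with a new seed.
    """
    n_target, n_masker, n_flash = counts
    grid = np.arange(EVENT_START_MIN, EVENT_END_MAX, grid_dt)
    gate_ok = _gate_mask(target_env, grid, gate) & _gate_mask(masker_env, grid, gate)
    feasible: Dict[float, np.ndarray] = {}
    for dur in {auditory_event_duration, flash_duration}:
        feasible[dur] = grid[gate_ok & (grid + dur <= EVENT_END_MAX)]
        if feasible[dur].size == 0:
            raise UnschedulableTrialError("empty feasible set for event placement")
    kinds = ["target"] * n_target + ["masker"] * n_masker + ["flash"] * n_flash
    # Greedy earliest-fit packs the maximum number of separation-respecting
    # onsets, so it gives a cheap exact upper bound on how many events this
    # envelope pair can host; reject impossible trials without sampling.
    widest = max(feasible, key=lambda d: feasible[d].size)
    if _max_packable(feasible[widest], min_separation) < len(kinds):
        raise UnschedulableTrialError("feasible set cannot host the drawn event counts")
    # Events are placed one at a time, each drawn uniformly from the
    # candidates still compatible with the separation constraint (this is
    # the conditional law of accepted rejection draws, so onsets remain
    # uniform over the feasible set).  Sequential placement can still
    # paint itself into a corner when an arrangement exists, so an empty
    # candidate set restarts the whole schedule; only exhausting the
    # attempt budget declares the trial unschedulable.
    attempts = 0
    while attempts < max_attempts:
        rng.shuffle(kinds)
        placed: Dict[str, list] = {"target": [], "masker": [], "flash": []}
        onsets: list = []
        stuck = False
        for kind in kinds:
            attempts += 1
            dur = flash_duration if kind == "flash" else auditory_event_duration
            cands = feasible[dur]
            if onsets:
                sep_ok = np.all(
                    np.abs(cands[:, None] - np.asarray(onsets)) >= min_separation,
                    axis=1,
                )
                cands = cands[sep_ok]
            if cands.size == 0:
                stuck = True
                break
            t = float(cands[rng.integers(cands.size)])
            onsets.append(t)
            placed[kind].append(t)
        if not stuck:
            return EventSchedule(
                target_onsets=tuple(sorted(placed["target"])),
                masker_onsets=tuple(sorted(placed["masker"])),
                flash_onsets=tuple(sorted(placed["flash"])),
                auditory_event_duration=auditory_event_duration,
            )
    raise UnschedulableTrialError(f"no valid schedule after {attempts} attempts")


def check_schedule(
    schedule: EventSchedule,
    target_env: NoiseEnvelope | None = None,
    masker_env: NoiseEnvelope | None = None,
    *,
    gate: float = ENVELOPE_GATE,
    window: float = RESPONSE_WINDOW,
) -> None:
    """Assert every schedule invariant; raises ValueError on violation.

    Checks edge exclusion, pairwise onset separation, event-count ranges,
    disjointness of the ``(onset, onset + window]`` attribution windows,
    and (when envelopes are given) the 75% gate.
    """
    sched = schedule
    if not (TARGET_EVENT_RANGE[0] <= len(sched.target_onsets) <= TARGET_EVENT_RANGE[1]):
        raise ValueError("target event count out of range")
    if not (TARGET_EVENT_RANGE[0] <= len(sched.masker_onsets) <= TARGET_EVENT_RANGE[1]):
        raise ValueError("masker event count out of range")
    if not (FLASH_RANGE[0] <= len(sched.flash_onsets) <= FLASH_RANGE[1]):
        raise ValueError("flash count out of range")
    typed = (
        [(t, sched.auditory_event_duration) for t in sched.target_onsets]
        + [(t, sched.auditory_event_duration) for t in sched.masker_onsets]
        + [(t, sched.flash_duration) for t in sched.flash_onsets]
    )
    for t, dur in typed:
        if t < EVENT_START_MIN or t + dur > EVENT_END_MAX:
            raise ValueError(f"event at {t} s violates edge exclusion")
    onsets = sorted(t for t, _ in typed)
    for a, b in zip(onsets, onsets[1:]):
        if b - a < MIN_ONSET_SEPARATION:
            raise ValueError(f"onsets {a} s and {b} s closer than the minimum separation")
        if b - a < window:  # implied by the separation check; kept explicit
            raise ValueError("attribution windows overlap")
    if target_env is not None and masker_env is not None:
        for env in (target_env, masker_env):
            idx = np.minimum(
                (np.asarray(onsets) * env.rate).astype(np.intp), len(env) - 1
            )
            if np.any(env.samples[idx] < gate * env.samples.max() - 1e-12):
                raise ValueError("envelope gate violated at an event onset")


def build_session(
    task: str,
    rng: np.random.Generator,
    n_per_condition: int = TRIALS_PER_CONDITION,
    *,
    duration: float = TRIAL_DURATION,
    envelope_rate: float = 24414.0,
    cutoff: float = 7.0,
    max_regens: int = 1000,
) -> Tuple[TrialSpec, ...]:
    """One subject's session: ``n_per_condition`` trials per condition,
    presentation order uniformly shuffled.

    If a trial's envelopes admit no valid schedule, fresh envelopes are
    drawn (new seed, same event counts) and the regeneration is logged and
    counted on the trial.
    """
    if task not in EVENT_DURATIONS:
        raise ValueError(f"unknown task {task!r}")
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    event_dur = EVENT_DURATIONS[task]
    trials: list[TrialSpec] = []
    for condition in CONDITIONS:
        for _ in range(n_per_condition):
            counts = draw_event_counts(rng)
            regens = 0
            while True:
                seed = int(rng.integers(2**31))
                env_rng = np.random.default_rng(seed)
                target, masker, _third = make_trial_envelopes(
                    duration, envelope_rate, cutoff, env_rng
                )
                try:
                    sched = schedule_events(
                        target, masker, counts, event_dur, rng
                    )
                    break
                except UnschedulableTrialError:
                    regens += 1
                    logger.info(
                        "unschedulable trial (condition=%s, counts=%s); "
                        "regenerating envelopes (%d)", condition, counts, regens,
                    )
                    if regens > max_regens:
                        raise
            trials.append(
                TrialSpec(
                    condition=condition, task=task, schedule=sched,
                    envelope_seed=seed, duration=duration,
                    envelope_rate=envelope_rate, envelope_cutoff=cutoff,
                    n_envelope_regens=regens,
                )
            )
    order = rng.permutation(len(trials))
    return tuple(trials[i] for i in order)


def session_to_frame(session: Sequence[TrialSpec]) -> pd.DataFrame:
    """Flatten a session to one row per event for CSV serialization."""
    rows = []
    for trial_id, trial in enumerate(session):
        sched = trial.schedule
        for kind, onsets, dur in (
            ("target", sched.target_onsets, sched.auditory_event_duration),
            ("masker", sched.masker_onsets, sched.auditory_event_duration),
            ("flash", sched.flash_onsets, sched.flash_duration),
        ):
            for onset in onsets:
                rows.append(
                    dict(
                        trial_id=trial_id, condition=trial.condition,
                        event_type=kind, onset_s=onset, duration_s=dur,
                        seed=trial.envelope_seed,
                    )
                )
    return pd.DataFrame(rows)
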