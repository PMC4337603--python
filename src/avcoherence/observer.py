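"""Simulated observers: the synthetic-data generator for behavioral runs.

A simulated observer presses a single button (shared between auditory
events and visual flashes, as in the task) with condition-dependent
probabilities: each target event elicits a press with probability
``(1 - lapse) * p_hit[condition]`` at a random latency inside the 1 s
attribution window, each masker event with ``(1 - lapse) *
p_fa[condition]``, each flash with ``p_visual_hit``; optional spontaneous
presses arrive as a Poisson process.  The simulator targets the
*statistical structure* of the behavioral data — per subject x condition
counts of hits, false alarms, and visual hits — not any internal sensory
or decision process.

Cohorts mirror the study's shape: two groups of 16 subjects (pitch task
and timbre task), 96 trials each.  An :class:`EffectProfile` specifies
per-task, per-condition generating d' and a criterion; these are
converted to hit/false-alarm probabilities through the equal-variance
Gaussian model (hr = Phi(d'/2 - c), far = Phi(-d'/2 - c)), with
between-subject normal jitter on both.  The shipped ``reference_profile``
encodes the reported effect directions (match-target > match-neither >
match-masker in d'; pitch task easier than timbre; conservative
criterion; visual hits near 88%); ``null_profile`` makes every condition
identical, for calibration studies.  Profiles are configuration, not
empirical claims.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .scheduler import CONDITIONS, TrialSpec, build_session

__all__ = [
    "ObserverParams",
    "ResponseLog",
    "EffectProfile",
    "Cohort",
    "reference_profile",
    "null_profile",
    "dprime_to_rates",
    "observer_from_profile",
    "simulate_trial_responses",
    "simulate_session_responses",
    "simulate_cohort",
    "simulate_counts_cohort",
]

RESPONSE_WINDOW = 1.0
DEFAULT_LATENCY = (0.15, 0.9)  # uniform support, keeps hits attributable
TASKS = ("pitch", "timbre")


@dataclass(frozen=True)
class ObserverParams:
    """Per-subject response probabilities and timing."""

    p_hit: Dict[str, float]  # per condition, per target event
    p_fa: Dict[str, float]  # per condition, per masker event
    p_visual_hit: float
    lapse: float = 0.0
    latency: Tuple[float, float] = DEFAULT_LATENCY
    spontaneous_rate: float = 0.0  # presses/s, unrelated to events

    def __post_init__(self) -> None:
        probs = [*self.p_hit.values(), *self.p_fa.values(), self.p_visual_hit, self.lapse]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.latency
        if not (0 < lo < hi <= RESPONSE_WINDOW):
            raise ValueError("latency support must lie within (0, 1] s")


@dataclass(frozen=True)
class ResponseLog:
    """Button-press times for one trial, strictly increasing."""

    trial_id: int
    press_times: Tuple[float, ...]


@dataclass(frozen=True)
class EffectProfile:
    """Generating parameters for a cohort, on the d' scale.

    ``dprime[task][condition]`` and ``criterion`` are population means;
    subjects are drawn with normal jitter (``sd_dprime``, ``sd_criterion``)
    around them.  ``p_fa`` floors at the model value even when jitter
    pushes d' negative, via clipping of both rates to (0.01, 0.99).
    """

    dprime: Dict[str, Dict[str, float]]
    criterion: float = 0.5
    sd_dprime: float = 0.35
    sd_criterion: float = 0.2
    p_visual_hit: float = 0.877
    lapse: float = 0.0
    spontaneous_rate: float = 0.0


def reference_profile() -> EffectProfile:
    """Effect directions matching the reported pattern, for demos/power runs."""
    return EffectProfile(
        dprime={
            "pitch": {"match_target": 2.4, "match_masker": 1.9, "match_neither": 2.15},
            "timbre": {"match_target": 1.55, "match_masker": 1.05, "match_neither": 1.3},
        },
    )


def null_profile(d: float = 1.5) -> EffectProfile:
    """Identical generating d' in every cell: the calibration null."""
    return EffectProfile(
        dprime={t: {c: d for c in CONDITIONS} for t in TASKS},
    )


def dprime_to_rates(d: float, criterion: float) -> Tuple[float, float]:
    """Equal-variance Gaussian model: hit and false-alarm probabilities
    for sensitivity ``d`` and criterion ``criterion`` (positive =
    conservative), clipped to (0.01, 0.99)."""
    hr = norm.cdf(d / 2.0 - criterion)
    far = norm.cdf(-d / 2.0 - criterion)
    return float(np.clip(hr, 0.01, 0.99)), float(np.clip(far, 0.01, 0.99))


def observer_from_profile(
    profile: EffectProfile, task: str, rng: np.random.Generator
) -> ObserverParams:
    """Draw one subject's parameters around the profile means."""
    c = profile.criterion + rng.normal(0.0, profile.sd_criterion)
    shift = rng.normal(0.0, profile.sd_dprime)  # shared across conditions
    p_hit, p_fa = {}, {}
    for cond in CONDITIONS:
        hr, far = dprime_to_rates(profile.dprime[task][cond] + shift, c)
        p_hit[cond], p_fa[cond] = hr, far
    return ObserverParams(
        p_hit=p_hit, p_fa=p_fa, p_visual_hit=profile.p_visual_hit,
        lapse=profile.lapse, spontaneous_rate=profile.spontaneous_rate,
    )


def simulate_trial_responses(
    spec: TrialSpec, params: ObserverParams, rng: np.random.Generator,
    trial_id: int = 0,
) -> ResponseLog:
    """Bernoulli press per event, plus Poisson spontaneous presses."""
    sched = spec.schedule
    presses: list[float] = []
    lo, hi = params.latency
    effective = 1.0 - params.lapse

    def maybe_press(onset: float, p: float) -> None:
        if rng.random() < p:
            presses.append(onset + rng.uniform(lo, hi))

    for onset in sched.target_onsets:
        maybe_press(onset, effective * params.p_hit[spec.condition])
    for onset in sched.masker_onsets:
        maybe_press(onset, effective * params.p_fa[spec.condition])
    for onset in sched.flash_onsets:
        maybe_press(onset, params.p_visual_hit)
    if params.spontaneous_rate > 0:
        n_spont = rng.poisson(params.spontaneous_rate * spec.duration)
        presses.extend(rng.uniform(0.0, spec.duration, n_spont))
    times = np.sort(np.asarray(presses))
    if times.size:
        times = times[np.concatenate(([True], np.diff(times) > 0))]  # strict
    return ResponseLog(trial_id=trial_id, press_times=tuple(float(t) for t in times))


def simulate_session_responses(
    session: Tuple[TrialSpec, ...], params: ObserverParams, rng: np.random.Generator
) -> Tuple[ResponseLog, ...]:
    return tuple(
        simulate_trial_responses(spec, params, rng, trial_id=i)
        for i, spec in enumerate(session)
    )


@dataclass(frozen=True)
class Cohort:
    """A simulated multi-subject dataset with full provenance.

    ``sessions[subject_id]`` is the trial list, ``logs[subject_id]`` the
    per-trial response logs, ``params[subject_id]`` the generating
    observer, ``tasks[subject_id]`` the group assignment.
    """

    sessions: Dict[int, Tuple[TrialSpec, ...]]
    logs: Dict[int, Tuple[ResponseLog, ...]]
    params: Dict[int, ObserverParams]
    tasks: Dict[int, str]
    master_seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.sessions)

    def logs_to_frame(self) -> pd.DataFrame:
        rows = [
            dict(subject=s, trial=log.trial_id, press_time_s=t)
            for s, logs in self.logs.items()
            for log in logs
            for t in log.press_times
        ]
        return pd.DataFrame(rows, columns=["subject", "trial", "press_time_s"])


def simulate_cohort(
    rng: np.random.Generator,
    n_per_group: int = 16,
    profile: EffectProfile | None = None,
    *,
    n_per_condition: int = 32,
    envelope_rate: float = 24414.0,
    tasks: Tuple[str, ...] = TASKS,
) -> Cohort:
    """Simulate the full study: ``n_per_group`` subjects per task group,
    each running a complete session of scheduled trials."""
    profile = profile if profile is not None else reference_profile()
    master_seed = int(rng.integers(2**31))
    root = np.random.default_rng(master_seed)
    sessions, logs, params, task_of = {}, {}, {}, {}
    sid = 0
    for task in tasks:
        for _ in range(n_per_group):
            sub_rng = np.random.default_rng(root.integers(2**31))
            p = observer_from_profile(profile, task, sub_rng)
            session = build_session(
                task, sub_rng, n_per_condition, envelope_rate=envelope_rate
            )
            sessions[sid] = session
            logs[sid] = simulate_session_responses(session, p, sub_rng)
            params[sid] = p
            task_of[sid] = task
            sid += 1
    return Cohort(
        sessions=sessions, logs=logs, params=params, tasks=task_of,
        master_seed=master_seed,
    )


def simulate_counts_cohort(
    rng: np.random.Generator,
    n_per_group: int = 16,
    profile: EffectProfile | None = None,
    *,
    n_target: int = 64,
    n_masker: int = 64,
    n_flashes: int = 32,
    tasks: Tuple[str, ...] = TASKS,
) -> pd.DataFrame:
    """Counts-level replicate generator for calibration studies.

    Skips scheduling and response timing entirely: per subject and
    condition, hits ~ Binomial(n_target, p_hit), false alarms ~
    Binomial(n_masker, p_fa), visual hits ~ Binomial(n_flashes,
    p_visual_hit), with the same per-subject parameter draws as
    :func:`simulate_cohort`.  The defaults match one session's expected
    event totals.  Columns: subject, task, condition, n_target, hits,
    n_masker, false_alarms, n_flashes, visual_hits.
    """
    profile = profile if profile is not None else reference_profile()
    rows = []
    sid = 0
    for task in tasks:
        for _ in range(n_per_group):
            p = observer_from_profile(profile, task, rng)
            for cond in CONDITIONS:
                rows.append(
                    dict(
                        subject=sid, task=task, condition=cond,
                        n_target=n_target,
                        hits=int(rng.binomial(n_target, p.p_hit[cond])),
                        n_masker=n_masker,
                        false_alarms=int(rng.binomial(n_masker, p.p_fa[cond])),
                        n_flashes=n_flashes,
                        visual_hits=int(rng.binomial(n_flashes, p.p_visual_hit)),
                    )
                )
            sid += 1
    return pd.DataFrame(rows)
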