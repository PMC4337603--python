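"""Response attribution and signal-detection scoring.

A button press is attributed to an event when it falls in the half-open
window ``(onset, onset + 1 s]``; the scheduler's 1.2 s onset-separation
guarantee makes these windows disjoint, so attribution is unambiguous.
The first press inside a window satisfies the event; later presses in the
same window, and presses in no window, are recorded as unattributed.

Per subject and condition, events are pooled across the condition's
trials: a response to a target event is a hit, to a masker event a false
alarm, to a flash a visual hit.  Raw hit/false-alarm/visual-hit rates are
reported as plain proportions; sensitivity and criterion use corrected
rates ``(count + 0.5) / (n + 1)`` so that both stay strictly inside
(0, 1) and d' has finite limits:

    d'     = z(HR) - z(FAR)
    ln(beta) = (z(FAR)^2 - z(HR)^2) / 2

with z the standard normal quantile.  ln(beta) is the log likelihood
ratio at the decision criterion under the equal-variance Gaussian model;
positive values mean conservative responding.

Subjects whose mean d' across the three conditions falls below a floor
(0.7 by default) can be excluded, mirroring the screening applied to the
harder timbre task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .observer import ResponseLog
from .scheduler import CONDITIONS, EventSchedule, TrialSpec

__all__ = [
    "AttributionOutcome",
    "SDTResult",
    "attribute_responses",
    "corrected_rate",
    "dprime",
    "ln_beta",
    "summarize_subject",
    "results_to_frame",
    "to_source_data_table",
    "apply_exclusion",
    "DPRIME_EXCLUSION_FLOOR",
]

RESPONSE_WINDOW = 1.0
DPRIME_EXCLUSION_FLOOR = 0.7
MEASURES = ("d_prime", "ln_beta", "hit_rate", "fa_rate", "visual_hit_rate")


@dataclass(frozen=True)
class AttributionOutcome:
    """Per-event response flags plus leftover presses.

    ``responded[kind][i]`` says whether the i-th event of that kind (in
    onset order) was answered; ``latencies`` holds the press latency for
    answered events and NaN otherwise.
    """

    responded: Dict[str, Tuple[bool, ...]]
    latencies: Dict[str, Tuple[float, ...]]
    unattributed: Tuple[float, ...]


def attribute_responses(
    log: ResponseLog, schedule: EventSchedule, window: float = RESPONSE_WINDOW
) -> AttributionOutcome:
    """Assign presses to events by the ``(onset, onset + window]`` rule.

    Presses are processed in time order; each press is attributed to the
    (unique) event whose window contains it, unless that event was
    already satisfied, in which case the press is unattributed.
    """
    events = sorted(
        [(t, "target", i) for i, t in enumerate(schedule.target_onsets)]
        + [(t, "masker", i) for i, t in enumerate(schedule.masker_onsets)]
        + [(t, "flash", i) for i, t in enumerate(schedule.flash_onsets)]
    )
    onsets = [e[0] for e in events]
    for a, b in zip(onsets, onsets[1:]):
        if b - a < window:
            raise ValueError("attribution windows overlap; schedule is invalid")
    responded = {
        "target": [False] * len(schedule.target_onsets),
        "masker": [False] * len(schedule.masker_onsets),
        "flash": [False] * len(schedule.flash_onsets),
    }
    latencies = {k: [float("nan")] * len(v) for k, v in responded.items()}
    unattributed: List[float] = []
    for press in sorted(log.press_times):
        j = int(np.searchsorted(onsets, press)) - 1  # latest onset < press
        hit = None
        if j >= 0 and 0 < press - onsets[j] <= window:
            hit = events[j]
        if hit is None:
            unattributed.append(press)
            continue
        _, kind, idx = hit
        if responded[kind][idx]:
            unattributed.append(press)  # first press wins
        else:
            responded[kind][idx] = True
            latencies[kind][idx] = press - hit[0]
    return AttributionOutcome(
        responded={k: tuple(v) for k, v in responded.items()},
        latencies={k: tuple(v) for k, v in latencies.items()},
        unattributed=tuple(unattributed),
    )


def corrected_rate(count: int, n: int) -> float:
    """The finite-limits correction: (count + 0.5) / (n + 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    return (count + 0.5) / (n + 1)


def dprime(hr: float, far: float) -> float:
    """Equal-variance sensitivity z(hr) - z(far); rates must be in (0, 1)."""
    if not (0 < hr < 1 and 0 < far < 1):
        raise ValueError("rates must lie strictly in (0, 1)")
    return float(norm.ppf(hr) - norm.ppf(far))


def ln_beta(hr: float, far: float) -> float:
    """Log likelihood-ratio criterion (z(far)^2 - z(hr)^2) / 2.

    Positive for a conservative criterion (both rates pushed low).
    """
    if not (0 < hr < 1 and 0 < far < 1):
        raise ValueError("rates must lie strictly in (0, 1)")
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return float((zf**2 - zh**2) / 2.0)


@dataclass(frozen=True)
class SDTResult:
    """Detection statistics for one subject x condition cell."""

    subject: int
    task: str
    condition: str
    n_target_events: int
    n_masker_events: int
    n_flashes: int
    hits: int
    false_alarms: int
    visual_hits: int
    hit_rate: float
    fa_rate: float
    visual_hit_rate: float
    corrected_hr: float
    corrected_far: float
    d_prime: float
    ln_beta: float


def _score_condition(
    subject: int, task: str, condition: str,
    hits: int, n_target: int, fas: int, n_masker: int,
    vhits: int, n_flash: int,
) -> SDTResult:
    chr_, cfar = corrected_rate(hits, n_target), corrected_rate(fas, n_masker)
    return SDTResult(
        subject=subject, task=task, condition=condition,
        n_target_events=n_target, n_masker_events=n_masker, n_flashes=n_flash,
        hits=hits, false_alarms=fas, visual_hits=vhits,
        hit_rate=hits / n_target, fa_rate=fas / n_masker,
        visual_hit_rate=vhits / n_flash if n_flash else float("nan"),
        corrected_hr=chr_, corrected_far=cfar,
        d_prime=dprime(chr_, cfar), ln_beta=ln_beta(chr_, cfar),
    )


def summarize_subject(
    logs: Sequence[ResponseLog],
    session: Sequence[TrialSpec],
    task: str,
    subject: int = 0,
    window: float = RESPONSE_WINDOW,
) -> List[SDTResult]:
    """Score one subject's session: one result per coherence condition.

    Events are pooled across each condition's trials before rates are
    formed (a full default session considers 64 potential hits and 64
    potential false alarms per condition).
    """
    if len(logs) != len(session):
        raise ValueError("one response log per trial required")
    tallies = {
        c: dict(hits=0, n_target=0, fas=0, n_masker=0, vhits=0, n_flash=0)
        for c in CONDITIONS
    }
    for log, spec in zip(logs, session):
        out = attribute_responses(log, spec.schedule, window)
        t = tallies[spec.condition]
        t["hits"] += sum(out.responded["target"])
        t["n_target"] += len(spec.schedule.target_onsets)
        t["fas"] += sum(out.responded["masker"])
        t["n_masker"] += len(spec.schedule.masker_onsets)
        t["vhits"] += sum(out.responded["flash"])
        t["n_flash"] += len(spec.schedule.flash_onsets)
    results = []
    for cond in CONDITIONS:
        t = tallies[cond]
        if t["n_target"] == 0 or t["n_masker"] == 0:
            raise ValueError(f"no events pooled for condition {cond!r}")
        results.append(
            _score_condition(
                subject, task, cond, t["hits"], t["n_target"],
                t["fas"], t["n_masker"], t["vhits"], t["n_flash"],
            )
        )
    return results


def results_to_frame(results: Sequence[SDTResult]) -> pd.DataFrame:
    """Long-format results table, one row per subject x condition."""
    return pd.DataFrame([r.__dict__ for r in results])


def to_source_data_table(frame: pd.DataFrame) -> pd.DataFrame:
    """One row per subject with per-condition measure columns.

    Mirrors the deposited per-subject layout: subject and task, then for
    every condition the d', bias (ln beta), hit rate, false-alarm rate,
    and visual hit rate.
    """
    wide = frame.pivot_table(
        index=["subject", "task"], columns="condition",
        values=list(MEASURES), sort=False,
    )
    wide.columns = [f"{m}_{c}" for m, c in wide.columns]
    order = [f"{m}_{c}" for m in MEASURES for c in CONDITIONS]
    return wide[order].reset_index()


def apply_exclusion(
    frame: pd.DataFrame, floor: float = DPRIME_EXCLUSION_FLOOR
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects whose mean d' across conditions is below ``floor``.

    Returns (kept results, exclusion report); the report lists one row
    per excluded subject with the mean d' that disqualified them.
    """
    mean_d = frame.groupby("subject")["d_prime"].mean()
    excluded = mean_d[mean_d < floor]
    report = excluded.rename("mean_d_prime").reset_index()
    kept = frame[~frame["subject"].isin(excluded.index)].reset_index(drop=True)
    return kept, report
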