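"""Fuzzy rule-based gait-phase detection (GPDA).

Five phases of the gait cycle are detected from normalized plantar-pressure
readings: loading response (LR), mid-stance (MSt), terminal stance (TSt),
pre-swing (PSw) and swing (Sw).  Each of the four FSR inputs is fuzzified by
a complementary pair of symmetric sigmoids ("low" and "high" sets), one rule
per phase combines the required input levels with the minimum T-norm, and the
phase with the maximum membership is taken as active at every sample.

Reference cycle
---------------
Detected phase durations are compared against the canonical partition of the
gait cycle — LR 10%, MSt 20%, TSt 20%, PSw 10%, Sw 40% of cycle time — with
each phase's expected duration obtained as ``pct / 100 * cycle_time`` from the
measured cycle's own total duration.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .acquisition import FSR_CHANNELS

__all__ = [
    "GaitPhase",
    "PHASE_LABELS",
    "PERRY_PERCENTAGES",
    "MembershipParams",
    "DEFAULT_MEMBERSHIP_PARAMS",
    "FuzzyRule",
    "DEFAULT_RULEBASE",
    "PhaseEvent",
    "membership_low",
    "membership_high",
    "minimum_tnorm",
    "rule_activation",
    "infer_phase_memberships",
    "evaluate_stream",
    "active_phases",
    "demarcate_phases",
    "reference_phase_duration",
    "segment_cycles",
    "phase_duration_differences",
]

logger = logging.getLogger(__name__)


class GaitPhase(enum.IntEnum):
    """The five detected phases, in canonical cycle order.

    The integer values double as the decimal digits of the phase-sequence
    feature downstream.
    """

    LR = 1
    MSt = 2
    TSt = 3
    PSw = 4
    Sw = 5


PHASE_LABELS = {p: p.name for p in GaitPhase}

#: Canonical share of the gait cycle occupied by each phase (percent).
PERRY_PERCENTAGES: Mapping[GaitPhase, float] = {
    GaitPhase.LR: 10.0,
    GaitPhase.MSt: 20.0,
    GaitPhase.TSt: 20.0,
    GaitPhase.PSw: 10.0,
    GaitPhase.Sw: 40.0,
}


@dataclass(frozen=True)
class MembershipParams:
    """Sigmoid shape for one input channel.

    ``inflection`` is the normalized reading at which both the low and the
    high grade equal 0.5 (kept at 0.5 to preserve symmetry of the domain);
    ``slope`` controls how sharply grades switch around it.  A steeper slope
    (50 instead of 15) is used on the toe channel because toe pressure during
    pre-swing is brief and its on/off transition is correspondingly sharp.
    """

    inflection: float = 0.5
    slope: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 < self.inflection < 1.0:
            raise ValueError(f"inflection must be in (0, 1), got {self.inflection}")
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")


DEFAULT_MEMBERSHIP_PARAMS: Mapping[str, MembershipParams] = {
    "fsr_heel": MembershipParams(),
    "fsr_5th": MembershipParams(),
    "fsr_1st": MembershipParams(),
    "fsr_toe": MembershipParams(slope=50.0),
}


def _check_domain(x: np.ndarray) -> None:
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("input outside [0, 1]; normalize the stream first")


def membership_low(x, params: MembershipParams = MembershipParams()):
    """Grade of membership in the "low" set: ``1 / (1 + exp(s (x - x0)))``."""
    arr = np.asarray(x, dtype=float)
    _check_domain(arr)
    grade = 1.0 / (1.0 + np.exp(params.slope * (arr - params.inflection)))
    return float(grade) if np.isscalar(x) else grade


def membership_high(x, params: MembershipParams = MembershipParams()):
    """Grade of membership in the "high" set, the complement of the low set."""
    low = membership_low(x, params)
    return 1.0 - low


def minimum_tnorm(grades: Iterable[float]) -> float:
    """Fuzzy conjunction of antecedent grades via the minimum T-norm."""
    values = [float(g) for g in grades]
    if not values:
        raise ValueError("minimum T-norm needs at least one antecedent grade")
    return min(values)


@dataclass(frozen=True)
class FuzzyRule:
    """One phase-detection rule: required level per channel, absent = don't care."""

    phase: GaitPhase
    antecedents: Mapping[str, str]  # channel -> "low" | "high"

    def __post_init__(self) -> None:
        if not self.antecedents:
            raise ValueError(f"rule for {self.phase.name} has no antecedents")
        bad = {lvl for lvl in self.antecedents.values() if lvl not in ("low", "high")}
        if bad:
            raise ValueError(f"invalid antecedent levels {bad} in {self.phase.name}")


#: One rule per phase; channels omitted from a rule are irrelevant for it.
DEFAULT_RULEBASE: tuple[FuzzyRule, ...] = (
    FuzzyRule(GaitPhase.LR, {"fsr_heel": "high", "fsr_5th": "low",
                             "fsr_1st": "low", "fsr_toe": "low"}),
    FuzzyRule(GaitPhase.MSt, {"fsr_heel": "high", "fsr_5th": "high"}),
    FuzzyRule(GaitPhase.TSt, {"fsr_heel": "low", "fsr_5th": "high",
                              "fsr_1st": "high"}),
    FuzzyRule(GaitPhase.PSw, {"fsr_heel": "low", "fsr_5th": "low",
                              "fsr_toe": "high"}),
    FuzzyRule(GaitPhase.Sw, {"fsr_heel": "low", "fsr_5th": "low",
                             "fsr_1st": "low", "fsr_toe": "low"}),
)


def rule_activation(
    rule: FuzzyRule,
    low_grades: Mapping[str, float],
    high_grades: Mapping[str, float],
) -> float:
    """Activation of one rule given precomputed low/high grades per channel.

    The rule's output membership is the minimum over its antecedent grades;
    don't-care channels do not participate.
    """
    grades = []
    for channel, level in rule.antecedents.items():
        table = low_grades if level == "low" else high_grades
        if channel not in table:
            raise KeyError(f"no {level} grade supplied for channel {channel!r}")
        grades.append(table[channel])
    return minimum_tnorm(grades)


def infer_phase_memberships(
    fsr_values: Mapping[str, float],
    rulebase: Sequence[FuzzyRule] = DEFAULT_RULEBASE,
    params: Mapping[str, MembershipParams] = DEFAULT_MEMBERSHIP_PARAMS,
) -> dict[GaitPhase, float]:
    """Fuzzify one normalized 4-channel reading and evaluate every rule."""
    low = {ch: membership_low(fsr_values[ch], params[ch]) for ch in FSR_CHANNELS}
    high = {ch: 1.0 - low[ch] for ch in FSR_CHANNELS}
    return {rule.phase: rule_activation(rule, low, high) for rule in rulebase}


def evaluate_stream(
    normalized: pd.DataFrame,
    side: str,
    rulebase: Sequence[FuzzyRule] = DEFAULT_RULEBASE,
    params: Mapping[str, MembershipParams] = DEFAULT_MEMBERSHIP_PARAMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate all rules over one foot's normalized stream, vectorized.

    Returns ``(timestamps, grades)`` with ``grades`` of shape (n, 5) in
    canonical phase order.
    """
    block = normalized[normalized["side"] == side]
    if len(block) == 0:
        raise ValueError(f"stream has no samples for side {side!r}")
    timestamps = block["timestamp"].to_numpy(dtype=float)
    low = {
        ch: membership_low(block[ch].to_numpy(dtype=float), params[ch])
        for ch in FSR_CHANNELS
    }
    high = {ch: 1.0 - low[ch] for ch in FSR_CHANNELS}
    grades = np.empty((len(block), len(rulebase)))
    for j, rule in enumerate(rulebase):
        cols = [
            (low if lvl == "low" else high)[ch]
            for ch, lvl in rule.antecedents.items()
        ]
        grades[:, j] = np.minimum.reduce(cols)
    return timestamps, grades


#: Grades within this distance of the per-sample maximum count as tied; a
#: knife-edge sample exactly on a pattern transition otherwise flips phase on
#: floating-point round-off alone.
TIE_TOLERANCE = 1e-9


def active_phases(grades: np.ndarray) -> np.ndarray:
    """Per-sample active phase by maximum membership.

    A tie (within ``TIE_TOLERANCE``) between the currently active phase and
    another phase retains the active one; any other tie resolves to the
    earliest phase in canonical order.  Returns integer phase values
    (GaitPhase).
    """
    phases = np.array([p.value for p in GaitPhase])
    idx = np.argmax(grades, axis=1)
    best = grades[np.arange(len(grades)), idx]
    out = np.empty(len(grades), dtype=int)
    prev = idx[0]
    for t in range(len(grades)):
        if grades[t, prev] >= best[t] - TIE_TOLERANCE:
            # previous phase still (jointly) maximal: keep it
            out[t] = phases[prev]
        else:
            prev = idx[t]
            out[t] = phases[prev]
    return out


@dataclass(frozen=True)
class PhaseEvent:
    """A maximal run of consecutive samples sharing one active phase."""

    phase: GaitPhase
    start: float
    end: float
    side: str = ""

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("event end must be after start")

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


def demarcate_phases(
    timestamps: np.ndarray,
    grades: np.ndarray,
    side: str = "",
    min_duration_ms: float = 0.0,
) -> list[PhaseEvent]:
    """Merge per-sample active phases into contiguous phase events.

    Each event spans from its first sample to the first sample of the next
    event; the last event is closed one nominal sample interval after its
    final sample.  ``min_duration_ms`` is an optional debounce: runs shorter
    than it are absorbed into the preceding event (0 disables, the default).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) == 0:
        raise ValueError("empty membership stream")
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    phases = active_phases(np.asarray(grades, dtype=float))
    dt = float(np.median(np.diff(timestamps))) if len(timestamps) > 1 else 0.02

    runs: list[tuple[int, float]] = []  # (phase value, start time)
    for t, ph in zip(timestamps, phases):
        if not runs or runs[-1][0] != ph:
            runs.append((int(ph), float(t)))
    bounds = [start for _, start in runs[1:]] + [float(timestamps[-1]) + dt]

    events: list[PhaseEvent] = []
    for (ph, start), end in zip(runs, bounds):
        if events and min_duration_ms > 0 and (end - start) * 1000.0 < min_duration_ms:
            prev = events.pop()
            events.append(PhaseEvent(prev.phase, prev.start, end, side))
        elif events and events[-1].phase == ph:
            prev = events.pop()
            events.append(PhaseEvent(prev.phase, prev.start, end, side))
        else:
            events.append(PhaseEvent(GaitPhase(ph), start, end, side))
    return events


def reference_phase_duration(phase_pct: float, cycle_time_ms: float) -> float:
    """Expected phase duration in ms: ``phase_pct / 100 * cycle_time_ms``."""
    if phase_pct < 0 or phase_pct > 100:
        raise ValueError(f"phase percentage must be in [0, 100], got {phase_pct}")
    if cycle_time_ms <= 0:
        raise ValueError(f"cycle time must be positive, got {cycle_time_ms}")
    return phase_pct / 100.0 * cycle_time_ms


def segment_cycles(events: Sequence[PhaseEvent]) -> list[list[PhaseEvent]]:
    """Group events into gait cycles, each starting at an LR onset.

    A cycle runs from one LR event up to (not including) the next LR event,
    or to the end of the recording.  Cycles missing any of the five phases
    are dropped with a logged warning (typically the truncated tail).
    """
    starts = [i for i, ev in enumerate(events) if ev.phase is GaitPhase.LR]
    cycles: list[list[PhaseEvent]] = []
    for n, i in enumerate(starts):
        j = starts[n + 1] if n + 1 < len(starts) else len(events)
        cycle = list(events[i:j])
        if {ev.phase for ev in cycle} == set(GaitPhase):
            cycles.append(cycle)
        else:
            logger.warning(
                "dropping incomplete cycle %d (phases %s)",
                n,
                sorted({ev.phase.name for ev in cycle}),
            )
    return cycles


def phase_duration_differences(
    events: Sequence[PhaseEvent],
    percentages: Mapping[GaitPhase, float] = PERRY_PERCENTAGES,
) -> dict[GaitPhase, float]:
    """Mean per-phase duration difference (ms) against the reference cycle.

    For every complete cycle the measured duration of each phase is compared
    with the reference duration derived from that cycle's own total length;
    positive values mean the detector over-estimates the phase.  Results are
    averaged across cycles.
    """
    cycles = segment_cycles(events)
    if not cycles:
        raise ValueError("no complete gait cycle in event sequence")
    diffs = {phase: [] for phase in GaitPhase}
    for cycle in cycles:
        total = sum(ev.duration_ms for ev in cycle)
        for phase in GaitPhase:
            measured = sum(ev.duration_ms for ev in cycle if ev.phase is phase)
            expected = reference_phase_duration(percentages[phase], total)
            diffs[phase].append(measured - expected)
    return {phase: float(np.mean(vals)) for phase, vals in diffs.items()}


def events_to_frame(events: Sequence[PhaseEvent]) -> pd.DataFrame:
    """Tabulate phase events as (phase, start, end, duration_ms, side)."""
    return pd.DataFrame(
        {
            "phase": [ev.phase.name for ev in events],
            "start": [ev.start for ev in events],
            "end": [ev.end for ev in events],
            "duration_ms": [ev.duration_ms for ev in events],
            "side": [ev.side for ev in events],
        }
    )
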