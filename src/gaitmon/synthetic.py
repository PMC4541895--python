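"""Synthetic insole-signal generator for all eight foot-movement patterns.

The simulator replaces live subjects: it emits bilateral 50 Hz streams in
the acquisition layer's format, with known sensor ranges, ground-truth gait
phases for walking, and an activity label per stream.

Walking traces follow the canonical phase schedule (LR 10%, MSt 20%, TSt
20%, PSw 10%, Sw 40% of cycle time).  Within each cycle the four pressure
channels trace the expected stance patterns — heel loaded through LR/MSt,
fifth metatarsal through MSt/TSt, first metatarsal in TSt, toe in PSw, all
unloaded in swing — with raised-cosine ramps between patterns so transitions
stay soft and continuous, and the two feet offset by half a cycle.  The
seven non-walking patterns each carry a distinct documented signature (see
each builder's docstring); all class-conditional feature distributions are
roughly Gaussian, as the downstream classifier assumes.

Generated pressure levels (including noise) are clipped to [0, 1] before
being mapped onto each sensor's voltage range, so every raw reading lies
inside the simulated sensor's calibrated [min, max] and normalization
round-trips exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .acquisition import (
    ACCEL_CHANNELS,
    FSR_CHANNELS,
    SIDES,
    STREAM_COLUMNS,
    CalibrationProfile,
)
from .features import BUFFER_SIZE, extract_features_batch
from .fuzzy import (
    DEFAULT_MEMBERSHIP_PARAMS,
    DEFAULT_RULEBASE,
    PERRY_PERCENTAGES,
    GaitPhase,
    active_phases,
    evaluate_stream,
)
from .gnb import ACTIVITIES

__all__ = [
    "GaitSimParams",
    "LabeledStream",
    "FeatureDataset",
    "SENSOR_RANGES",
    "sensor_profile",
    "simulate_walk_forward",
    "simulate_activity",
    "simulate_calibration",
    "build_training_corpus",
]

#: True effective voltage range of every simulated FSR: unloaded sensors sit
#: slightly above zero from foot contact, loaded ones a little below the
#: 3.3 V rail, and ranges differ sensor to sensor.
SENSOR_RANGES: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "left": {
        "fsr_heel": (0.60, 2.90),
        "fsr_5th": (0.55, 2.80),
        "fsr_1st": (0.58, 2.85),
        "fsr_toe": (0.50, 3.00),
    },
    "right": {
        "fsr_heel": (0.62, 2.95),
        "fsr_5th": (0.53, 2.78),
        "fsr_1st": (0.57, 2.88),
        "fsr_toe": (0.52, 2.96),
    },
}


def sensor_profile() -> CalibrationProfile:
    """Calibration profile holding the simulator's exact sensor ranges."""
    return CalibrationProfile.from_ranges(SENSOR_RANGES)


@dataclass(frozen=True)
class GaitSimParams:
    """Study conditions for the simulator.

    ``cadence_spm`` is steps per minute; the default 100 gives a 1.2 s
    stride (cycle) time, a typical adult walking pace.  ``noise_sd`` is the
    Gaussian noise level as a fraction of each sensor's range (and in g for
    the accelerations).  ``transition_ramp_ms`` is the raised-cosine ramp
    spanning each pressure-pattern transition.
    """

    cadence_spm: float = 100.0
    noise_sd: float = 0.05
    transition_ramp_ms: float = 60.0
    schedule: Mapping[GaitPhase, float] = field(
        default_factory=lambda: dict(PERRY_PERCENTAGES)
    )
    fs: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        total = sum(self.schedule.values())
        if not math.isclose(total, 100.0):
            raise ValueError(f"phase schedule must sum to 100, got {total}")

    @property
    def cycle_time_s(self) -> float:
        """Stride time in seconds (two steps per stride)."""
        return 120.0 / self.cadence_spm


@dataclass(frozen=True)
class LabeledStream:
    """A simulated bilateral recording with ground-truth labels.

    ``data`` maps (side, channel) to the raw signal array; all channels share
    ``timestamps``.  ``gt_phases`` holds the per-side scheduled gait phase for
    walking activities (None otherwise).
    """

    timestamps: np.ndarray
    data: Mapping[tuple[str, str], np.ndarray]
    activity: str
    seed: int
    gt_phases: Mapping[str, np.ndarray] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def frame(self) -> pd.DataFrame:
        """Long-format stream (one row per timestamp and side)."""
        parts = []
        for side in SIDES:
            part = {"timestamp": self.timestamps, "side": side}
            for ch in FSR_CHANNELS + ACCEL_CHANNELS:
                part[ch] = self.data[(side, ch)]
            parts.append(pd.DataFrame(part))
        out = pd.concat(parts, ignore_index=True)
        return (
            out.sort_values(["timestamp", "side"], kind="stable")
            .reset_index(drop=True)[list(STREAM_COLUMNS)]
        )

    def labels_frame(self) -> pd.DataFrame:
        """Per-sample ground-truth labels (activity, and phase if walking)."""
        rows = []
        for side in SIDES:
            phases = (
                [GaitPhase(p).name for p in self.gt_phases[side]]
                if self.gt_phases is not None
                else [""] * self.n_samples
            )
            rows.append(
                pd.DataFrame(
                    {
                        "timestamp": self.timestamps,
                        "side": side,
                        "activity": self.activity,
                        "phase": phases,
                    }
                )
            )
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["timestamp", "side"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Walking-gait envelope
# ---------------------------------------------------------------------------

#: Ideal pressure level per phase (rows, canonical order) and channel
#: (heel, 5th, 1st, toe).  Don't-care channels in the rule base are held low
#: so every phase presents an unambiguous pattern.
_PHASE_LEVELS = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],  # LR
        [1.0, 1.0, 0.0, 0.0],  # MSt
        [0.0, 1.0, 1.0, 0.0],  # TSt
        [0.0, 0.0, 0.0, 1.0],  # PSw
        [0.0, 0.0, 0.0, 0.0],  # Sw
    ]
)


def _phase_boundaries(schedule: Mapping[GaitPhase, float]) -> np.ndarray:
    fracs = np.array([schedule[p] for p in GaitPhase]) / 100.0
    return np.concatenate([[0.0], np.cumsum(fracs)])


def _scheduled_phase(frac: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Ground-truth phase value per sample from the cycle fraction."""
    idx = np.clip(np.searchsorted(bounds, frac, side="right") - 1, 0, 4)
    return idx + 1  # GaitPhase values are 1..5


def _ramped_levels(
    frac: np.ndarray, levels: np.ndarray, bounds: np.ndarray, ramp_frac: float
) -> np.ndarray:
    """Piecewise-constant per-phase levels with raised-cosine transitions.

    Each transition spans [boundary - ramp/2, boundary + ramp/2] in cycle
    fraction; at the boundary itself every changing channel sits at the
    midpoint of its old and new level.
    """
    seg = np.diff(bounds)
    if ramp_frac >= seg.min():
        raise ValueError(
            "transition ramp longer than the shortest phase segment; "
            "increase cycle time or shorten the ramp"
        )
    p = np.clip(np.searchsorted(bounds, frac, side="right") - 1, 0, 4)
    cur = levels[p]
    prev = levels[(p - 1) % 5]
    nxt = levels[(p + 1) % 5]
    dprev = frac - bounds[p]
    dnext = bounds[p + 1] - frac
    half = ramp_frac / 2.0
    out = cur.copy()
    m = dprev < half
    s = 0.5 + dprev[m] / ramp_frac
    w = 0.5 * (1.0 - np.cos(np.pi * s))
    out[m] = prev[m] + (cur[m] - prev[m]) * w
    m2 = (dnext < half) & ~m
    s2 = 0.5 - dnext[m2] / ramp_frac
    w2 = 0.5 * (1.0 - np.cos(np.pi * s2))
    out[m2] = cur[m2] + (nxt[m2] - cur[m2]) * w2
    return out


def _emit(
    timestamps: np.ndarray,
    levels: Mapping[tuple[str, str], np.ndarray],
    accels: Mapping[tuple[str, str], np.ndarray],
    activity: str,
    seed: int,
    noise_sd: float,
    gt_phases: Mapping[str, np.ndarray] | None,
    rng: np.random.Generator,
) -> LabeledStream:
    """Map pressure levels onto sensor voltages, add noise, package a stream."""
    data: dict[tuple[str, str], np.ndarray] = {}
    for side in SIDES:
        for ch in FSR_CHANNELS:
            lo, hi = SENSOR_RANGES[side][ch]
            level = levels[(side, ch)]
            if noise_sd > 0:
                level = level + rng.normal(0.0, noise_sd, size=level.shape)
            level = np.clip(level, 0.0, 1.0)
            data[(side, ch)] = lo + (hi - lo) * level
        for ch in ACCEL_CHANNELS:
            sig = accels[(side, ch)]
            if noise_sd > 0:
                sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
            data[(side, ch)] = sig
    return LabeledStream(
        timestamps=timestamps,
        data=data,
        activity=activity,
        seed=seed,
        gt_phases=gt_phases,
    )


def _walk_stream(
    n_samples: int,
    params: GaitSimParams,
    activity: str,
    backwards: bool = False,
) -> LabeledStream:
    """Shared engine for forward and backward walking.

    Backward gait plays the pressure schedule in reverse temporal order
    (toe-to-heel progression), is 15% slower, and is forefoot-led: heel
    contact is softer and toe/first-metatarsal contact fuller than in
    forward gait.
    """
    rng = np.random.default_rng(params.seed)
    T = params.cycle_time_s * (1.0 / 0.85 if backwards else 1.0)
    t = np.arange(n_samples) / params.fs
    bounds = _phase_boundaries(params.schedule)
    ramp_frac = params.transition_ramp_ms / 1000.0 / T
    channel_amp = (
        {"fsr_heel": 0.65, "fsr_5th": 0.9, "fsr_1st": 1.0, "fsr_toe": 1.0}
        if backwards
        else {"fsr_heel": 1.0, "fsr_5th": 1.0, "fsr_1st": 1.0, "fsr_toe": 1.0}
    )
    ap_amp = 0.25 if backwards else 0.35
    levels: dict[tuple[str, str], np.ndarray] = {}
    accels: dict[tuple[str, str], np.ndarray] = {}
    gt: dict[str, np.ndarray] = {}
    for side, offset in (("left", 0.0), ("right", 0.5)):
        frac = (t / T + offset) % 1.0
        if backwards:
            frac = (1.0 - frac) % 1.0
        for j, ch in enumerate(FSR_CHANNELS):
            levels[(side, ch)] = channel_amp[ch] * _ramped_levels(
                frac, _PHASE_LEVELS[:, j], bounds, ramp_frac
            )
        phase_frac = t / T + offset
        accels[(side, "accel_ap")] = ap_amp * np.sin(
            2 * np.pi * phase_frac
        ) + 0.15 * np.sin(4 * np.pi * phase_frac + 0.6)
        accels[(side, "accel_v")] = 0.45 * np.sin(4 * np.pi * phase_frac + 0.3)
        gt[side] = _scheduled_phase(frac, bounds)
    return _emit(t, levels, accels, activity, params.seed, params.noise_sd, gt, rng)


def simulate_walk_forward(
    params: GaitSimParams | None = None, n_cycles: int = 10
) -> LabeledStream:
    """Simulate ``n_cycles`` strides of forward walking with phase labels."""
    params = params or GaitSimParams()
    n = int(round(n_cycles * params.cycle_time_s * params.fs))
    if n < 1:
        raise ValueError("requested walk is shorter than one sample")
    return _walk_stream(n, params, "walking_forward")


# ---------------------------------------------------------------------------
# Non-walking activity signatures
# ---------------------------------------------------------------------------

def _pulse(frac: np.ndarray, duty: float) -> np.ndarray:
    """A raised-cosine pressure bump occupying the first ``duty`` of a cycle."""
    out = np.zeros_like(frac)
    m = frac < duty
    out[m] = 0.5 * (1.0 - np.cos(2 * np.pi * frac[m] / duty))
    return out


def _sit_stand_profile(frac: np.ndarray, rising: bool) -> np.ndarray:
    """Monotone transfer between loaded (0.85) and unloaded (0.08) pressure.

    The transition occupies cycle fractions 0.15-0.45; sitting down decays
    (weight moves onto the chair, most of the cycle is spent unloaded) and
    standing up rises (most of the cycle is spent fully loaded).
    """
    lo, hi = 0.08, 0.85
    start, end = (lo, hi) if rising else (hi, lo)
    out = np.full_like(frac, start)
    m = (frac >= 0.15) & (frac < 0.45)
    s = (frac[m] - 0.15) / 0.30
    out[m] = start + (end - start) * 0.5 * (1.0 - np.cos(np.pi * s))
    out[frac >= 0.45] = end
    return out


def _oscillatory_stream(
    n_samples: int,
    params: GaitSimParams,
    activity: str,
    period_s: float,
    channel_amp: Mapping[str, float],
    duty: float,
    side_amp: Mapping[str, float],
    ap_amp: Mapping[str, float],
    v_amp: Mapping[str, float],
) -> LabeledStream:
    """Shared engine for lateral stepping and turning patterns."""
    rng = np.random.default_rng(params.seed)
    t = np.arange(n_samples) / params.fs
    levels: dict[tuple[str, str], np.ndarray] = {}
    accels: dict[tuple[str, str], np.ndarray] = {}
    for side, offset in (("left", 0.0), ("right", 0.5)):
        frac = (t / period_s + offset) % 1.0
        pulse = _pulse(frac, duty)
        for ch in FSR_CHANNELS:
            levels[(side, ch)] = side_amp[side] * channel_amp[ch] * pulse
        accels[(side, "accel_ap")] = ap_amp[side] * np.sin(
            2 * np.pi * (t / period_s + offset)
        )
        accels[(side, "accel_v")] = v_amp[side] * np.sin(
            4 * np.pi * (t / period_s + offset) + 0.4
        )
    return _emit(t, levels, accels, activity, params.seed, params.noise_sd, None, rng)


def _sit_stand_stream(
    n_samples: int, params: GaitSimParams, activity: str, rising: bool
) -> LabeledStream:
    """Sit-down / stand-up events repeated every 3 s.

    All four sensors load or unload together; a vertical-acceleration burst
    accompanies each weight transfer.  The two activities differ in where
    the cycle dwells: sitting down is mostly unloaded, standing up mostly
    loaded, which separates their time-domain pressure statistics.
    """
    rng = np.random.default_rng(params.seed)
    period_s = 3.0
    t = np.arange(n_samples) / params.fs
    levels: dict[tuple[str, str], np.ndarray] = {}
    accels: dict[tuple[str, str], np.ndarray] = {}
    for side in SIDES:
        frac = (t / period_s) % 1.0
        profile = _sit_stand_profile(frac, rising)
        for ch in FSR_CHANNELS:
            levels[(side, ch)] = profile
        burst = np.zeros_like(frac)
        m = (frac >= 0.15) & (frac < 0.45)
        burst[m] = np.sin(np.pi * (frac[m] - 0.15) / 0.30)
        accels[(side, "accel_v")] = (0.4 if rising else -0.4) * burst
        accels[(side, "accel_ap")] = 0.08 * np.sin(2 * np.pi * t / period_s)
    return _emit(t, levels, accels, activity, params.seed, params.noise_sd, None, rng)


def _simulate_n(kind: str, n_samples: int, params: GaitSimParams) -> LabeledStream:
    if kind == "walking_forward":
        return _walk_stream(n_samples, params, kind)
    if kind == "walking_backwards":
        return _walk_stream(n_samples, params, kind, backwards=True)
    if kind in ("lateral_left", "lateral_right"):
        lead = "left" if kind == "lateral_left" else "right"
        trail = "right" if lead == "left" else "left"
        return _oscillatory_stream(
            n_samples,
            params,
            kind,
            period_s=0.85,
            channel_amp={"fsr_heel": 0.9, "fsr_5th": 0.9, "fsr_1st": 0.9,
                         "fsr_toe": 0.7},
            duty=0.55,
            side_amp={lead: 1.0, trail: 0.55},
            ap_amp={"left": 0.10, "right": 0.10},
            v_amp={lead: 0.5, trail: 0.35},
        )
    if kind in ("turning_left", "turning_right"):
        inner = "left" if kind == "turning_left" else "right"
        outer = "right" if inner == "left" else "left"
        return _oscillatory_stream(
            n_samples,
            params,
            kind,
            period_s=2.0,
            channel_amp={"fsr_heel": 0.2, "fsr_5th": 0.75, "fsr_1st": 0.95,
                         "fsr_toe": 0.55},
            duty=0.7,
            side_amp={inner: 1.0, outer: 0.6},
            ap_amp={inner: 0.15, outer: 0.40},
            v_amp={"left": 0.3, "right": 0.3},
        )
    if kind == "sitting_down":
        return _sit_stand_stream(n_samples, params, kind, rising=False)
    if kind == "standing_up":
        return _sit_stand_stream(n_samples, params, kind, rising=True)
    raise ValueError(f"unknown activity kind {kind!r}; expected one of {ACTIVITIES}")


def simulate_activity(
    kind: str,
    duration_s: float = 30.0,
    params: GaitSimParams | None = None,
) -> LabeledStream:
    """Simulate one of the eight foot-movement patterns for ``duration_s``.

    Activity signatures, briefly: forward walking follows the phase
    schedule heel-to-toe; backward walking reverses it toe-to-heel (and is
    slower and forefoot-led); lateral stepping loads the whole foot at once
    at ~1.2 Hz with the leading side heavier and reduced antero-posterior
    acceleration; turning is a slow (0.5 Hz) forefoot-weighted sway with the
    inner foot loaded and the outer leg swinging harder; sitting down and
    standing up are repeated monotone weight transfers dwelling unloaded and
    loaded respectively.
    """
    params = params or GaitSimParams()
    n = int(round(duration_s * params.fs))
    if n < 1:
        raise ValueError("duration shorter than one sample")
    return _simulate_n(kind, n, params)


def simulate_calibration(
    n_readings: int = 200, seed: int = 0, jitter: float = 0.02
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the two-stage calibration recordings (unloaded, loaded).

    Readings jitter around each sensor's true range endpoints and are kept
    non-negative.  Returns two streams suitable for :func:`gaitmon.acquisition.calibrate`.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_readings) / 50.0
    frames = []
    for endpoint in (0, 1):
        parts = []
        for side in SIDES:
            part = {"timestamp": t, "side": side}
            for ch in FSR_CHANNELS:
                center = SENSOR_RANGES[side][ch][endpoint]
                part[ch] = np.clip(
                    center + rng.normal(0.0, jitter, n_readings), 0.0, None
                )
            for ch in ACCEL_CHANNELS:
                part[ch] = rng.normal(0.0, jitter, n_readings)
            parts.append(pd.DataFrame(part))
        frame = pd.concat(parts, ignore_index=True)
        frames.append(
            frame.sort_values(["timestamp", "side"], kind="stable")
            .reset_index(drop=True)[list(STREAM_COLUMNS)]
        )
    return frames[0], frames[1]


# ---------------------------------------------------------------------------
# Training corpus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDataset:
    """A labeled feature matrix (n samples x 37 features)."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.feature_names))
        frame["label"] = self.labels
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureDataset":
        labels = frame["label"].to_numpy()
        X = frame.drop(columns=["label"]).to_numpy(dtype=float)
        return cls(X, labels, tuple(c for c in frame.columns if c != "label"))


def stream_features(
    stream: LabeledStream,
    profile: CalibrationProfile | None = None,
) -> np.ndarray:
    """Run the full front end over one stream and return its feature matrix.

    Normalizes the raw pressures, runs the fuzzy phase detector on each
    foot, and feeds signals plus detected phases to the feature extractor.
    """
    from .acquisition import normalize  # local to avoid cycle at import time

    profile = profile or sensor_profile()
    frame = normalize(stream.frame, profile)
    phases = {}
    channels: dict[tuple[str, str], np.ndarray] = {}
    for side in SIDES:
        _, grades = evaluate_stream(frame, side, DEFAULT_RULEBASE,
                                    DEFAULT_MEMBERSHIP_PARAMS)
        phases[side] = active_phases(grades)
        block = frame[frame["side"] == side]
        for ch in FSR_CHANNELS + ACCEL_CHANNELS:
            channels[(side, ch)] = block[ch].to_numpy(dtype=float)
    return extract_features_batch(channels, phases["left"], phases["right"])


def build_training_corpus(
    n_per_class: int = 1200,
    params: GaitSimParams | None = None,
    seed: int = 0,
) -> FeatureDataset:
    """Build the labeled training corpus: ``n_per_class`` vectors per activity.

    Each activity stream is long enough to fill the 128-sample warm-up plus
    ``n_per_class`` emitted vectors; every stream gets its own deterministic
    child seed, so the corpus is bit-for-bit reproducible from ``seed``.
    """
    from .features import FEATURE_NAMES

    params = params or GaitSimParams()
    n_samples = n_per_class + BUFFER_SIZE - 1
    blocks, labels = [], []
    for k, kind in enumerate(ACTIVITIES):
        child = (seed + 7919 * (k + 1)) % (2**31)
        stream = _simulate_n(kind, n_samples, replace(params, seed=child))
        X = stream_features(stream)[:n_per_class]
        blocks.append(X)
        labels.extend([kind] * len(X))
    return FeatureDataset(
        X=np.vstack(blocks),
        labels=np.asarray(labels, dtype=object),
        feature_names=FEATURE_NAMES,
    )
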