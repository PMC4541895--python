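"""Ingestion, smoothing, calibration and normalization of insole sample streams.

A *stream* is a tidy table with one row per (timestamp, side) sample carrying
four force-sensitive-resistor (FSR) readings and the antero-posterior and
vertical accelerations, sampled nominally at 50 Hz per foot.  Raw FSR readings
are in whatever unit the acquisition front-end produces (volts here); the
calibration procedure estimates each sensor's effective range [min, max] from
an unloaded and a fully loaded recording, and normalization maps readings into
[0, 1] so the fuzzy membership functions see a common domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "FSR_CHANNELS",
    "ACCEL_CHANNELS",
    "SIGNAL_CHANNELS",
    "SIDES",
    "STREAM_COLUMNS",
    "QUANTILE_METHOD",
    "StreamFormatError",
    "CorruptSampleError",
    "CalibrationError",
    "ChannelRange",
    "CalibrationProfile",
    "read_stream",
    "write_stream",
    "validate_stream",
    "low_pass_filter",
    "first_quartile",
    "estimate_effective_range",
    "calibrate",
    "normalize",
]

FSR_CHANNELS = ("fsr_heel", "fsr_5th", "fsr_1st", "fsr_toe")
ACCEL_CHANNELS = ("accel_ap", "accel_v")
SIGNAL_CHANNELS = FSR_CHANNELS + ACCEL_CHANNELS
SIDES = ("left", "right")
STREAM_COLUMNS = ("timestamp", "side") + SIGNAL_CHANNELS

#: Quantile convention used throughout calibration: linear interpolation
#: between order statistics (numpy's default, the classic "type 7" scheme).
QUANTILE_METHOD = "linear"


class StreamFormatError(ValueError):
    """A sample stream violates the layout or ordering contract."""


class CorruptSampleError(ValueError):
    """A sample carries a physically implausible (negative) FSR reading."""


class CalibrationError(ValueError):
    """A sensor's estimated effective range is degenerate (min >= max)."""


# ---------------------------------------------------------------------------
# Stream I/O
# ---------------------------------------------------------------------------

def read_stream(path: str | Path) -> pd.DataFrame:
    """Read a sample stream from CSV (header mandatory) or JSON-lines.

    The format is chosen by file extension: ``.csv`` for CSV, anything else
    is treated as JSON-lines with one record per line.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path)
    else:
        frame = pd.read_json(path, lines=True)
    validate_stream(frame)
    return frame[list(STREAM_COLUMNS)]


def write_stream(stream: pd.DataFrame, path: str | Path) -> None:
    """Write a stream to CSV or JSON-lines depending on the extension."""
    path = Path(path)
    frame = stream[list(STREAM_COLUMNS)]
    if path.suffix.lower() == ".csv":
        frame.to_csv(path, index=False)
    else:
        frame.to_json(path, orient="records", lines=True)


def validate_stream(stream: pd.DataFrame) -> None:
    """Check layout, per-side timestamp ordering and reading plausibility.

    Raises
    ------
    StreamFormatError
        Missing columns, unknown side labels or non-increasing timestamps.
    CorruptSampleError
        Negative FSR readings; these are rejected rather than clamped.
    """
    missing = set(STREAM_COLUMNS) - set(stream.columns)
    if missing:
        raise StreamFormatError(f"stream is missing columns: {sorted(missing)}")
    if len(stream) == 0:
        raise StreamFormatError("stream is empty")
    unknown = set(stream["side"].unique()) - set(SIDES)
    if unknown:
        raise StreamFormatError(f"unknown side labels: {sorted(unknown)}")
    for side, group in stream.groupby("side"):
        ts = group["timestamp"].to_numpy(dtype=float)
        if np.any(np.diff(ts) <= 0):
            raise StreamFormatError(
                f"timestamps not strictly increasing for side {side!r}"
            )
    fsr = stream[list(FSR_CHANNELS)].to_numpy(dtype=float)
    if np.any(fsr < 0):
        raise CorruptSampleError("negative FSR reading in stream")


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def low_pass_filter(stream: pd.DataFrame, coefficient: float = 0.3) -> pd.DataFrame:
    """Smooth every sensor channel with a single-pole exponential moving average.

    ``y[0] = x[0]`` and ``y[t] = a*x[t] + (1-a)*y[t-1]`` with smoothing
    coefficient ``a``; each side's channels are filtered independently so the
    two feet never mix.  ``a = 1`` reproduces the input exactly.  The output is
    always a convex combination of past inputs, so it stays inside the input's
    [min, max] envelope.

    Parameters
    ----------
    stream:
        Sample stream (validated layout).
    coefficient:
        Smoothing coefficient in (0, 1]; smaller is smoother.
    """
    if not 0.0 < coefficient <= 1.0:
        raise ValueError(f"smoothing coefficient must be in (0, 1], got {coefficient}")
    validate_stream(stream)
    out = stream.copy()
    a = float(coefficient)
    for _, idx in stream.groupby("side").groups.items():
        block = stream.loc[idx, list(SIGNAL_CHANNELS)].to_numpy(dtype=float)
        # y[t] = a x[t] + (1-a) y[t-1]; zi chosen so that y[0] == x[0]
        zi = (1.0 - a) * block[0]
        smoothed, _ = lfilter([a], [1.0, -(1.0 - a)], block, axis=0, zi=zi[None, :])
        out.loc[idx, list(SIGNAL_CHANNELS)] = smoothed
    return out


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def first_quartile(readings: Iterable[float]) -> float:
    """First quartile under the package-wide linear-interpolation convention."""
    arr = np.asarray(list(readings), dtype=float)
    if arr.size < 4:
        raise ValueError(f"need at least 4 readings, got {arr.size}")
    return float(np.quantile(arr, 0.25, method=QUANTILE_METHOD))


@dataclass(frozen=True)
class ChannelRange:
    """Effective range [min, max] of one FSR sensor."""

    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise CalibrationError(
                f"degenerate effective range: min {self.min} >= max {self.max}"
            )

    @property
    def span(self) -> float:
        return self.max - self.min


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-side, per-channel effective FSR ranges used for normalization."""

    ranges: Mapping[str, Mapping[str, ChannelRange]]

    def channel(self, side: str, channel: str) -> ChannelRange:
        try:
            return self.ranges[side][channel]
        except KeyError as exc:
            raise KeyError(f"profile has no entry for {side}/{channel}") from exc

    def to_json(self, path: str | Path) -> None:
        doc = {
            side: {ch: {"min": r.min, "max": r.max} for ch, r in chans.items()}
            for side, chans in self.ranges.items()
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationProfile":
        doc = json.loads(Path(path).read_text())
        return cls(
            {
                side: {ch: ChannelRange(v["min"], v["max"]) for ch, v in chans.items()}
                for side, chans in doc.items()
            }
        )

    @classmethod
    def from_ranges(
        cls, ranges: Mapping[str, Mapping[str, tuple[float, float]]]
    ) -> "CalibrationProfile":
        return cls(
            {
                side: {ch: ChannelRange(lo, hi) for ch, (lo, hi) in chans.items()}
                for side, chans in ranges.items()
            }
        )


def estimate_effective_range(
    unloaded_readings: Iterable[float],
    loaded_readings: Iterable[float],
    channel: str = "",
) -> ChannelRange:
    """Estimate one sensor's effective range from the two calibration stages.

    The unloaded stage (foot in the air) and loaded stage (full body weight)
    recordings are each reduced to their first quartile; the unloaded quartile
    becomes the range minimum and the loaded quartile the maximum.  Taking a
    low quantile at both stages discards transient spikes at the start of each
    recording.

    Raises
    ------
    CalibrationError
        If the estimated minimum is not below the maximum (stuck or
        disconnected sensor); the message names the channel.
    """
    lo = first_quartile(unloaded_readings)
    hi = first_quartile(loaded_readings)
    if not lo < hi:
        label = channel or "channel"
        raise CalibrationError(
            f"calibration failed for {label}: unloaded Q1 {lo} >= loaded Q1 {hi}"
        )
    return ChannelRange(lo, hi)


def calibrate(
    unloaded: pd.DataFrame, loaded: pd.DataFrame
) -> CalibrationProfile:
    """Build a CalibrationProfile from unloaded and loaded recordings.

    Both arguments are sample streams; every (side, FSR channel) pair present
    in the unloaded stream must be present in the loaded one.
    """
    validate_stream(unloaded)
    validate_stream(loaded)
    ranges: dict[str, dict[str, ChannelRange]] = {}
    for side in SIDES:
        un = unloaded[unloaded["side"] == side]
        lo = loaded[loaded["side"] == side]
        if len(un) == 0 or len(lo) == 0:
            continue
        ranges[side] = {
            ch: estimate_effective_range(un[ch], lo[ch], channel=f"{side}/{ch}")
            for ch in FSR_CHANNELS
        }
    if not ranges:
        raise CalibrationError("no common sides in calibration recordings")
    return CalibrationProfile(ranges)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(stream: pd.DataFrame, profile: CalibrationProfile) -> pd.DataFrame:
    """Map every FSR reading into [0, 1] using the calibrated effective range.

    Each reading x becomes ``(x - min) / (max - min)`` clamped to [0, 1];
    readings saturating beyond the calibrated range therefore pin at the
    bounds instead of escaping the membership functions' domain.
    Accelerations pass through unchanged.
    """
    validate_stream(stream)
    out = stream.copy()
    for side in out["side"].unique():
        mask = out["side"] == side
        for ch in FSR_CHANNELS:
            rng = profile.channel(str(side), ch)
            x = out.loc[mask, ch].to_numpy(dtype=float)
            out.loc[mask, ch] = np.clip((x - rng.min) / rng.span, 0.0, 1.0)
    return out
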