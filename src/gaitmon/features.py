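"""Per-sample feature extraction over 128-sample ring buffers.

Twelve signal buffers are maintained — the eight FSR channels (four per
insole) and the antero-posterior and vertical accelerations of each insole.
Once every buffer holds 128 values (~2.56 s at 50 Hz) a 37-dimensional
feature vector is emitted for each incoming sample:

* features 1-3 per buffer: time-domain mean, root-mean-square, and the
  dominant non-DC frequency of the 128-point FFT magnitude spectrum (Hz);
* feature 4, computed once per sample: the gait-phase-sequence code, the
  last four *activated* phases of one foot concatenated as decimal digits
  (LR=1, MSt=2, TSt=3, PSw=4, Sw=5; fewer than four activations leave
  leading zeros).

The fixed feature order is: left FSRs (heel, 5th, 1st, toe), right FSRs,
left accelerations (AP, vertical), right accelerations — three features
each — with the phase-sequence code last.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .acquisition import ACCEL_CHANNELS, FSR_CHANNELS
from .fuzzy import GaitPhase

__all__ = [
    "BUFFER_SIZE",
    "SAMPLE_RATE_HZ",
    "N_FEATURES",
    "BUFFER_ORDER",
    "FEATURE_NAMES",
    "spectral_magnitudes",
    "dominant_frequency",
    "buffer_features",
    "phase_sequence_code",
    "FeatureExtractor",
    "extract_features_batch",
]

BUFFER_SIZE = 128
SAMPLE_RATE_HZ = 50.0
N_FEATURES = 37

#: (side, channel) pairs in canonical buffer order.
BUFFER_ORDER: tuple[tuple[str, str], ...] = tuple(
    [("left", ch) for ch in FSR_CHANNELS]
    + [("right", ch) for ch in FSR_CHANNELS]
    + [("left", ch) for ch in ACCEL_CHANNELS]
    + [("right", ch) for ch in ACCEL_CHANNELS]
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{side}_{ch}_{stat}" for side, ch in BUFFER_ORDER for stat in ("mean", "rms", "domfreq")
) + ("phase_sequence_code",)

_PEAK_TOLERANCE = 1e-12


def spectral_magnitudes(buffer: np.ndarray) -> np.ndarray:
    """One-sided FFT magnitude spectrum of a full buffer (bins 0..64).

    Bin width is 50/128 Hz; no window is applied before the transform.
    """
    arr = np.asarray(buffer, dtype=float)
    if arr.shape != (BUFFER_SIZE,):
        raise ValueError(f"buffer must hold exactly {BUFFER_SIZE} values")
    return np.abs(np.fft.rfft(arr))


def dominant_frequency(buffer: np.ndarray, fs: float = SAMPLE_RATE_HZ) -> float:
    """Frequency (Hz) of the strongest non-DC spectral bin; 0 if spectrum is flat zero."""
    mags = spectral_magnitudes(buffer)[1:]
    if mags.max() <= _PEAK_TOLERANCE:
        return 0.0
    return float((int(np.argmax(mags)) + 1) * fs / BUFFER_SIZE)


def buffer_features(buffer: np.ndarray, fs: float = SAMPLE_RATE_HZ) -> tuple[float, float, float]:
    """Features 1-3 of one buffer: mean, RMS, dominant non-DC frequency."""
    arr = np.asarray(buffer, dtype=float)
    if arr.shape != (BUFFER_SIZE,):
        raise ValueError(f"buffer must hold exactly {BUFFER_SIZE} values")
    mean = float(arr.mean())
    rms = float(np.sqrt(np.mean(arr**2)))
    return mean, rms, dominant_frequency(arr, fs)


def phase_sequence_code(phases: Sequence[GaitPhase]) -> int:
    """Decimal concatenation of up to four activated phases, oldest first.

    An empty buffer codes to 0; with fewer than four activations the missing
    leading digits are implicitly zero, so the code always lies in [0, 5555].
    """
    if len(phases) > 4:
        raise ValueError("phase-sequence buffer holds at most 4 activations")
    code = 0
    for phase in phases:
        code = code * 10 + int(phase)
    return code


@dataclass
class FeatureExtractor:
    """Streaming 37-feature extractor over bilateral normalized samples.

    ``update`` consumes one bilateral sample (per-side channel values plus
    the per-side active gait phase) and returns the feature vector once all
    buffers are full, or ``None`` during the 127-sample warm-up.  The
    phase-sequence buffer records *activations* — appended only when the
    tracked foot's active phase changes — and feeds feature 4.
    """

    sequence_foot: str = "left"
    fs: float = SAMPLE_RATE_HZ
    _buffers: dict = field(default_factory=dict, repr=False)
    _phase_buffer: deque = field(default_factory=lambda: deque(maxlen=4), repr=False)
    _last_phase: GaitPhase | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.sequence_foot not in ("left", "right"):
            raise ValueError("sequence_foot must be 'left' or 'right'")
        self._buffers = {key: deque(maxlen=BUFFER_SIZE) for key in BUFFER_ORDER}

    @property
    def warmed_up(self) -> bool:
        return all(len(buf) == BUFFER_SIZE for buf in self._buffers.values())

    def update(
        self,
        left: Mapping[str, float],
        right: Mapping[str, float],
        left_phase: GaitPhase,
        right_phase: GaitPhase,
    ) -> np.ndarray | None:
        values = {"left": left, "right": right}
        for (side, ch), buf in self._buffers.items():
            buf.append(float(values[side][ch]))
        tracked = left_phase if self.sequence_foot == "left" else right_phase
        if tracked != self._last_phase:
            self._phase_buffer.append(GaitPhase(tracked))
            self._last_phase = GaitPhase(tracked)
        if not self.warmed_up:
            return None
        vector = np.empty(N_FEATURES)
        for i, key in enumerate(BUFFER_ORDER):
            arr = np.asarray(self._buffers[key], dtype=float)
            vector[3 * i : 3 * i + 3] = buffer_features(arr, self.fs)
        vector[-1] = phase_sequence_code(list(self._phase_buffer))
        return vector


def _sequence_codes(phases: np.ndarray) -> np.ndarray:
    """Per-sample phase-sequence codes from one foot's active-phase stream."""
    buf: deque = deque(maxlen=4)
    codes = np.empty(len(phases), dtype=float)
    last = None
    for t, ph in enumerate(phases):
        if ph != last:
            buf.append(int(ph))
            last = ph
        codes[t] = phase_sequence_code([GaitPhase(p) for p in buf])
    return codes


def extract_features_batch(
    channels: Mapping[tuple[str, str], np.ndarray],
    left_phases: np.ndarray,
    right_phases: np.ndarray,
    sequence_foot: str = "left",
    fs: float = SAMPLE_RATE_HZ,
) -> np.ndarray:
    """Vectorized equivalent of streaming extraction over a whole recording.

    ``channels`` maps every (side, channel) pair of ``BUFFER_ORDER`` to its
    full signal array; all arrays and both phase streams must share length
    n >= 128.  Returns the (n - 127, 37) feature matrix whose row t matches
    the streaming extractor's output after consuming sample t + 127.
    """
    n = len(left_phases)
    if len(right_phases) != n:
        raise ValueError("left and right phase streams differ in length")
    if n < BUFFER_SIZE:
        raise ValueError(f"need at least {BUFFER_SIZE} samples, got {n}")
    out = np.empty((n - BUFFER_SIZE + 1, N_FEATURES))
    for i, key in enumerate(BUFFER_ORDER):
        sig = np.asarray(channels[key], dtype=float)
        if len(sig) != n:
            raise ValueError(f"channel {key} length {len(sig)} != {n}")
        windows = sliding_window_view(sig, BUFFER_SIZE)
        out[:, 3 * i] = windows.mean(axis=1)
        out[:, 3 * i + 1] = np.sqrt(np.mean(windows**2, axis=1))
        mags = np.abs(np.fft.rfft(windows, axis=1))[:, 1:]
        peak_bin = np.argmax(mags, axis=1) + 1
        flat = mags.max(axis=1) <= _PEAK_TOLERANCE
        out[:, 3 * i + 2] = np.where(flat, 0.0, peak_bin * fs / BUFFER_SIZE)
    phases = left_phases if sequence_foot == "left" else right_phases
    out[:, -1] = _sequence_codes(np.asarray(phases))[BUFFER_SIZE - 1 :]
    return out
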