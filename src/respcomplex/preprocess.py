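"""Reduce a raw recording to clean nocturnal total-respiration segments.

Stages, in order: restrict to the nighttime window (23:00-05:00 by default),
flag movement periods from the accelerometer and excise them, sum the chest
and abdomen channels into the total respiratory signal, linearly detrend each
retained run, and low-pass filter it (5th-order 2 Hz Butterworth, zero-phase
by default so breath landmark times are not shifted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.signal

from .synthetic import RawRecording

__all__ = [
    "IntervalSet",
    "CleanSignal",
    "Segment",
    "EmptySelectionError",
    "select_night_window",
    "detect_movement",
    "combine_and_clean",
    "detrend_linear",
    "lowpass_butterworth",
]


class EmptySelectionError(ValueError):
    """Raised when a recording does not overlap the requested night window."""


@dataclass
class IntervalSet:
    """Sorted, non-overlapping half-open ``[start, end)`` intervals (seconds)."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = self._merge(self.intervals)

    @staticmethod
    def _merge(raw: list[tuple[float, float]]) -> list[tuple[float, float]]:
        merged: list[tuple[float, float]] = []
        for s, e in sorted(raw):
            if e <= s:
                raise ValueError(f"interval end must exceed start, got [{s}, {e})")
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_duration(self) -> float:
        return sum(e - s for s, e in self.intervals)

    def pad(self, pad_s: float) -> "IntervalSet":
        return IntervalSet(
            [(max(0.0, s - pad_s), e + pad_s) for s, e in self.intervals]
        )

    def contains(self, t: float | np.ndarray):
        """Membership test for scalar or array times."""
        t = np.asarray(t, dtype=float)
        inside = np.zeros(t.shape, dtype=bool)
        for s, e in self.intervals:
            inside |= (t >= s) & (t < e)
        return inside if inside.shape else bool(inside)


class Segment(NamedTuple):
    offset_s: float
    samples: np.ndarray


@dataclass
class CleanSignal:
    """Movement-free, detrended, low-pass-filtered total-respiration runs.

    ``retained_fraction`` is the retained duration divided by the duration of
    the recording handed in (after any night-window selection).
    """

    segments: list[Segment]
    fs: float
    retained_fraction: float

    def __post_init__(self) -> None:
        offsets = [s.offset_s for s in self.segments]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("segment offsets must be strictly increasing")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total_duration(self) -> float:
        return sum(len(s.samples) for s in self.segments) / self.fs


def _night_anchor(day: datetime, w_start: time, w_end: time) -> tuple[datetime, datetime]:
    ws = datetime.combine(day.date(), w_start)
    we = datetime.combine(day.date(), w_end)
    if w_end <= w_start:  # window crosses midnight
        we += timedelta(days=1)
    return ws, we


def select_night_window(
    recording: RawRecording,
    window_start: time = time(23, 0),
    window_end: time = time(5, 0),
) -> RawRecording:
    """Return the sub-recording inside the nighttime analysis window.

    The window is interpreted on the recording's own wall clock; when it
    crosses midnight the occurrence with the largest overlap is used.  A
    recording disjoint from every candidate window raises
    :class:`EmptySelectionError`.
    """
    rec_start = recording.start_clock
    rec_end = recording.end_clock

    best: tuple[float, datetime, datetime] | None = None
    for day_shift in (-1, 0, 1):
        ws, we = _night_anchor(
            rec_start + timedelta(days=day_shift), window_start, window_end
        )
        lo, hi = max(ws, rec_start), min(we, rec_end)
        overlap = (hi - lo).total_seconds()
        if overlap > 0 and (best is None or overlap > best[0]):
            best = (overlap, lo, hi)
    if best is None:
        raise EmptySelectionError(
            f"recording {rec_start:%H:%M}-{rec_end:%H:%M} does not overlap "
            f"the night window {window_start:%H:%M}-{window_end:%H:%M}"
        )

    _, lo, hi = best
    i0 = int(round((lo - rec_start).total_seconds() * recording.fs))
    i1 = int(round((hi - rec_start).total_seconds() * recording.fs))
    i0, i1 = max(i0, 0), min(i1, recording.n_samples)

    t0 = i0 / recording.fs
    t1 = i1 / recording.fs
    gt = None
    if recording.ground_truth is not None:
        gt = recording.ground_truth
        keep = (gt["t_valley_start"] >= t0 - 1e-9) & (gt["t_valley_end"] <= t1 + 1e-9)
        gt = gt.loc[keep].copy()
        for col in ("t_valley_start", "t_peak", "t_valley_end"):
            gt[col] -= t0
        gt = gt.reset_index(drop=True)
    artifacts = [
        (max(s, t0) - t0, min(e, t1) - t0)
        for s, e in recording.artifacts
        if min(e, t1) > max(s, t0)
    ]
    return RawRecording(
        start_clock=rec_start + timedelta(seconds=t0),
        fs=recording.fs,
        chest=recording.chest[i0:i1].copy(),
        abdomen=recording.abdomen[i0:i1].copy(),
        accel=recording.accel[i0:i1].copy(),
        ground_truth=gt,
        artifacts=artifacts,
    )


def detect_movement(
    accel: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    threshold_g: float = 0.05,
    pad_s: float = 2.0,
    step_s: float = 0.5,
) -> IntervalSet:
    """Flag windows where the accelerometer-magnitude SD exceeds a threshold.

    A sliding window (default 1 s, 0.5 s step) over the vector magnitude of
    the 3-axis signal; flagged windows are padded by ``pad_s`` on each side
    and merged.
    """
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise ValueError(f"accel must be an (n, 3) array, got shape {accel.shape}")
    mag = np.sqrt((accel**2).sum(axis=1))
    n = len(mag)
    w = max(2, int(round(window_s * fs)))
    step = max(1, int(round(step_s * fs)))
    if n < w:
        return IntervalSet([])

    # windowed SD via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(mag)])
    c2 = np.concatenate([[0.0], np.cumsum(mag**2)])
    starts = np.arange(0, n - w + 1, step)
    s1 = c1[starts + w] - c1[starts]
    s2 = c2[starts + w] - c2[starts]
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    flagged = np.sqrt(var) > threshold_g

    raw = [
        (starts[i] / fs, (starts[i] + w) / fs) for i in np.flatnonzero(flagged)
    ]
    if not raw:
        return IntervalSet([])
    return IntervalSet(raw).pad(pad_s)


def detrend_linear(samples: np.ndarray) -> np.ndarray:
    """Remove the ordinary-least-squares line fit to (index, value)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError(f"detrend needs >= 2 samples, got {samples.size}")
    return scipy.signal.detrend(samples, type="linear")


def lowpass_butterworth(
    samples: np.ndarray,
    fs: float,
    order: int = 5,
    cutoff: float = 2.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth IIR low-pass; zero-phase (forward-backward) by default."""
    if not 0 < cutoff < fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={fs / 2} Hz), got {cutoff}"
        )
    samples = np.asarray(samples, dtype=float)
    sos = scipy.signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    if zero_phase:
        return scipy.signal.sosfiltfilt(sos, samples)
    return scipy.signal.sosfilt(sos, samples)


def combine_and_clean(
    recording: RawRecording,
    movement: IntervalSet,
    min_segment_s: float = 60.0,
    *,
    filter_order: int = 5,
    cutoff_hz: float = 2.0,
    zero_phase: bool = True,
) -> CleanSignal:
    """Sum channels, excise movement, detrend then low-pass each run.

    Runs shorter than ``min_segment_s`` after excision are dropped.  A fully
    excised recording yields an empty :class:`CleanSignal` with
    ``retained_fraction`` 0 (not an error).
    """
    total = recording.total_respiration()
    n = len(total)
    fs = recording.fs
    t = np.arange(n) / fs
    keep = ~movement.contains(t) if len(movement) else np.ones(n, dtype=bool)

    min_len = int(round(min_segment_s * fs))
    segments: list[Segment] = []
    retained = 0
    # contiguous True runs
    boundaries = np.flatnonzero(np.diff(keep.astype(np.int8)))
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [n]])
    for s, e in zip(starts, ends):
        if not keep[s]:
            continue
        if e - s < max(min_len, 2):
            continue
        x = detrend_linear(total[s:e])
        x = lowpass_butterworth(
            x, fs, order=filter_order, cutoff=cutoff_hz, zero_phase=zero_phase
        )
        segments.append(Segment(offset_s=s / fs, samples=x))
        retained += e - s

    return CleanSignal(
        segments=segments,
        fs=fs,
        retained_fraction=retained / n if n else 0.0,
    )
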