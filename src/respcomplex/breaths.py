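"""Breath segmentation: extremum search and BBI/RA series construction.

One breath is anchored valley-to-valley (inspiration then expiration), so the
breath-to-breath interval decomposes exactly as BBI = TI + TE and the
expiratory fraction TE_ratio = TE/BBI stays inside (0, 1).  The respiratory
amplitude RA is the peak value minus the preceding valley value (the
inspiratory excursion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .preprocess import CleanSignal

__all__ = [
    "Extrema",
    "BreathSeries",
    "find_extrema",
    "build_breath_series",
    "concatenate_series",
    "breaths_from_clean",
]

BREATH_COLUMNS = [
    "t_valley_start",
    "t_peak",
    "t_valley_end",
    "TI",
    "TE",
    "BBI",
    "RA",
    "TE_ratio",
    "segment_id",
]


@dataclass
class Extrema:
    """Strictly alternating valley/peak sample indices within one segment."""

    indices: np.ndarray  # int sample indices, increasing
    is_peak: np.ndarray  # bool, same length

    def __len__(self) -> int:
        return len(self.indices)


def find_extrema(
    segment: np.ndarray,
    fs: float,
    min_prominence: float | None = None,
    min_peak_distance_s: float = 0.8,
) -> Extrema:
    """Detect alternating valleys and peaks of a respiration segment.

    Peaks and valleys are found independently (prominence- and spacing-
    constrained), merged in time order, and forced to alternate by keeping
    the more extreme of any two consecutive same-type extrema (earlier one on
    ties).  ``min_prominence`` defaults to 20% of the segment's interquartile
    range.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 3:
        return Extrema(np.array([], dtype=int), np.array([], dtype=bool))
    if min_prominence is None:
        q75, q25 = np.percentile(segment, [75, 25])
        min_prominence = 0.2 * (q75 - q25)
    distance = max(1, int(round(min_peak_distance_s * fs)))

    peaks, _ = scipy.signal.find_peaks(
        segment, prominence=min_prominence, distance=distance
    )
    valleys, _ = scipy.signal.find_peaks(
        -segment, prominence=min_prominence, distance=distance
    )

    idx = np.concatenate([peaks, valleys])
    kind = np.concatenate(
        [np.ones(len(peaks), dtype=bool), np.zeros(len(valleys), dtype=bool)]
    )
    order = np.argsort(idx, kind="stable")
    idx, kind = idx[order], kind[order]

    kept: list[tuple[int, bool]] = []
    for i, pk in zip(idx, kind):
        if kept and kept[-1][1] == pk:
            prev_i = kept[-1][0]
            if pk:
                better = segment[i] > segment[prev_i]  # tie keeps the earlier
            else:
                better = segment[i] < segment[prev_i]
            if better:
                kept[-1] = (int(i), bool(pk))
        else:
            kept.append((int(i), bool(pk)))

    if not kept:
        return Extrema(np.array([], dtype=int), np.array([], dtype=bool))
    out_idx = np.array([k[0] for k in kept], dtype=int)
    out_pk = np.array([k[1] for k in kept], dtype=bool)
    return Extrema(out_idx, out_pk)


@dataclass
class BreathSeries:
    """Per-breath timing and amplitude table, the pipeline's central object.

    Wraps a DataFrame with columns :data:`BREATH_COLUMNS`; times are seconds
    from the recording start.  ``n_dropped`` counts breaths discarded by the
    plausibility filters.
    """

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=BREATH_COLUMNS)
    )
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = set(BREATH_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"BreathSeries missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def bbi(self) -> np.ndarray:
        return self.df["BBI"].to_numpy(dtype=float)

    @property
    def ra(self) -> np.ndarray:
        return self.df["RA"].to_numpy(dtype=float)

    @property
    def ti(self) -> np.ndarray:
        return self.df["TI"].to_numpy(dtype=float)

    @property
    def te(self) -> np.ndarray:
        return self.df["TE"].to_numpy(dtype=float)

    @property
    def te_ratio(self) -> np.ndarray:
        return self.df["TE_ratio"].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BreathSeries":
        return cls(pd.read_csv(path))


def build_breath_series(
    extrema: Extrema,
    segment: np.ndarray,
    fs: float,
    *,
    segment_id: int = 0,
    offset_s: float = 0.0,
    bbi_min_s: float = 1.0,
    bbi_max_s: float = 15.0,
    ra_min_frac: float = 0.1,
) -> BreathSeries:
    """Turn (valley, peak, valley) triples into breaths with plausibility filters.

    Filters: BBI within [``bbi_min_s``, ``bbi_max_s``] (4-60 breaths/min),
    RA > 0 and at least ``ra_min_frac`` of the segment's median candidate RA.
    Dropped breaths are counted, not silently discarded.
    """
    segment = np.asarray(segment, dtype=float)
    idx, pk = extrema.indices, extrema.is_peak
    if len(idx) < 3:
        return BreathSeries()
    # triples (valley, peak, valley)
    k = np.flatnonzero(~pk[:-2] & pk[1:-1] & ~pk[2:])
    if len(k) == 0:
        return BreathSeries()
    v0, p, v1 = idx[k], idx[k + 1], idx[k + 2]
    t0, tp, t1 = v0 / fs, p / fs, v1 / fs
    ti = tp - t0
    te = t1 - tp
    df = pd.DataFrame(
        {
            "t_valley_start": offset_s + t0,
            "t_peak": offset_s + tp,
            "t_valley_end": offset_s + t1,
            "TI": ti,
            "TE": te,
            "BBI": ti + te,
            "RA": segment[p] - segment[v0],
            "TE_ratio": te / (ti + te),
            "segment_id": segment_id,
        },
        columns=BREATH_COLUMNS,
    )
    n_candidates = len(df)
    ok = (df["BBI"] >= bbi_min_s) & (df["BBI"] <= bbi_max_s) & (df["RA"] > 0)
    median_ra = df.loc[ok, "RA"].median()
    if np.isfinite(median_ra):
        ok &= df["RA"] >= ra_min_frac * median_ra
    df = df.loc[ok].reset_index(drop=True)
    return BreathSeries(df, n_dropped=n_candidates - len(df))


def concatenate_series(series_list: list[BreathSeries]) -> BreathSeries:
    """Breath-domain concatenation of time-ordered series.

    Segment identities are preserved, so no synthetic breath ever spans an
    excised gap.  Overlapping inputs raise ``ValueError``.
    """
    frames = [s.df for s in series_list if len(s)]
    n_dropped = sum(s.n_dropped for s in series_list)
    if not frames:
        return BreathSeries(n_dropped=n_dropped)
    prev_end = -np.inf
    for f in frames:
        if f["t_valley_start"].iloc[0] < prev_end - 1e-9:
            raise ValueError("breath series overlap in time; inputs must be ordered")
        prev_end = f["t_valley_end"].iloc[-1]
    out = pd.concat(frames, ignore_index=True)
    return BreathSeries(out, n_dropped=n_dropped)


def breaths_from_clean(
    clean: CleanSignal,
    *,
    min_prominence: float | None = None,
    min_peak_distance_s: float = 0.8,
    bbi_min_s: float = 1.0,
    bbi_max_s: float = 15.0,
    ra_min_frac: float = 0.1,
) -> BreathSeries:
    """Segment every clean run and concatenate the resulting breath series."""
    parts = []
    for seg_id, seg in enumerate(clean.segments):
        ext = find_extrema(
            seg.samples,
            clean.fs,
            min_prominence=min_prominence,
            min_peak_distance_s=min_peak_distance_s,
        )
        parts.append(
            build_breath_series(
                ext,
                seg.samples,
                clean.fs,
                segment_id=seg_id,
                offset_s=seg.offset_s,
                bbi_min_s=bbi_min_s,
                bbi_max_s=bbi_max_s,
                ra_min_frac=ra_min_frac,
            )
        )
    return concatenate_series(parts)
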