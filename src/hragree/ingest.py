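"""Ingestion and preprocessing of raw paired device streams.

The reference channel arrives as beat-level R-R intervals (ms). It is
converted to instantaneous bpm (60000 / RR), linearly resampled onto a
1-second grid, low-pass filtered with a zero-phase 5th-order Butterworth
at 0.1 Hz to remove high-frequency artifacts, averaged into 10-second
slots and then into per-minute values. The test channel arrives already
at per-minute cadence. Both channels are then paired minute-by-minute on
the absolute minute lattice anchored at the manifest session start;
sessions with fewer than 20 paired minutes are excluded.

Minute bins are left-closed right-open and labelled by bin start. A
downsampled bin is considered present when at least ``MIN_BIN_FRACTION``
of its constituent slots are present (the 1-s grid cannot cover second 0
of a session, because the first beat falls strictly after the start, so a
strict all-present rule would void every session's first minute).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .series import (
    HR_VALID_HIGH,
    HR_VALID_LOW,
    PairedMinuteSession,
    RRStream,
    UniformHRSeries,
)

__all__ = [
    "rr_to_bpm",
    "resample_uniform",
    "lowpass_filter",
    "downsample_mean",
    "validity_gate",
    "reference_to_minutes",
    "pair_minutes",
    "align_sessions",
    "read_rr_stream",
    "read_test_minutes",
    "write_paired_sessions",
    "SessionExclusion",
    "MIN_BIN_FRACTION",
    "MIN_PAIRED_MINUTES",
]

logger = logging.getLogger(__name__)

#: Fraction of constituent slots a downsampled bin needs to count as present.
MIN_BIN_FRACTION = 0.8
#: Sessions with fewer paired minutes than this are excluded.
MIN_PAIRED_MINUTES = 20

FILTER_ORDER = 5
FILTER_CUTOFF_HZ = 0.1


@dataclass(frozen=True)
class SessionExclusion:
    session_id: str
    stage: str
    reason: str


def rr_to_bpm(stream: RRStream) -> tuple[np.ndarray, np.ndarray]:
    """Convert beat-level R-R intervals to instantaneous HR.

    Returns ``(beat_times_s, bpm)`` with ``bpm_i = 60000 / rr_ms_i``
    attached to the beat's own timestamp; length is preserved.
    (The RRStream constructor already rejects non-positive intervals,
    naming the offending row.)
    """
    return stream.beat_times_s, 60000.0 / stream.rr_ms


def resample_uniform(
    times_s: np.ndarray, values: np.ndarray, cadence_s: float = 1.0
) -> UniformHRSeries:
    """Linearly interpolate an irregular series onto a uniform grid.

    The grid spans the data (first whole-cadence tick at or after the
    first point, to the last tick at or before the last point) so no
    extrapolation occurs; ticks sit on the absolute session lattice so
    later minute bins align across devices.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_s.size < 2:
        raise ValueError("resampling needs at least 2 points")
    t0 = float(np.ceil(times_s[0] / cadence_s) * cadence_s)
    t1 = float(np.floor(times_s[-1] / cadence_s) * cadence_s)
    if t1 < t0:
        raise ValueError("data span shorter than one cadence interval")
    grid = np.arange(t0, t1 + 0.5 * cadence_s, cadence_s)
    hr = np.interp(grid, times_s, values)
    return UniformHRSeries(
        session_id="", cadence_s=cadence_s, start_offset_s=t0, hr=hr
    )


def lowpass_filter(
    series: UniformHRSeries,
    order: int = FILTER_ORDER,
    cutoff_hz: float = FILTER_CUTOFF_HZ,
) -> UniformHRSeries:
    """Zero-phase Butterworth low-pass filter on a 1-s grid.

    Forward-backward application removes group delay, which would
    otherwise shift the reference channel by tens of seconds relative to
    the test channel. The cutoff is normalized against the Nyquist
    frequency of the grid (0.1 Hz / 0.5 Hz = 0.2 for 1-s cadence).
    """
    if series.cadence_s != 1.0:
        raise ValueError("lowpass_filter expects a 1-s cadence series")
    min_len = 3 * (order + 1) + 1
    if len(series) < min_len:
        raise ValueError(
            f"series of {len(series)} samples is too short to filter "
            f"(needs > {3 * (order + 1)}); exclude this session"
        )
    nyquist = 0.5 / series.cadence_s
    b, a = butter(order, cutoff_hz / nyquist, btype="low")
    hr = filtfilt(b, a, series.hr)
    return UniformHRSeries(
        session_id=series.session_id,
        cadence_s=series.cadence_s,
        start_offset_s=series.start_offset_s,
        hr=hr,
        mask=series.mask.copy(),
    )


def downsample_mean(
    series: UniformHRSeries,
    target_cadence_s: float,
    min_fraction: float = MIN_BIN_FRACTION,
) -> UniformHRSeries:
    """Average a uniform series into coarser bins on the session lattice.

    Bins are left-closed right-open intervals ``[j*T, (j+1)*T)`` labelled
    by their start. Each output bin is the mean of its present constituent
    slots, and is marked missing when fewer than ``min_fraction`` of the
    bin's nominal slots are present.
    """
    factor = target_cadence_s / series.cadence_s
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"target cadence {target_cadence_s}s is not an integer multiple "
            f"of input cadence {series.cadence_s}s"
        )
    factor = int(round(factor))
    t = series.times_s
    bins = np.floor(t / target_cadence_s + 1e-9).astype(int)
    first = bins[0]
    rel = bins - first
    n_bins = rel[-1] + 1
    w = series.mask.astype(float)
    vals = np.where(series.mask, series.hr, 0.0)
    sums = np.bincount(rel, weights=vals, minlength=n_bins)
    counts = np.bincount(rel, weights=w, minlength=n_bins)
    present = counts >= min_fraction * factor
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.where(present, sums / np.maximum(counts, 1e-12), np.nan)
    return UniformHRSeries(
        session_id=series.session_id,
        cadence_s=float(target_cadence_s),
        start_offset_s=first * float(target_cadence_s),
        hr=hr,
        mask=present,
    )


def validity_gate(series: UniformHRSeries) -> UniformHRSeries:
    """Mark physiologically impossible per-slot values as missing.

    Values outside the open interval (20, 250) bpm guard against corrupt
    rows; this is a data-hygiene rule, not a protocol rule.
    """
    bad = series.mask & ~(
        (series.hr > HR_VALID_LOW) & (series.hr < HR_VALID_HIGH)
    )
    if np.any(bad):
        logger.warning(
            "session %s: %d slot(s) outside (%g, %g) bpm set missing",
            series.session_id, int(bad.sum()), HR_VALID_LOW, HR_VALID_HIGH,
        )
    return UniformHRSeries(
        session_id=series.session_id,
        cadence_s=series.cadence_s,
        start_offset_s=series.start_offset_s,
        hr=np.where(bad, np.nan, series.hr),
        mask=series.mask & ~bad,
    )


def reference_to_minutes(
    stream: RRStream,
    order: int = FILTER_ORDER,
    cutoff_hz: float = FILTER_CUTOFF_HZ,
) -> UniformHRSeries:
    """Full reference-channel chain: R-R -> bpm -> 1 s -> filter -> 10 s -> 60 s."""
    times, bpm = rr_to_bpm(stream)
    one_s = resample_uniform(times, bpm, cadence_s=1.0)
    filtered = lowpass_filter(one_s, order=order, cutoff_hz=cutoff_hz)
    ten_s = downsample_mean(filtered, 10.0)
    minutes = downsample_mean(ten_s, 60.0)
    minutes.session_id = stream.session_id
    return validity_gate(minutes)


def pair_minutes(
    test: UniformHRSeries, reference: UniformHRSeries
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersect two minute series on their shared absolute minute indices.

    Symmetric in its arguments: swapping test and reference yields the
    same minute indices. Returns (minute_index, test_hr, reference_hr).
    """
    for s in (test, reference):
        if s.cadence_s != 60.0:
            raise ValueError("pair_minutes expects 60-s cadence series")

    def _index_map(s: UniformHRSeries) -> dict[int, float]:
        first = int(round(s.start_offset_s / 60.0))
        return {
            first + i: float(s.hr[i]) for i in range(len(s)) if s.mask[i]
        }

    t_map, r_map = _index_map(test), _index_map(reference)
    shared = sorted(t_map.keys() & r_map.keys())
    idx = np.array(shared, dtype=int)
    return idx, np.array([t_map[i] for i in shared]), np.array(
        [r_map[i] for i in shared]
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _seconds_from(start: pd.Timestamp, stamps: pd.Series) -> np.ndarray:
    return (pd.to_datetime(stamps) - start).dt.total_seconds().to_numpy()


def read_rr_stream(
    path: str | Path, session_start: pd.Timestamp, session_id: str = ""
) -> RRStream:
    """Read a reference-stream CSV (``timestamp_iso8601, rr_ms``)."""
    df = _read_csv_dialect(path, ["timestamp_iso8601", "rr_ms"])
    times = _seconds_from(session_start, df["timestamp_iso8601"])
    return RRStream(
        session_id=session_id,
        beat_times_s=times,
        rr_ms=df["rr_ms"].astype(float).to_numpy(),
    )


def read_test_minutes(
    path: str | Path, session_start: pd.Timestamp, session_id: str = ""
) -> UniformHRSeries:
    """Read a test-stream CSV (``timestamp_iso8601, hr_bpm``) onto the
    session's minute lattice."""
    df = _read_csv_dialect(path, ["timestamp_iso8601", "hr_bpm"])
    times = _seconds_from(session_start, df["timestamp_iso8601"])
    minute = np.floor(times / 60.0 + 1e-9).astype(int)
    if minute.size == 0:
        return UniformHRSeries(session_id, 60.0, 0.0, np.array([]))
    first, last = int(minute.min()), int(minute.max())
    hr = np.full(last - first + 1, np.nan)
    hr[minute - first] = df["hr_bpm"].astype(float).to_numpy()
    series = UniformHRSeries(
        session_id=session_id,
        cadence_s=60.0,
        start_offset_s=first * 60.0,
        hr=hr,
    )
    return validity_gate(series)


def _read_csv_dialect(path: str | Path, columns: list[str]) -> pd.DataFrame:
    """Read a stream CSV, tolerating a missing header row."""
    df = pd.read_csv(path)
    if list(df.columns[: len(columns)]) != columns:
        df = pd.read_csv(path, header=None, names=columns)
    return df[columns]


def align_sessions(
    manifest: pd.DataFrame,
    participants: pd.DataFrame,
    data_dir: str | Path,
    min_minutes: int = MIN_PAIRED_MINUTES,
    filter_order: int = FILTER_ORDER,
    filter_cutoff_hz: float = FILTER_CUTOFF_HZ,
) -> tuple[list[PairedMinuteSession], list[SessionExclusion]]:
    """Build paired per-minute sessions for every surviving manifest row.

    Sessions are excluded (and logged, not fatal) when a stream file is
    missing, a stream is too short to process, the devices share no
    minutes, or fewer than ``min_minutes`` paired minutes remain.
    """
    data_dir = Path(data_dir)
    ages = participants.set_index("participant_id")["age_years"].to_dict()
    sessions: list[PairedMinuteSession] = []
    exclusions: list[SessionExclusion] = []

    for row in manifest.itertuples(index=False):
        sid = row.session_id
        start = pd.Timestamp(row.start_iso8601)
        ref_path = data_dir / row.reference_file
        test_path = data_dir / row.test_file
        missing = [p for p in (ref_path, test_path) if not p.exists()]
        if missing:
            exclusions.append(
                SessionExclusion(sid, "ingest", f"missing_file:{missing[0].name}")
            )
            logger.warning("session %s skipped: missing %s", sid, missing[0])
            continue
        if row.participant_id not in ages:
            exclusions.append(SessionExclusion(sid, "ingest", "unknown_participant"))
            continue
        try:
            stream = read_rr_stream(ref_path, start, sid)
            ref_minutes = reference_to_minutes(
                stream, order=filter_order, cutoff_hz=filter_cutoff_hz
            )
        except ValueError as exc:
            exclusions.append(SessionExclusion(sid, "ingest", f"reference_stream:{exc}"))
            continue
        test_minutes = read_test_minutes(test_path, start, sid)

        idx, test_hr, ref_hr = pair_minutes(test_minutes, ref_minutes)
        if idx.size == 0:
            exclusions.append(SessionExclusion(sid, "align", "no_overlapping_minutes"))
            continue
        if idx.size < min_minutes:
            exclusions.append(
                SessionExclusion(
                    sid, "align", f"too_few_paired_minutes:{idx.size}"
                )
            )
            continue
        sessions.append(
            PairedMinuteSession(
                session_id=sid,
                participant_id=row.participant_id,
                age=float(ages[row.participant_id]),
                minute_index=idx,
                test_hr=test_hr,
                reference_hr=ref_hr,
            )
        )
    return sessions, exclusions


def write_paired_sessions(
    sessions: Iterable[PairedMinuteSession], path: str | Path
) -> None:
    """Write the intermediate paired-session table
    (``session_id, minute_index, test_hr_bpm, reference_hr_bpm``)."""
    frames = [
        pd.DataFrame(
            {
                "session_id": s.session_id,
                "minute_index": s.minute_index,
                "test_hr_bpm": s.test_hr,
                "reference_hr_bpm": s.reference_hr,
            }
        )
        for s in sessions
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["session_id", "minute_index", "test_hr_bpm", "reference_hr_bpm"]
        )
    )
    out.to_csv(path, index=False)
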