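"""Per-session summaries and high-intensity classification.

For each paired session this module computes the two HR averages the
comparison rests on — the baseline mean over the first 5 minutes (the rest
period) and the peak mean over the best 20 consecutive minutes — plus the
age-predicted theoretical maximum HR (220 - age), the normalized intensity
ratio HR_N = HRmean / (p * (220 - age)), and the session's confusion-matrix
outcome with the reference channel as gold standard: a session is positive
when its ratio is strictly greater than 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import PairedMinuteSession

__all__ = [
    "SessionSummary",
    "theoretical_max_hr",
    "normalized_intensity",
    "classify_session",
    "baseline_mean",
    "peak20_mean",
    "summarize_session",
    "summarize_cohort",
    "PEAK_WINDOW_MINUTES",
    "BASELINE_MINUTES",
]

PEAK_WINDOW_MINUTES = 20
BASELINE_MINUTES = 5


@dataclass(frozen=True)
class SessionSummary:
    session_id: str
    participant_id: str
    age: float
    baseline_test: float | None  # bpm; None when the first 5 min are incomplete
    baseline_ref: float | None
    peak20_test: float
    peak20_ref: float
    peak20_test_start: int  # minute index where each device's best window begins
    peak20_ref_start: int
    hr_th_max: float


def theoretical_max_hr(age: float) -> float:
    """Age-predicted maximum HR: 220 - age."""
    if age <= 0:
        raise ValueError("age must be positive")
    return 220.0 - age


def normalized_intensity(hr_mu: float, age: float, p: float) -> float:
    """Normalized intensity ratio HR_N = HRmean / (p * (220 - age))."""
    if not 0 < p <= 1.2:
        raise ValueError("threshold fraction p must lie in (0, 1.2]")
    return hr_mu / (p * theoretical_max_hr(age))


def classify_session(hr_n_test: float, hr_n_reference: float) -> str:
    """Confusion outcome for one session under the strict >1 positivity rule.

    The reference channel is the gold standard. A ratio of exactly 1
    counts as negative (positivity is defined strictly as >1).
    """
    test_pos = hr_n_test > 1.0
    ref_pos = hr_n_reference > 1.0
    if test_pos and ref_pos:
        return "TP"
    if test_pos and not ref_pos:
        return "FP"
    if not test_pos and ref_pos:
        return "FN"
    return "TN"


def baseline_mean(
    session: PairedMinuteSession, n_minutes: int = BASELINE_MINUTES
) -> tuple[float, float] | None:
    """Mean of each device over paired minutes 0..n_minutes-1.

    Returns None when any of the first ``n_minutes`` minutes lacks a pair
    (late device starts and dropouts make the rest-period mean
    uninterpretable).
    """
    wanted = np.arange(n_minutes)
    present = np.isin(wanted, session.minute_index)
    if not present.all():
        return None
    sel = np.isin(session.minute_index, wanted)
    return float(session.test_hr[sel].mean()), float(session.reference_hr[sel].mean())


def peak20_mean(
    minute_index: np.ndarray,
    values: np.ndarray,
    window: int = PEAK_WINDOW_MINUTES,
) -> tuple[int, float]:
    """Best mean over any ``window`` *consecutive present* minutes.

    Slides a window one minute at a time over runs of consecutive minute
    indices (windows spanning dropout gaps are not 20-minute intervals and
    are skipped) and returns ``(start_minute, mean)`` of the window with
    the highest mean; ties go to the earliest start.
    """
    minute_index = np.asarray(minute_index, dtype=int)
    values = np.asarray(values, dtype=float)
    n = minute_index.size
    if n < window:
        raise ValueError(
            f"no complete {window}-minute window ({n} paired minutes); "
            "session should be excluded"
        )
    csum = np.concatenate([[0.0], np.cumsum(values)])
    starts = np.arange(n - window + 1)
    # Window is gap-free iff its index span equals window - 1.
    contiguous = minute_index[starts + window - 1] - minute_index[starts] == window - 1
    if not contiguous.any():
        raise ValueError(
            f"no gap-free {window}-minute window; session should be excluded"
        )
    means = (csum[starts + window] - csum[starts]) / window
    means = np.where(contiguous, means, -np.inf)
    best = int(np.argmax(means))  # argmax returns the earliest maximum
    return int(minute_index[best]), float(means[best])


def summarize_session(session: PairedMinuteSession) -> SessionSummary:
    """Compute baseline, peak-20 and HRmax summaries for one paired session.

    The peak 20-minute window is located on the reference (gold standard)
    series over the paired minute grid, and *both* devices are averaged
    over that same window. A per-device window search would let each
    device's own noise pick its luckiest window, confounding time-window
    disagreement with HR disagreement and inflating the test device's
    apparent peak.
    """
    base = baseline_mean(session)
    r_start, r_peak = peak20_mean(session.minute_index, session.reference_hr)
    window = (session.minute_index >= r_start) & (
        session.minute_index < r_start + PEAK_WINDOW_MINUTES
    )
    t_peak = float(session.test_hr[window].mean())
    t_start = r_start
    return SessionSummary(
        session_id=session.session_id,
        participant_id=session.participant_id,
        age=session.age,
        baseline_test=None if base is None else base[0],
        baseline_ref=None if base is None else base[1],
        peak20_test=t_peak,
        peak20_ref=r_peak,
        peak20_test_start=t_start,
        peak20_ref_start=r_start,
        hr_th_max=theoretical_max_hr(session.age),
    )


def summarize_cohort(
    sessions: list[PairedMinuteSession],
    exclusions: list | None = None,
) -> pd.DataFrame:
    """Session-summary table for a list of paired sessions.

    Columns: session_id, participant_id, age, baseline_test, baseline_ref,
    peak20_test, peak20_ref, hr_th_max (baselines NaN when incomplete).
    Sessions without any gap-free 20-minute window cannot be summarized;
    they are skipped and, when ``exclusions`` is given, appended to it as
    ``SessionExclusion`` records.
    """
    from .ingest import SessionExclusion

    rows = []
    for s in sessions:
        try:
            summ = summarize_session(s)
        except ValueError as exc:
            logging.getLogger(__name__).warning(
                "session %s excluded at feature stage: %s", s.session_id, exc
            )
            if exclusions is not None:
                exclusions.append(
                    SessionExclusion(s.session_id, "features", "no_gap_free_20min_window")
                )
            continue
        rows.append(
            {
                "session_id": summ.session_id,
                "participant_id": summ.participant_id,
                "age": summ.age,
                "baseline_test": np.nan if summ.baseline_test is None else summ.baseline_test,
                "baseline_ref": np.nan if summ.baseline_ref is None else summ.baseline_ref,
                "peak20_test": summ.peak20_test,
                "peak20_ref": summ.peak20_ref,
                "hr_th_max": summ.hr_th_max,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "session_id",
            "participant_id",
            "age",
            "baseline_test",
            "baseline_ref",
            "peak20_test",
            "peak20_ref",
            "hr_th_max",
        ],
    )
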