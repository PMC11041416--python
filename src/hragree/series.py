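"""Shared time-series containers for paired-device heart-rate data.

All within-session times are seconds from the session start declared in the
manifest; absolute wall-clock timestamps only exist at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Physiological validity gate for per-minute HR values (bpm, exclusive).
HR_VALID_LOW = 20.0
HR_VALID_HIGH = 250.0


@dataclass
class RRStream:
    """Beat-level R-R intervals from a chest-strap (ECG) reference device.

    Parameters
    ----------
    session_id : str
    beat_times_s : np.ndarray
        Beat timestamps in seconds from session start, strictly increasing.
    rr_ms : np.ndarray
        R-R interval ending at each beat, in milliseconds (all > 0).
    """

    session_id: str
    beat_times_s: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.beat_times_s.shape != self.rr_ms.shape:
            raise ValueError("beat_times_s and rr_ms must have equal length")
        if self.rr_ms.size:
            bad = np.nonzero(~(self.rr_ms > 0))[0]
            if bad.size:
                raise ValueError(
                    f"non-positive R-R interval at row {bad[0]} "
                    f"(rr_ms={self.rr_ms[bad[0]]!r})"
                )
            if np.any(np.diff(self.beat_times_s) <= 0):
                raise ValueError("beat timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.beat_times_s.size


@dataclass
class UniformHRSeries:
    """Uniformly sampled HR series with a missing-slot mask.

    ``hr[i]`` is the value for the slot starting at
    ``start_offset_s + i * cadence_s`` (left-closed, right-open bins).
    Missing slots carry NaN in ``hr`` and False in ``mask``.
    """

    session_id: str
    cadence_s: float
    start_offset_s: float
    hr: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.hr)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.hr.shape != self.mask.shape:
            raise ValueError("hr and mask must have equal length")

    def __len__(self) -> int:
        return self.hr.size

    @property
    def times_s(self) -> np.ndarray:
        return self.start_offset_s + np.arange(self.hr.size) * self.cadence_s

    def present_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass
class PairedMinuteSession:
    """Timestamp-aligned per-minute (test, reference) HR pairs for one session.

    ``minute_index`` counts whole minutes from the manifest session start;
    both device arrays are defined on exactly these minutes.
    """

    session_id: str
    participant_id: str
    age: float
    minute_index: np.ndarray
    test_hr: np.ndarray
    reference_hr: np.ndarray

    def __post_init__(self) -> None:
        self.minute_index = np.asarray(self.minute_index, dtype=int)
        self.test_hr = np.asarray(self.test_hr, dtype=float)
        self.reference_hr = np.asarray(self.reference_hr, dtype=float)
        n = self.minute_index.size
        if self.test_hr.size != n or self.reference_hr.size != n:
            raise ValueError("paired arrays must share one minute grid")
        if n and np.any(np.diff(self.minute_index) <= 0):
            raise ValueError("minute_index must be strictly increasing")

    def __len__(self) -> int:
        return self.minute_index.size
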