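"""Synthetic paired-device exercise cohort.

Generates fully synthetic one-hour exercise sessions for a cohort of older
adults, as recorded simultaneously by two heart-rate devices:

* a chest-strap reference channel emitting beat-level R-R intervals
  (milliseconds, with small beat-timing jitter), and
* a wrist-worn test channel emitting one HR sample per minute, whose
  expected value is a monotone saturating (sigmoid) distortion of the true
  HR, with additive Gaussian noise and occasional dropped minutes.

The latent ground truth is a 1-second heart-rate trajectory built from a
session protocol (rest / warm-up / high-intensity / cool-down), with phase
targets anchored to heart-rate reserve: target = resting HR + intensity x
(HRmax - resting HR), where HRmax follows the age-predicted rule 220 - age.
Phase changes are approached with a first-order exponential (time constant
60 s) and overlaid with smooth Ornstein-Uhlenbeck noise, so that the
trajectory has realistic autocorrelation rather than white noise.

Every emission is a pure function of its inputs and an integer seed;
per-session seeds are derived by stable hashing so that cohort generation
is independent of iteration order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .series import RRStream, UniformHRSeries

__all__ = [
    "Phase",
    "SessionProtocol",
    "ParticipantProfile",
    "DeviceErrorModel",
    "TrueTrajectory",
    "CohortConfig",
    "sigmoid_distortion",
    "simulate_true_hr",
    "emit_reference_rr",
    "emit_test_minutes",
    "simulate_session_means",
    "generate_cohort",
    "session_seed",
    "default_protocol",
    "error_preset",
    "cohort_preset",
    "ERROR_PRESETS",
    "COHORT_PRESETS",
]

PHASE_LABELS = ("rest", "warmup", "high", "cooldown")


@dataclass(frozen=True)
class Phase:
    label: str
    duration_min: float
    intensity: float  # fraction of heart-rate reserve in [0, 1]

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {self.label!r}")
        if not self.duration_min > 0:
            raise ValueError(f"phase {self.label!r} has non-positive duration")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")


@dataclass(frozen=True)
class SessionProtocol:
    """Ordered exercise phases; the default sums to a 60-minute session
    with at least 20 minutes of high-intensity work."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        high = sum(p.duration_min for p in self.phases if p.label == "high")
        if high and high < 20:
            raise ValueError("'high' phase must last at least 20 minutes")

    @property
    def total_duration_min(self) -> float:
        return sum(p.duration_min for p in self.phases)


def default_protocol() -> SessionProtocol:
    """Rest 5 min, warm-up 10 min, high-intensity 30 min, cool-down 15 min."""
    return SessionProtocol(
        (
            Phase("rest", 5, 0.0),
            Phase("warmup", 10, 0.50),
            Phase("high", 30, 0.85),
            Phase("cooldown", 15, 0.30),
        )
    )


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    age: int  # years
    resting_hr: float  # bpm
    n_sessions: int

    def __post_init__(self) -> None:
        if not 40 <= self.age <= 90:
            raise ValueError("age must lie in [40, 90] years")
        if not 45 <= self.resting_hr <= 90:
            raise ValueError("resting_hr must lie in [45, 90] bpm")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


@dataclass(frozen=True)
class DeviceErrorModel:
    """Error structure of the two channels.

    The test channel's expected reading for true HR ``h`` is the
    four-parameter logistic ``g(h) = a + (b - a) / (1 + exp(-(h - c)/d))``
    (floor ``a``, ceiling ``b``, midpoint ``c``, scale ``d``, all bpm),
    strictly increasing for ``d > 0``.
    """

    rr_jitter_sd_ms: float = 0.0
    sigmoid_a: float = -380.0
    sigmoid_b: float = 620.0
    sigmoid_c: float = 120.0
    sigmoid_d: float = 250.0
    test_noise_sd: float = 0.0
    test_dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.rr_jitter_sd_ms < 0 or self.test_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.test_dropout_prob < 1.0:
            raise ValueError("test_dropout_prob must lie in [0, 1)")
        if not self.sigmoid_b > self.sigmoid_a:
            raise ValueError("sigmoid ceiling b must exceed floor a")
        if not self.sigmoid_d > 0:
            raise ValueError("sigmoid scale d must be > 0")

    def distort(self, hr: np.ndarray | float) -> np.ndarray | float:
        return sigmoid_distortion(
            hr, self.sigmoid_a, self.sigmoid_b, self.sigmoid_c, self.sigmoid_d
        )


def sigmoid_distortion(h, a: float, b: float, c: float, d: float):
    """Four-parameter logistic ``a + (b - a)/(1 + exp(-(h - c)/d))``."""
    h = np.asarray(h, dtype=float)
    out = a + (b - a) / (1.0 + np.exp(-(h - c) / d))
    return float(out) if out.ndim == 0 else out


@dataclass
class TrueTrajectory:
    """Latent ground-truth HR at 1-second cadence (slot-start convention)."""

    times_s: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.times_s.shape != self.hr.shape:
            raise ValueError("times_s and hr must have equal length")
        if self.hr.size and not np.all(self.hr > 0):
            raise ValueError("true HR must be positive everywhere")

    def __len__(self) -> int:
        return self.hr.size

    def minute_means(self) -> np.ndarray:
        """Means over complete minutes; the ground-truth sidecar records these."""
        n_min = self.hr.size // 60
        return self.hr[: n_min * 60].reshape(n_min, 60).mean(axis=1)


# ---------------------------------------------------------------------------
# Latent trajectory
# ---------------------------------------------------------------------------

#: First-order time constant of phase-to-phase HR transitions (seconds).
TRANSITION_TAU_S = 60.0
#: Stationary SD (bpm) and correlation time (s) of the smooth HR noise.
OU_NOISE_SD = 2.0
OU_NOISE_TAU_S = 30.0


def _ou_noise(n: int, sd: float, tau_s: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise on a 1-s grid (exact discretization)."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-1.0 / tau_s)
    w = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n)
    x0 = rng.normal(0.0, sd)
    # AR(1) recursion x_t = phi x_{t-1} + w_t with stationary start.
    out = lfilter([1.0], [1.0, -phi], w, zi=[phi * x0])[0]
    return out


def simulate_true_hr(
    profile: ParticipantProfile,
    protocol: SessionProtocol,
    seed: int,
    *,
    noise_sd: float = OU_NOISE_SD,
    noise_tau_s: float = OU_NOISE_TAU_S,
    transition_tau_s: float = TRANSITION_TAU_S,
) -> TrueTrajectory:
    """Simulate the latent 1-s HR trajectory for one session.

    Each phase pulls HR exponentially (time constant ``transition_tau_s``)
    toward ``resting_hr + intensity * (220 - age - resting_hr)``, starting
    from the level reached at the end of the previous phase; smooth
    zero-mean noise is superimposed. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    hr_max = 220.0 - profile.age
    reserve = hr_max - profile.resting_hr
    segments = []
    level = profile.resting_hr
    for phase in protocol.phases:
        n = int(round(phase.duration_min * 60))
        target = profile.resting_hr + phase.intensity * reserve
        t = np.arange(n, dtype=float)
        seg = target + (level - target) * np.exp(-t / transition_tau_s)
        level = float(seg[-1])
        segments.append(seg)
    hr = np.concatenate(segments)
    hr = hr + _ou_noise(hr.size, noise_sd, noise_tau_s, rng)
    hr = np.maximum(hr, 30.0)  # guard: trajectory must stay positive
    return TrueTrajectory(np.arange(hr.size, dtype=float), hr)


# ---------------------------------------------------------------------------
# Device emissions
# ---------------------------------------------------------------------------

MIN_RR_MS = 250.0


def emit_reference_rr(
    traj: TrueTrajectory, err: DeviceErrorModel, seed: int
) -> RRStream:
    """Emit the reference-channel beat stream for a trajectory.

    Beat times come from integrating the instantaneous rate hr/60
    beats per second (a beat fires each time the accumulated phase crosses
    an integer); each R-R interval is then perturbed with Gaussian jitter
    of SD ``rr_jitter_sd_ms`` and clipped to >= 250 ms. Beats falling
    outside the session span after jitter are dropped.
    """
    if len(traj) == 0:
        raise ValueError("cannot emit beats from an empty trajectory")
    rng = np.random.default_rng(seed)
    span_s = float(len(traj))  # 1-s cadence
    # hr[i] is constant over [i, i+1): cumulative beat count is piecewise linear.
    grid = np.arange(len(traj) + 1, dtype=float)
    cum_beats = np.concatenate([[0.0], np.cumsum(traj.hr / 60.0)])
    n_beats = int(np.floor(cum_beats[-1] + 1e-9))
    if n_beats == 0:
        raise ValueError("trajectory too short to contain a single beat")
    beat_times = np.interp(np.arange(1, n_beats + 1, dtype=float), cum_beats, grid)
    rr_ms = np.diff(beat_times, prepend=0.0) * 1000.0
    if err.rr_jitter_sd_ms > 0:
        rr_ms = rr_ms + rng.normal(0.0, err.rr_jitter_sd_ms, size=rr_ms.size)
    rr_ms = np.maximum(rr_ms, MIN_RR_MS)
    times = np.cumsum(rr_ms) / 1000.0
    keep = times <= span_s + 1e-6  # cumsum round-off must not drop the last beat
    return RRStream(session_id="", beat_times_s=times[keep], rr_ms=rr_ms[keep])


def emit_test_minutes(
    traj: TrueTrajectory, err: DeviceErrorModel, seed: int
) -> UniformHRSeries:
    """Emit the test-channel per-minute HR series for a trajectory.

    Each full minute's true-HR mean is passed through the sigmoid
    distortion, Gaussian noise of SD ``test_noise_sd`` is added, and the
    minute is then dropped (masked missing) with probability
    ``test_dropout_prob``. Deterministic given ``seed``.
    """
    if len(traj) < 60:
        raise ValueError("trajectory must cover at least one full minute")
    rng = np.random.default_rng(seed)
    means = traj.minute_means()
    hr = np.asarray(err.distort(means), dtype=float)
    hr = hr + rng.normal(0.0, err.test_noise_sd, size=hr.size)
    dropped = rng.random(hr.size) < err.test_dropout_prob
    hr = np.where(dropped, np.nan, hr)
    return UniformHRSeries(
        session_id="", cadence_s=60.0, start_offset_s=0.0, hr=hr, mask=~dropped
    )


# ---------------------------------------------------------------------------
# Cohort presets and configuration
# ---------------------------------------------------------------------------

def _identity_sigmoid(shift: float = 0.0) -> dict:
    # Unit slope at the midpoint (b - a = 4 d) keeps |g(h) - h - shift| well
    # under 1 bpm across [40, 200]: the leading error term is
    # (h - c)^3 / (12 d^2), at most ~0.08 bpm with d = 1000.
    c, d = 100.0, 1000.0
    return dict(
        sigmoid_a=c - 2 * d + shift,
        sigmoid_b=c + 2 * d + shift,
        sigmoid_c=c,
        sigmoid_d=d,
    )


ERROR_PRESETS: dict[str, DeviceErrorModel] = {
    # Pass-through configuration for null-pipeline checks.
    "identity-clean": DeviceErrorModel(**_identity_sigmoid()),
    # Identity shape with realistic channel noise.
    "identity-noisy": DeviceErrorModel(
        rr_jitter_sd_ms=5.0,
        test_noise_sd=3.0,
        test_dropout_prob=0.03,
        **_identity_sigmoid(),
    ),
    # Uniform +6 bpm test-channel bias, used for bias-recovery studies.
    "identity-bias6": DeviceErrorModel(
        rr_jitter_sd_ms=5.0,
        test_noise_sd=3.0,
        test_dropout_prob=0.0,
        **_identity_sigmoid(shift=6.0),
    ),
    # The study condition: monotone saturating wrist-device distortion.
    "saturating": DeviceErrorModel(
        rr_jitter_sd_ms=5.0,
        sigmoid_a=20.0,
        sigmoid_b=160.0,
        sigmoid_c=100.0,
        sigmoid_d=30.0,
        test_noise_sd=3.0,
        test_dropout_prob=0.03,
    ),
}


def error_preset(name: str) -> DeviceErrorModel:
    try:
        return ERROR_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown error preset {name!r}; available: {sorted(ERROR_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class CohortConfig:
    participants: tuple[ParticipantProfile, ...]
    protocol: SessionProtocol = field(default_factory=default_protocol)
    error: DeviceErrorModel = field(
        default_factory=lambda: error_preset("saturating")
    )

    @property
    def n_sessions(self) -> int:
        return sum(p.n_sessions for p in self.participants)


# Default cohort: 11 participants with the study's ages and per-participant
# session counts (595 sessions in total); resting HRs are fixed plausible
# values for sedentary-to-active older adults.
_TABLE1_AGES = (58, 73, 60, 63, 63, 76, 56, 68, 67, 67, 68)
_TABLE1_SESSIONS = (81, 43, 55, 38, 56, 98, 61, 28, 43, 56, 36)
_TABLE1_RESTING = (62, 68, 60, 65, 63, 70, 58, 66, 64, 61, 67)


def _table1_participants() -> tuple[ParticipantProfile, ...]:
    return tuple(
        ParticipantProfile(f"P{i + 1:02d}", age, rest, n)
        for i, (age, n, rest) in enumerate(
            zip(_TABLE1_AGES, _TABLE1_SESSIONS, _TABLE1_RESTING)
        )
    )


COHORT_PRESETS: dict[str, CohortConfig] = {
    "table1-cohort": CohortConfig(participants=_table1_participants()),
    "tiny": CohortConfig(
        participants=(
            ParticipantProfile("P01", 60, 62.0, 3),
            ParticipantProfile("P02", 70, 66.0, 3),
        ),
        error=error_preset("identity-noisy"),
    ),
}


def cohort_preset(name: str, *, error: DeviceErrorModel | None = None) -> CohortConfig:
    try:
        cfg = COHORT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown cohort preset {name!r}; available: {sorted(COHORT_PRESETS)}"
        ) from None
    return cfg if error is None else replace(cfg, error=error)


def session_seed(master_seed: int, participant_id: str, session_index: int) -> int:
    """Stable per-session seed independent of generation order."""
    key = f"{master_seed}:{participant_id}:{session_index}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_EPOCH = datetime(2023, 1, 2, 10, 0, 0)


def _session_start(p_index: int, s_index: int) -> datetime:
    # Three sessions a week per participant, staggered by participant.
    return _EPOCH + timedelta(days=2 * s_index, minutes=75 * p_index)


def _iso(ts: datetime, offsets_s: np.ndarray) -> np.ndarray:
    base = np.datetime64(ts, "ms")
    ms = np.round(np.asarray(offsets_s, dtype=float) * 1000.0).astype("timedelta64[ms]")
    return np.datetime_as_string(base + ms, unit="ms")


def generate_cohort(
    config: CohortConfig, master_seed: int, out_dir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a full synthetic cohort dataset to ``out_dir``.

    Produces ``participants.csv``, ``manifest.csv``, one reference and one
    test stream CSV per session under ``streams/``, and a ground-truth
    sidecar ``truth.csv`` with the latent minute-mean HR of every session.
    Returns the participant table and the manifest as DataFrames.
    """
    out = Path(out_dir)
    streams = out / "streams"
    try:
        streams.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {streams}: {exc}") from exc

    manifest_rows = []
    truth_frames = []
    for p_index, prof in enumerate(config.participants):
        for s_index in range(prof.n_sessions):
            sid = f"{prof.participant_id}_s{s_index:03d}"
            seed = session_seed(master_seed, prof.participant_id, s_index)
            traj = simulate_true_hr(prof, config.protocol, seed)
            ref = emit_reference_rr(traj, config.error, seed + 1)
            test = emit_test_minutes(traj, config.error, seed + 2)
            start = _session_start(p_index, s_index)

            ref_file = f"streams/ref_{sid}.csv"
            test_file = f"streams/test_{sid}.csv"
            pd.DataFrame(
                {
                    "timestamp_iso8601": _iso(start, ref.beat_times_s),
                    "rr_ms": np.round(ref.rr_ms, 3),
                }
            ).to_csv(out / ref_file, index=False)
            kept = test.mask
            pd.DataFrame(
                {
                    "timestamp_iso8601": _iso(start, test.times_s[kept]),
                    "hr_bpm": np.round(test.hr[kept], 3),
                }
            ).to_csv(out / test_file, index=False)

            manifest_rows.append(
                {
                    "session_id": sid,
                    "participant_id": prof.participant_id,
                    "start_iso8601": start.isoformat(timespec="seconds"),
                    "reference_file": ref_file,
                    "test_file": test_file,
                }
            )
            means = traj.minute_means()
            truth_frames.append(
                pd.DataFrame(
                    {
                        "session_id": sid,
                        "minute_index": np.arange(means.size),
                        "true_hr_bpm": means,
                    }
                )
            )

    participants = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in config.participants],
            "age_years": [p.age for p in config.participants],
        }
    )
    manifest = pd.DataFrame(manifest_rows)
    participants.to_csv(out / "participants.csv", index=False)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(out / "truth.csv", index=False)
    return participants, manifest


# ---------------------------------------------------------------------------
# Fast session-mean simulator for Monte-Carlo studies
# ---------------------------------------------------------------------------

def simulate_session_means(
    config: CohortConfig, master_seed: int
) -> pd.DataFrame:
    """Draw session-level (reference, test) HR means without full streams.

    A light-weight counterpart of the stream pipeline for Monte-Carlo
    studies: per session it draws the reference baseline mean around the
    participant's resting HR and the high-intensity mean around the
    protocol's high-phase target, then applies the same sigmoid distortion
    and minute-noise model (noise SD shrunk by sqrt(20) for the 20-minute
    average) to obtain the test-channel means.
    """
    rng = np.random.default_rng(master_seed)
    high = max(
        (p for p in config.protocol.phases if p.label == "high"),
        key=lambda p: p.intensity,
        default=None,
    )
    if high is None:
        raise ValueError("protocol has no high-intensity phase")
    err = config.error
    rows = []
    for prof in config.participants:
        reserve = 220.0 - prof.age - prof.resting_hr
        n = prof.n_sessions
        ref_base = rng.normal(prof.resting_hr, 2.0, size=n)
        ref_high = rng.normal(prof.resting_hr + high.intensity * reserve, 3.0, size=n)
        sd20 = err.test_noise_sd / np.sqrt(20.0)
        test_base = err.distort(ref_base) + rng.normal(0.0, sd20, size=n)
        test_high = err.distort(ref_high) + rng.normal(0.0, sd20, size=n)
        for i in range(n):
            rows.append(
                {
                    "session_id": f"{prof.participant_id}_s{i:03d}",
                    "participant_id": prof.participant_id,
                    "age": prof.age,
                    "baseline_ref": ref_base[i],
                    "baseline_test": test_base[i],
                    "peak20_ref": ref_high[i],
                    "peak20_test": test_high[i],
                }
            )
    return pd.DataFrame(rows)
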