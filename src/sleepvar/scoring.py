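"""Minute-epoch actigraphy sleep/wake scoring and night-level sleep measures.

The scorer is the zero-crossing-mode linear filter used by wrist actigraphs of
the Cole-Kripke family: each minute receives a score

    S = 0.0033 * (1.06*a[-4] + 0.54*a[-3] + 0.58*a[-2] + 0.76*a[-1]
                  + 2.3*a[0] + 0.74*a[+1] + 0.67*a[+2])

over a seven-minute window of activity counts (four preceding minutes, the
current minute, two following minutes) and is labelled sleep when S < 1.
Raw labels are then cleaned with the Webster rescoring rules, the nightly
sleep period is detected as the span between the first and last sufficiently
long sleep run, and four night-level measures are derived: sleep start
(minutes relative to midnight, negative before midnight), sleep duration,
number of awakenings, and sleep efficiency.  Sleep duration and start can be
age-adjusted against National Sleep Foundation recommendations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# epoch labels
WAKE = 0
SLEEP = 1
UNDEFINED = -1

#: filter weights for minutes t-4 .. t+2
SCORE_WEIGHTS = np.array([1.06, 0.54, 0.58, 0.76, 2.3, 0.74, 0.67])
SCORE_SCALE = 0.0033
SLEEP_THRESHOLD = 1.0

#: minutes at the start/end of a series without a full window
N_BEFORE = 4
N_AFTER = 2


@dataclass
class EpochSeries:
    """One participant-night of contiguous minute-resolution epochs."""

    participant_id: str
    night_date: dt.date                 # calendar date the night is assigned to
    start_offset_min: int               # minutes of epoch 0 relative to midnight of night_date
    activity: np.ndarray                # zero-crossing counts, one per minute
    light: np.ndarray                   # ambient light, one per minute
    offwrist: np.ndarray                # bool, one per minute

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity)
        self.light = np.asarray(self.light)
        self.offwrist = np.asarray(self.offwrist, dtype=bool)
        n = len(self.activity)
        if len(self.light) != n or len(self.offwrist) != n:
            raise ValueError("activity, light and offwrist must have equal length")
        if np.any(self.activity < 0) or np.any(self.light < 0):
            raise ValueError("activity and light must be non-negative")

    def __len__(self) -> int:
        return len(self.activity)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        midnight = pd.Timestamp(self.night_date)
        start = midnight + pd.Timedelta(minutes=self.start_offset_min)
        return pd.date_range(start, periods=len(self), freq="min")


@dataclass
class AgeNorm:
    """One age band of the National Sleep Foundation recommendations."""

    age_lo: int
    age_hi: int | None                  # inclusive; None = open-ended
    recommended_duration: int           # minutes
    recommended_start: int              # minutes relative to midnight

    def contains(self, age: float) -> bool:
        if age < self.age_lo:
            return False
        return self.age_hi is None or age <= self.age_hi


#: NSF recommended sleep duration and start by age band
DEFAULT_AGE_NORMS: tuple[AgeNorm, ...] = (
    AgeNorm(6, 13, 600, -210),
    AgeNorm(14, 17, 540, -150),
    AgeNorm(18, None, 480, -90),
)


@dataclass
class SleepPeriod:
    start: int | None                   # index into the label array, inclusive
    end: int | None                     # index, inclusive
    valid: bool
    reason: str | None = None


@dataclass
class NightRecord:
    """Per-night derived sleep measures."""

    participant_id: str
    date: dt.date
    sleep_start: float | None           # minutes relative to midnight (negative = before)
    sleep_end: float | None             # exclusive end, same reference
    duration: float | None              # minutes, = sleep_end - sleep_start
    awakenings: int | None
    efficiency: float | None            # percent in [0, 100]
    valid: bool
    invalid_reason: str | None = None


def score_minute(window7: Sequence[float]) -> tuple[float, int]:
    """Score a single minute from its seven-minute activity window.

    Parameters
    ----------
    window7
        Activity counts for minutes t-4, t-3, t-2, t-1, t, t+1, t+2.

    Returns
    -------
    (s_value, label) where label is SLEEP iff s_value < 1.
    """
    w = np.asarray(window7, dtype=float)
    if w.shape != (7,):
        raise ValueError("window must contain exactly 7 activity counts")
    if np.any(w < 0):
        raise ValueError("activity counts must be non-negative")
    s = SCORE_SCALE * float(SCORE_WEIGHTS @ w)
    return s, (SLEEP if s < SLEEP_THRESHOLD else WAKE)


def score_series(series: EpochSeries) -> np.ndarray:
    """Label every minute of a series as SLEEP / WAKE / UNDEFINED.

    The first four and last two minutes lack a full window and are UNDEFINED,
    as are off-wrist minutes.
    """
    n = len(series)
    if n < N_BEFORE + N_AFTER + 1:
        raise ValueError("series must contain at least 7 minutes")
    s = SCORE_SCALE * np.correlate(series.activity.astype(float), SCORE_WEIGHTS, mode="valid")
    labels = np.full(n, UNDEFINED, dtype=np.int8)
    core = np.where(s < SLEEP_THRESHOLD, SLEEP, WAKE).astype(np.int8)
    labels[N_BEFORE:n - N_AFTER] = core
    labels[series.offwrist] = UNDEFINED
    return labels


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode: list of (value, start, length)."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


# Webster rescoring rules: (min preceding wake minutes, sleep minutes rescored)
_WAKE_TAIL_RULES = ((15, 4), (10, 3), (4, 1))
# (max sleep-bout length, min wake minutes required on both sides)
_BOUT_RULES = ((6, 10), (10, 20))


def _rescore_once(labels: np.ndarray) -> np.ndarray:
    runs = _runs(labels)
    out = labels.copy()
    for i, (val, start, length) in enumerate(runs):
        if val == WAKE:
            # rules a-c: rescore the first sleep minutes after a long wake run
            n_rescore = 0
            for min_wake, n in _WAKE_TAIL_RULES:
                if length >= min_wake:
                    n_rescore = n
                    break
            if n_rescore and i + 1 < len(runs):
                nval, nstart, nlen = runs[i + 1]
                if nval == SLEEP:
                    out[nstart:nstart + min(n_rescore, nlen)] = WAKE
        elif val == SLEEP and 0 < i < len(runs) - 1:
            # rules d-e: short sleep bouts flanked by long wake on both sides
            pval, _, plen = runs[i - 1]
            nval, _, nlen = runs[i + 1]
            if pval == WAKE and nval == WAKE:
                for max_len, min_wake in _BOUT_RULES:
                    if length <= max_len and plen >= min_wake and nlen >= min_wake:
                        out[start:start + length] = WAKE
                        break
    return out


def rescore_labels(labels: np.ndarray, enabled: bool = True) -> np.ndarray:
    """Apply the Webster rescoring rules in a single pass.

    Spurious sleep minutes adjacent to long wake bouts are rescored wake:
    after >=4 wake minutes the next 1 sleep minute, after >=10 the next 3,
    after >=15 the next 4; sleep bouts <=6 min flanked by >=10 min of wake
    (or <=10 min flanked by >=20) are rescored entirely.  All rules are
    evaluated against the input run structure and applied at once; the rule
    set is a post-processing pass, not a fixed-point operator (iterating it
    would let the long pre-sleep wake run erode the night open-endedly).
    UNDEFINED minutes break runs and are never rescored.
    """
    labels = np.asarray(labels, dtype=np.int8)
    if not enabled:
        return labels.copy()
    return _rescore_once(labels)


def detect_sleep_period(
    labels: np.ndarray,
    light: np.ndarray | None = None,
    offwrist: np.ndarray | None = None,
    min_run_minutes: int = 20,
    light_threshold: float | None = None,
    override: tuple[int, int] | None = None,
) -> SleepPeriod:
    """Detect the nightly sleep period from rescored labels.

    The period spans from the first minute of the first run of at least
    ``min_run_minutes`` consecutive sleep minutes to the last minute of the
    last such run.  A run is disqualified when it contains off-wrist minutes
    or (with ``light_threshold`` set) its median ambient light exceeds the
    threshold.  ``override`` supplies externally determined (start, end)
    indices, standing in for the expert manual adjustment step.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if override is not None:
        s, e = override
        if not (0 <= s <= e < n):
            return SleepPeriod(None, None, False, "override out of bounds")
        return SleepPeriod(int(s), int(e), True)

    qualifying = []
    for val, start, length in _runs(labels):
        if val != SLEEP or length < min_run_minutes:
            continue
        sl = slice(start, start + length)
        if offwrist is not None and np.any(np.asarray(offwrist, dtype=bool)[sl]):
            continue
        if light_threshold is not None and light is not None:
            if float(np.median(np.asarray(light)[sl])) > light_threshold:
                continue
        qualifying.append((start, start + length - 1))
    if not qualifying:
        return SleepPeriod(None, None, False, f"no sleep run >= {min_run_minutes} min")
    return SleepPeriod(qualifying[0][0], qualifying[-1][1], True)


def compute_night_measures(
    labels: np.ndarray,
    period: SleepPeriod,
    start_offset_min: int,
    participant_id: str = "",
    date: dt.date | None = None,
) -> NightRecord:
    """Derive the four night measures from labels and a detected period.

    ``start_offset_min`` places index 0 of the label array relative to the
    reference midnight, so sleep start/end come out in minutes vs. midnight
    (negative = before midnight).  An awakening is a maximal run of
    non-sleep minutes strictly inside the period that is followed by sleep;
    UNDEFINED minutes inside the period are treated as wake.  Efficiency is
    the percentage of in-period minutes labelled sleep.
    """
    if not period.valid:
        return NightRecord(participant_id, date, None, None, None, None, None,
                           valid=False, invalid_reason=period.reason or "invalid period")
    labels = np.asarray(labels)
    seg = np.where(labels[period.start:period.end + 1] == SLEEP, SLEEP, WAKE)
    length = len(seg)
    sleep_min = int(np.sum(seg == SLEEP))
    efficiency = 100.0 * sleep_min / length
    awakenings = 0
    for val, start, runlen in _runs(seg):
        if val == WAKE and start > 0 and start + runlen < length:
            awakenings += 1
    sleep_start = start_offset_min + period.start
    sleep_end = start_offset_min + period.end + 1
    return NightRecord(
        participant_id, date,
        sleep_start=float(sleep_start), sleep_end=float(sleep_end),
        duration=float(length), awakenings=awakenings,
        efficiency=efficiency, valid=True,
    )


def adjust_for_age(
    value: float,
    measure: str,
    age: float,
    norms: Iterable[AgeNorm] = DEFAULT_AGE_NORMS,
) -> float:
    """Subtract the NSF age-group recommendation from an observed value.

    ``measure`` is ``"duration"`` or ``"start"``; the recommended duration
    (or recommended start time) for the participant's age band is subtracted
    from the observed minutes.
    """
    if age < 6:
        raise ValueError("age norms are defined for ages >= 6")
    if measure not in ("duration", "start"):
        raise ValueError(f"unknown measure {measure!r}")
    for norm in norms:
        if norm.contains(age):
            ref = norm.recommended_duration if measure == "duration" else norm.recommended_start
            return value - ref
    raise ValueError(f"no age norm covers age {age}")


def score_night(
    series: EpochSeries,
    rescoring_enabled: bool = True,
    min_run_minutes: int = 20,
    light_threshold: float | None = None,
    override: tuple[int, int] | None = None,
) -> NightRecord:
    """Full per-night pipeline: score, rescore, detect, derive measures."""
    labels = score_series(series)
    labels = rescore_labels(labels, enabled=rescoring_enabled)
    period = detect_sleep_period(
        labels, light=series.light, offwrist=series.offwrist,
        min_run_minutes=min_run_minutes, light_threshold=light_threshold,
        override=override,
    )
    return compute_night_measures(
        labels, period, series.start_offset_min,
        participant_id=series.participant_id, date=series.night_date,
    )


def nights_to_frame(records: Iterable[NightRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "participant_id": r.participant_id,
            "date": r.date,
            "sleep_start_min": r.sleep_start,
            "sleep_end_min": r.sleep_end,
            "duration_min": r.duration,
            "awakenings": r.awakenings,
            "efficiency_pct": r.efficiency,
            "valid": r.valid,
            "invalid_reason": r.invalid_reason or "",
        })
    return pd.DataFrame(rows, columns=[
        "participant_id", "date", "sleep_start_min", "sleep_end_min",
        "duration_min", "awakenings", "efficiency_pct", "valid", "invalid_reason",
    ])
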