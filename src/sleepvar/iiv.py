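"""Intra-individual variability: visit-anchored one-week sleep summaries.

For every participant-visit, the valid nights falling in the half-open week
[visit - 7 days, visit) are summarized per sleep measure by mean, sample SD
(n-1 denominator) and coefficient of variation CV = SD / |mean|.  Windows
with fewer than 2 nights are excluded (``included = False``).  Sleep duration
is age-adjusted per night against the NSF recommendation before summarizing;
the constant within-age-group offset shifts the mean but leaves SD untouched
(CV of duration is computed on the adjusted values).  Sleep start is signed
(minutes vs. midnight), so its CV uses |mean| and is flagged undefined when
the mean is essentially zero.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import AgeNorm, DEFAULT_AGE_NORMS, adjust_for_age

MEASURES = ("sleep_start", "duration", "awakenings", "efficiency")

_NIGHT_COLS = {
    "sleep_start": "sleep_start_min",
    "duration": "duration_min",
    "awakenings": "awakenings",
    "efficiency": "efficiency_pct",
}

CV_EPS = 1e-9


@dataclass
class MeasureSummary:
    mean: float
    sd: float
    cv: float            # NaN when undefined
    cv_defined: bool


def summarize_measure(values: Sequence[float], eps: float = CV_EPS) -> MeasureSummary:
    """Mean, sample SD and CV of one measure over a window's nights.

    Raises ``ValueError`` below 2 values (the window is excluded upstream).
    CV = sd / |mean|; a near-zero mean makes CV undefined (NaN, flagged).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("at least 2 nights are required to summarize a window")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if abs(mean) < eps:
        return MeasureSummary(mean, sd, float("nan"), False)
    return MeasureSummary(mean, sd, sd / abs(mean), True)


def select_window(
    nights: pd.DataFrame,
    visit_date: dt.date,
    span_days: int = 7,
) -> pd.DataFrame:
    """Valid nights dated within [visit_date - span_days, visit_date), by date."""
    df = nights[nights["valid"].astype(bool)].copy()
    dates = pd.to_datetime(df["date"]).dt.date
    lo = visit_date - dt.timedelta(days=span_days)
    mask = (dates >= lo) & (dates < visit_date)
    return df[mask].sort_values("date")


def build_window_summaries(
    nights: pd.DataFrame,
    visits: pd.DataFrame,
    profiles: pd.DataFrame,
    norms: Sequence[AgeNorm] = DEFAULT_AGE_NORMS,
    span_days: int = 7,
    min_nights: int = 2,
    adjust_start: bool = False,
) -> pd.DataFrame:
    """One row per participant-visit with n_nights and the 12 summary columns.

    Columns: participant_id, visit, n_nights, included, then
    {measure}_{mean,sd,cv} for sleep_start, duration, awakenings, efficiency.
    Duration (and optionally sleep start) is NSF-age-adjusted per night
    before summarizing.  Windows with fewer than ``min_nights`` valid nights
    get included=False and NaN statistics.
    """
    ages = profiles.set_index("participant_id")["age"]
    rows = []
    for _, visit_row in visits.iterrows():
        pid = visit_row["participant_id"]
        visit_date = pd.to_datetime(visit_row["date"]).date()
        window = select_window(nights[nights["participant_id"] == pid], visit_date, span_days)
        row: dict = {"participant_id": pid, "visit": visit_row["visit"],
                     "n_nights": len(window), "included": len(window) >= min_nights}
        if len(window) >= min_nights:
            age = float(ages.get(pid, np.nan))
            for measure in MEASURES:
                vals = window[_NIGHT_COLS[measure]].to_numpy(dtype=float)
                if measure == "duration" and np.isfinite(age):
                    vals = np.array([adjust_for_age(v, "duration", age, norms) for v in vals])
                elif measure == "sleep_start" and adjust_start and np.isfinite(age):
                    vals = np.array([adjust_for_age(v, "start", age, norms) for v in vals])
                s = summarize_measure(vals)
                row[f"{measure}_mean"] = s.mean
                row[f"{measure}_sd"] = s.sd
                row[f"{measure}_cv"] = s.cv
        else:
            for measure in MEASURES:
                for stat in ("mean", "sd", "cv"):
                    row[f"{measure}_{stat}"] = np.nan
        rows.append(row)
    cols = ["participant_id", "visit", "n_nights", "included"]
    cols += [f"{m}_{s}" for m in MEASURES for s in ("mean", "sd", "cv")]
    return pd.DataFrame(rows, columns=cols)
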