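"""Seeded synthetic cohort generator for actigraphy sleep studies in ASD.

Generates participant profiles (age, sex, IQ, autism severity), per-participant
sleep architecture, minute-resolution actigraphy nights with known ground
truth, realistic partial wear compliance, and caregiver-reported scale scores
coupled to the realized sleep-variability statistics.  Every generator is a
pure function of its arguments and a seed, so downstream scoring, aggregation
and modelling stages can be validated against the planted truth.

The sleep/wake activity regimes are deliberately simple: wake minutes draw
overdispersed zero-crossing counts from a negative binomial, sleep minutes
from a zero-inflated Poisson, which is all the linear sleep scorer needs to
separate the regimes.  Awakening episodes are a Poisson count of geometric-
length wake bouts placed uniformly (non-overlapping, with at least one sleep
minute between bouts) inside the true sleep interval.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import EpochSeries

ASD = "ASD"
TD = "TD"

#: night series span, minutes relative to the night's reference midnight
SERIES_START_MIN = -360   # 18:00 the previous evening
SERIES_END_MIN = 720      # 12:00 noon

#: distribution of nights worn per 7-day visit window (nights 0..7),
#: proportional to the observed wear pattern at the study midpoint
TABLE4_MIDPOINT_PATTERN = np.array([0, 0, 21, 12, 10, 9, 2, 4]) / 58.0
TABLE4_ENDPOINT_PATTERN = np.array([0, 0, 14, 5, 6, 9, 4, 0]) / 38.0


@dataclass
class ParticipantProfile:
    participant_id: str
    group: str                     # ASD or TD
    age: int                       # years, >= 6
    sex: str                       # "male" / "female"
    iq: int                        # KBIT-2 composite
    ados_css: int | None = None    # 1-10, ASD only

    def __post_init__(self) -> None:
        if self.group not in (ASD, TD):
            raise ValueError(f"group must be ASD or TD, got {self.group!r}")
        if self.age < 6:
            raise ValueError("age must be >= 6")
        if (self.ados_css is not None) != (self.group == ASD):
            raise ValueError("ados_css must be present iff group is ASD")


@dataclass
class SleepArchitecture:
    """Per-participant latent sleep parameters."""

    mean_bedtime: float            # minutes vs midnight, negative = before
    bedtime_sd: float              # night-to-night SD of bedtime
    mean_duration: float           # minutes
    duration_sd: float
    awakening_rate: float          # expected wake episodes per night
    awakening_length_mean: float   # minutes, geometric mean length
    latent_quality: float = 0.0    # unitless, drives scale coupling
    #: episode-free consolidation margin (min) after sleep onset and before
    #: the final waking, emulating consolidated sleep at the period edges
    boundary_margin: float = 25.0

    def __post_init__(self) -> None:
        if self.mean_duration <= 0:
            raise ValueError("mean_duration must be positive")
        if self.awakening_rate < 0 or self.bedtime_sd < 0 or self.duration_sd < 0:
            raise ValueError("rates and SDs must be non-negative")


@dataclass
class ScaleCoupling:
    """Generative model of the anxiety scale from observable sleep statistics.

    CASI-Anx = intercept + beta_abi_sleep * ABI_sleep
             + beta_sd_efficiency * SD(efficiency)
             + beta_cv_awakenings * CV(awakenings) + N(0, noise_sd),
    clipped to the instrument range.
    """

    intercept: float = 8.0
    beta_abi_sleep: float = 2.5
    beta_sd_efficiency: float = 3.0
    beta_cv_awakenings: float = 8.0
    noise_sd: float = 2.5
    scale_ranges: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "casi_anx": (0, 63),
        "srs2": (0, 195),
        "abc_irritability": (0, 45),
        "abc_hyperactivity": (0, 48),
        "abi_sleep": (0, 7),
    })

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ActivityModel:
    """Activity-count and light regimes for wake vs. sleep minutes."""

    wake_mean: float = 180.0       # negative-binomial mean (zero-crossing counts)
    wake_dispersion: float = 5.0   # NB shape; smaller = more overdispersed
    sleep_zero_prob: float = 0.65  # zero inflation during sleep
    sleep_mean: float = 12.0       # Poisson mean of non-zero sleep minutes
    light_wake_scale: float = 120.0
    light_sleep_scale: float = 1.0


@dataclass
class CohortParams:
    """Population-level defaults emulating the study cohort's demographics
    and sleep summaries (ages right-skewed with mean 14.5 / median 12,
    sleep duration ~481 min, sleep start ~-81 min, ~17.5 awakenings/night,
    efficiency ~91%)."""

    # demographics
    asd_age_mean: float = 14.5
    asd_age_sd: float = 7.91
    td_age_mean: float = 11.4
    td_age_sd: float = 5.38
    age_min: int = 6
    asd_male_fraction: float = 0.777
    td_male_fraction: float = 0.74
    iq_mean: float = 99.0
    iq_sd: float = 19.55
    ados_mean: float = 7.59
    ados_sd: float = 1.74
    # sleep architecture population
    bedtime_mean: float = -81.0
    bedtime_between_sd: float = 60.0
    bedtime_within_sd: float = 40.0
    duration_mean: float = 481.0
    duration_between_sd: float = 55.0
    duration_within_sd: float = 45.0
    awakening_rate_mean: float = 17.5
    awakening_rate_sd: float = 6.2
    awakening_rate_quality_loading: float = -0.6   # share of rate SD driven by latent quality
    awakening_length_mean: float = 2.5
    # caregiver-reported sleep item (ordinal 0-7)
    abi_asd_mean: float = 3.45
    abi_asd_quality_slope: float = -1.3
    abi_asd_noise_sd: float = 1.4
    abi_td_mean: float = 1.05
    abi_td_noise_sd: float = 1.2
    activity: ActivityModel = field(default_factory=ActivityModel)


@dataclass
class NightTruth:
    """Ground truth for one generated night."""

    participant_id: str
    date: dt.date
    true_start: float              # minutes vs midnight
    true_end: float                # exclusive
    true_duration: float
    n_awakenings: int
    wake_minutes: int              # total awakening minutes inside the interval
    true_efficiency: float         # percent
    episodes: list[tuple[int, int]] = field(default_factory=list)  # (start_min, length)


def _subseed(seed: int, *parts: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, parts)]))


def generate_profiles(
    n_asd: int,
    n_td: int,
    seed: int,
    params: CohortParams | None = None,
) -> list[ParticipantProfile]:
    """Draw participant profiles from the configured population.

    Ages follow a shifted gamma (support >= ``age_min``) matching the target
    mean and SD, which reproduces the right-skew of the study population;
    sex is Bernoulli with group-specific male fraction; IQ and ADOS CSS are
    rounded truncated normals.
    """
    if n_asd < 0 or n_td < 0:
        raise ValueError("participant counts must be non-negative")
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    profiles: list[ParticipantProfile] = []
    specs = [(ASD, n_asd, params.asd_age_mean, params.asd_age_sd, params.asd_male_fraction),
             (TD, n_td, params.td_age_mean, params.td_age_sd, params.td_male_fraction)]
    for group, n, age_mean, age_sd, male_frac in specs:
        excess = age_mean - params.age_min
        k = (excess / age_sd) ** 2
        theta = excess / k if k > 0 else 1.0
        for i in range(n):
            age = int(round(params.age_min + rng.gamma(k, theta)))
            sex = "male" if rng.random() < male_frac else "female"
            iq = int(np.clip(round(rng.normal(params.iq_mean, params.iq_sd)), 40, 160))
            ados = None
            if group == ASD:
                ados = int(np.clip(round(rng.normal(params.ados_mean, params.ados_sd)), 1, 10))
            profiles.append(ParticipantProfile(
                participant_id=f"{group}-{i + 1:03d}", group=group,
                age=age, sex=sex, iq=iq, ados_css=ados,
            ))
    return profiles


def generate_architecture(
    seed: int,
    params: CohortParams | None = None,
) -> SleepArchitecture:
    """Draw one participant's sleep architecture; the latent quality scalar
    loads negatively on the awakening rate so that poorer sleepers have more
    fragmented nights."""
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    q = rng.normal()
    load = params.awakening_rate_quality_loading
    resid = np.sqrt(max(0.0, 1.0 - load ** 2))
    rate = params.awakening_rate_mean + params.awakening_rate_sd * (load * q + resid * rng.normal())
    return SleepArchitecture(
        mean_bedtime=rng.normal(params.bedtime_mean, params.bedtime_between_sd),
        bedtime_sd=params.bedtime_within_sd,
        mean_duration=max(240.0, rng.normal(params.duration_mean, params.duration_between_sd)),
        duration_sd=params.duration_within_sd,
        awakening_rate=float(np.clip(rate, 0.5, 45.0)),
        awakening_length_mean=params.awakening_length_mean,
        latent_quality=float(q),
    )


def _place_episodes(
    rng: np.random.Generator,
    interval_start: int,
    interval_end: int,
    rate: float,
    length_mean: float,
    margin: float = 0.0,
) -> list[tuple[int, int]]:
    """Place a Poisson number of non-overlapping geometric-length wake bouts
    uniformly inside the sleep interval, separated by at least one sleep
    minute and keeping ``margin`` episode-free minutes at both interval edges.

    Sampling in the gap-reduced space keeps the realized episode count equal
    to the Poisson draw (rejection of overlaps would bias the count down).
    """
    duration = interval_end - interval_start
    margin = int(min(margin, max(duration // 4, 1)))
    lo, hi = interval_start + max(1, margin), interval_end - max(1, margin)
    space = hi - lo
    if space <= 0 or rate <= 0:
        return []
    k = int(rng.poisson(rate))
    if k == 0:
        return []
    p = 1.0 / max(length_mean, 1.0)
    for _ in range(100):
        lengths = rng.geometric(p, size=k)
        free = space - int(lengths.sum()) - (k - 1)
        if free >= 0:
            break
        k -= 1   # interval too crowded; very rare at realistic rates
        if k == 0:
            return []
        lengths = lengths[:k]
    offsets = np.sort(rng.uniform(0, free + 1, size=k))
    episodes = []
    cum = 0
    for i in range(k):
        start = lo + int(offsets[i]) + cum + i
        episodes.append((start, int(lengths[i])))
        cum += int(lengths[i])
    return episodes


def generate_night(
    arch: SleepArchitecture,
    date: dt.date,
    seed: int,
    participant_id: str = "P",
    activity: ActivityModel | None = None,
) -> tuple[EpochSeries, NightTruth]:
    """Generate one minute-resolution night (18:00 to noon) plus its truth.

    The true sleep interval is drawn from the architecture; awakening
    episodes are planted inside it; activity counts come from the wake
    (negative binomial) or sleep (zero-inflated Poisson) regime; ambient
    light is high outside the sleep interval and near zero inside.
    """
    activity = activity or ActivityModel()
    rng = np.random.default_rng(seed)
    n = SERIES_END_MIN - SERIES_START_MIN
    bedtime = rng.normal(arch.mean_bedtime, arch.bedtime_sd)
    bedtime = float(np.clip(bedtime, SERIES_START_MIN + 60, 300))
    duration = rng.normal(arch.mean_duration, arch.duration_sd)
    duration = float(np.clip(duration, 60, SERIES_END_MIN - 20 - bedtime))
    start = int(round(bedtime))
    end = int(round(bedtime + duration))          # exclusive, minutes vs midnight
    episodes = _place_episodes(rng, start, end, arch.awakening_rate,
                               arch.awakening_length_mean, arch.boundary_margin)

    asleep = np.zeros(n, dtype=bool)
    i0 = start - SERIES_START_MIN
    i1 = end - SERIES_START_MIN
    asleep[i0:i1] = True
    for ep_start, ep_len in episodes:
        j = ep_start - SERIES_START_MIN
        asleep[j:j + ep_len] = False

    counts = np.empty(n, dtype=np.int64)
    n_sleep = int(asleep.sum())
    nb_p = activity.wake_dispersion / (activity.wake_dispersion + activity.wake_mean)
    counts[~asleep] = rng.negative_binomial(activity.wake_dispersion, nb_p, size=n - n_sleep)
    sleep_counts = rng.poisson(activity.sleep_mean, size=n_sleep)
    sleep_counts[rng.random(n_sleep) < activity.sleep_zero_prob] = 0
    counts[asleep] = sleep_counts

    in_interval = np.zeros(n, dtype=bool)
    in_interval[i0:i1] = True
    light = np.where(
        in_interval,
        rng.exponential(activity.light_sleep_scale, size=n),
        rng.exponential(activity.light_wake_scale, size=n),
    )

    series = EpochSeries(
        participant_id=participant_id, night_date=date,
        start_offset_min=SERIES_START_MIN,
        activity=counts, light=light, offwrist=np.zeros(n, dtype=bool),
    )
    wake_minutes = int(sum(l for _, l in episodes))
    truth = NightTruth(
        participant_id=participant_id, date=date,
        true_start=float(start), true_end=float(end),
        true_duration=float(end - start),
        n_awakenings=len(episodes), wake_minutes=wake_minutes,
        true_efficiency=100.0 * (end - start - wake_minutes) / (end - start),
        episodes=episodes,
    )
    return series, truth


def generate_compliance(
    n_nights_available: int,
    pattern: Sequence[float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw which of the available nights were actually worn.

    ``pattern`` is a probability distribution over the number of nights worn
    (support 0..7, default proportional to the observed midpoint wear
    pattern).  Returns sorted 0-based night indices.
    """
    if pattern is None:
        pattern = TABLE4_MIDPOINT_PATTERN
    pattern = np.asarray(pattern, dtype=float)
    if pattern.ndim != 1 or len(pattern) != 8 or np.any(pattern < 0) or not np.isclose(pattern.sum(), 1.0):
        raise ValueError("pattern must be a non-negative distribution over 0..7 nights")
    rng = np.random.default_rng(seed)
    k = min(int(rng.choice(8, p=pattern)), n_nights_available)
    return np.sort(rng.choice(n_nights_available, size=k, replace=False))


@dataclass
class RealizedWindow:
    """Observable per-visit summary statistics the scale coupling acts on."""

    n_nights: int
    sd_efficiency: float
    cv_awakenings: float


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1))


def realized_window_from_truth(truths: Sequence[NightTruth]) -> RealizedWindow | None:
    """Summarize ground-truth nights into the coupling statistics (requires
    at least 2 nights, mirroring the downstream inclusion filter)."""
    if len(truths) < 2:
        return None
    eff = np.array([t.true_efficiency for t in truths])
    awak = np.array([t.n_awakenings for t in truths], dtype=float)
    mean_awak = abs(float(np.mean(awak)))
    cv = _sample_sd(awak) / mean_awak if mean_awak > 1e-9 else 0.0
    return RealizedWindow(len(truths), _sample_sd(eff), cv)


def generate_abi_sleep(
    group: str,
    latent_quality: float,
    seed: int,
    params: CohortParams | None = None,
    bounds: tuple[int, int] = (0, 7),
) -> int:
    """Ordinal caregiver-reported sleep-problem item (default 0-7 scale)."""
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    if group == ASD:
        raw = (params.abi_asd_mean + params.abi_asd_quality_slope * latent_quality
               + rng.normal(0, params.abi_asd_noise_sd))
    else:
        raw = params.abi_td_mean + rng.normal(0, params.abi_td_noise_sd)
    return int(np.clip(round(raw), bounds[0], bounds[1]))


def generate_scales(
    profile: ParticipantProfile,
    realized_window: RealizedWindow | None,
    abi_sleep: int,
    coupling: ScaleCoupling,
    seed: int,
    latent_quality: float = 0.0,
) -> dict[str, float]:
    """Generate one visit's caregiver scale scores.

    The anxiety score is a linear function of the caregiver sleep item and
    the realized (observable) variability statistics; the remaining scales
    load on the latent sleep quality only.  All scores are clipped to their
    instrument ranges.
    """
    if realized_window is None:
        raise ValueError("realized_window is required (compute it from the generated nights)")
    rng = np.random.default_rng(seed)
    lo, hi = coupling.scale_ranges["casi_anx"]
    casi = (coupling.intercept
            + coupling.beta_abi_sleep * abi_sleep
            + coupling.beta_sd_efficiency * realized_window.sd_efficiency
            + coupling.beta_cv_awakenings * realized_window.cv_awakenings
            + rng.normal(0, coupling.noise_sd))
    q = latent_quality
    srs = 95 - 15 * q + rng.normal(0, 20)
    irrit = 12 - 4 * q + rng.normal(0, 6)
    hyper = 17 - 5 * q + rng.normal(0, 7)
    r = coupling.scale_ranges
    return {
        "casi_anx": float(np.clip(casi, lo, hi)),
        "srs2": float(np.clip(srs, *r["srs2"])),
        "abc_irritability": float(np.clip(irrit, *r["abc_irritability"])),
        "abc_hyperactivity": float(np.clip(hyper, *r["abc_hyperactivity"])),
    }


@dataclass
class CohortData:
    profiles: pd.DataFrame
    epochs: list[EpochSeries]
    truth_nights: pd.DataFrame
    visits: pd.DataFrame              # participant_id, visit, date
    scales: pd.DataFrame              # participant_id, visit, abi_sleep, casi_anx, ...
    coupling: ScaleCoupling


def profiles_to_frame(profiles: Sequence[ParticipantProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": p.participant_id, "group": p.group, "age": p.age,
        "sex": p.sex, "iq": p.iq,
        "ados_css": p.ados_css if p.ados_css is not None else np.nan,
    } for p in profiles], columns=["participant_id", "group", "age", "sex", "iq", "ados_css"])


def truths_to_frame(truths: Sequence[NightTruth]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": t.participant_id, "date": t.date,
        "true_start_min": t.true_start, "true_end_min": t.true_end,
        "true_duration_min": t.true_duration, "n_awakenings": t.n_awakenings,
        "wake_minutes": t.wake_minutes, "true_efficiency_pct": t.true_efficiency,
    } for t in truths], columns=[
        "participant_id", "date", "true_start_min", "true_end_min",
        "true_duration_min", "n_awakenings", "wake_minutes", "true_efficiency_pct"])


def generate_cohort(
    n_asd: int = 139,
    n_td: int = 34,
    seed: int = 0,
    params: CohortParams | None = None,
    coupling: ScaleCoupling | None = None,
    study_start: dt.date = dt.date(2015, 9, 1),
    midpoint_day: int = 28,
    endpoint_day: int = 56,
    compliance_patterns: Mapping[str, Sequence[float]] | None = None,
    p_insufficient: Mapping[str, float] | None = None,
) -> CohortData:
    """Generate a full synthetic cohort.

    ASD participants contribute actigraphy nights in the 7-day windows before
    the midpoint and endpoint visits; whether a participant reaches the
    >=2-night bar in a window is Bernoulli (defaults 81/139 and 101/139 of
    falling short, matching the observed attrition), and the nights-worn
    count for sufficient wearers follows the per-visit wear pattern.
    Caregiver scales are generated at baseline, midpoint and endpoint; the
    anxiety score at actigraphy visits is coupled to the realized window
    statistics.  TD participants contribute the caregiver sleep item at a
    single (baseline) visit only.
    """
    params = params or CohortParams()
    coupling = coupling or ScaleCoupling()
    compliance_patterns = compliance_patterns or {
        "midpoint": TABLE4_MIDPOINT_PATTERN, "endpoint": TABLE4_ENDPOINT_PATTERN}
    p_insufficient = p_insufficient or {"midpoint": 81 / 139, "endpoint": 101 / 139}
    visit_days = {"midpoint": midpoint_day, "endpoint": endpoint_day}

    profiles = generate_profiles(n_asd, n_td, seed, params)
    epochs: list[EpochSeries] = []
    truths: list[NightTruth] = []
    visit_rows = []
    scale_rows = []

    for pi, prof in enumerate(profiles):
        arch = generate_architecture(_subseed(seed, 1, pi).integers(2 ** 31), params)
        q = arch.latent_quality
        if prof.group == TD:
            rng = _subseed(seed, 2, pi)
            abi = generate_abi_sleep(TD, q, rng.integers(2 ** 31), params)
            scale_rows.append({"participant_id": prof.participant_id, "visit": "baseline",
                               "abi_sleep": abi, "casi_anx": np.nan, "srs2": np.nan,
                               "abc_irritability": np.nan, "abc_hyperactivity": np.nan})
            continue

        truths_by_visit: dict[str, list[NightTruth]] = {}
        for vi, (visit, day) in enumerate(visit_days.items()):
            visit_date = study_start + dt.timedelta(days=day)
            visit_rows.append({"participant_id": prof.participant_id,
                               "visit": visit, "date": visit_date})
            rng = _subseed(seed, 3, pi, vi)
            if rng.random() < p_insufficient[visit]:
                k = int(rng.integers(0, 2))     # 0 or 1 nights: excluded downstream
                worn = np.sort(rng.choice(7, size=k, replace=False))
            else:
                worn = generate_compliance(7, compliance_patterns[visit],
                                           int(rng.integers(2 ** 31)))
            vis_truths = []
            for offset in worn:
                night_date = visit_date - dt.timedelta(days=int(7 - offset))
                series, truth = generate_night(
                    arch, night_date, int(_subseed(seed, 4, pi, vi, int(offset)).integers(2 ** 31)),
                    participant_id=prof.participant_id, activity=params.activity)
                epochs.append(series)
                truths.append(truth)
                vis_truths.append(truth)
            truths_by_visit[visit] = vis_truths

        for vi, visit in enumerate(["baseline", "midpoint", "endpoint"]):
            rng = _subseed(seed, 5, pi, vi)
            abi = generate_abi_sleep(ASD, q, int(rng.integers(2 ** 31)), params)
            window = realized_window_from_truth(truths_by_visit.get(visit, []))
            if window is not None:
                scales = generate_scales(prof, window, abi, coupling,
                                         int(rng.integers(2 ** 31)), latent_quality=q)
            else:
                # no usable actigraphy window: anxiety draws on the caregiver
                # item and latent quality only (row is excluded from the
                # prediction feature table anyway)
                rng2 = np.random.default_rng(int(rng.integers(2 ** 31)))
                lo, hi = coupling.scale_ranges["casi_anx"]
                casi = (coupling.intercept + coupling.beta_abi_sleep * abi
                        - 2.0 * q + rng2.normal(0, coupling.noise_sd))
                scales = {
                    "casi_anx": float(np.clip(casi, lo, hi)),
                    "srs2": float(np.clip(95 - 15 * q + rng2.normal(0, 20), 0, 195)),
                    "abc_irritability": float(np.clip(12 - 4 * q + rng2.normal(0, 6), 0, 45)),
                    "abc_hyperactivity": float(np.clip(17 - 5 * q + rng2.normal(0, 7), 0, 48)),
                }
            scale_rows.append({"participant_id": prof.participant_id, "visit": visit,
                               "abi_sleep": abi, **scales})

    return CohortData(
        profiles=profiles_to_frame(profiles),
        epochs=epochs,
        truth_nights=truths_to_frame(truths),
        visits=pd.DataFrame(visit_rows, columns=["participant_id", "visit", "date"]),
        scales=pd.DataFrame(scale_rows, columns=[
            "participant_id", "visit", "abi_sleep", "casi_anx", "srs2",
            "abc_irritability", "abc_hyperactivity"]),
        coupling=coupling,
    )


def epochs_to_frame(epochs: Sequence[EpochSeries]) -> pd.DataFrame:
    """Long epoch table: participant_id, timestamp, activity_zcm, light, offwrist."""
    frames = []
    for s in epochs:
        frames.append(pd.DataFrame({
            "participant_id": s.participant_id,
            "timestamp": s.timestamps,
            "activity_zcm": s.activity.astype(int),
            "light": np.round(s.light, 3),
            "offwrist": s.offwrist.astype(int),
        }))
    if not frames:
        return pd.DataFrame(columns=["participant_id", "timestamp", "activity_zcm", "light", "offwrist"])
    return pd.concat(frames, ignore_index=True)


def frame_to_epochs(df: pd.DataFrame) -> list[EpochSeries]:
    """Rebuild per-night series from a long epoch table.

    Series are split at timestamp gaps (> 1 minute); the night is assigned to
    the calendar date 12 hours after the first epoch, so an 18:00-to-noon
    recording belongs to the morning's date.
    """
    out: list[EpochSeries] = []
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    for pid, g in df.groupby("participant_id", sort=True):
        g = g.sort_values("timestamp")
        gaps = g["timestamp"].diff() > pd.Timedelta(minutes=1)
        for _, chunk in g.groupby(gaps.cumsum()):
            first = chunk["timestamp"].iloc[0]
            night_date = (first + pd.Timedelta(hours=12)).date()
            midnight = pd.Timestamp(night_date)
            out.append(EpochSeries(
                participant_id=str(pid), night_date=night_date,
                start_offset_min=int((first - midnight) / pd.Timedelta(minutes=1)),
                activity=chunk["activity_zcm"].to_numpy(),
                light=chunk["light"].to_numpy(),
                offwrist=chunk["offwrist"].to_numpy().astype(bool),
            ))
    return out


def write_cohort(data: CohortData, outdir: str | Path) -> dict[str, Path]:
    """Write cohort files as delimited text; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": outdir / "profiles.csv",
        "epochs": outdir / "epochs.csv",
        "truth_nights": outdir / "truth_nights.csv",
        "visits": outdir / "visits.csv",
        "scales": outdir / "scales.csv",
        "coupling": outdir / "truth_coupling.csv",
    }
    data.profiles.to_csv(paths["profiles"], index=False)
    edf = epochs_to_frame(data.epochs)
    edf["timestamp"] = pd.to_datetime(edf["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    edf.to_csv(paths["epochs"], index=False)
    data.truth_nights.to_csv(paths["truth_nights"], index=False)
    data.visits.to_csv(paths["visits"], index=False)
    data.scales.to_csv(paths["scales"], index=False)
    cp = {k: v for k, v in asdict(data.coupling).items() if k != "scale_ranges"}
    pd.DataFrame([cp]).to_csv(paths["coupling"], index=False)
    return paths
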