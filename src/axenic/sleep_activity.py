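"""Sleep and activity scoring from beam-crossing series.

Sleep is the standard operational definition for flies: any maximal run of at
least five consecutive minutes with zero beam crossings.  Flies that do not
move for 24 consecutive hours or more are considered dead and removed.  For
profiles, the multi-day record is folded onto one 24-h cycle (anchored at
lights-on) and binned by 30 minutes; day/night summaries report crossings per
minute and sleep minutes per 30-minute bin.

Missing minutes (NaN counts) terminate zero-runs by default — an unobserved
minute is not evidence of immobility.  A permissive mode bridges missing gaps
up to a configurable length; bridged minutes count toward episode duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dams_io import BeamCountSeries

__all__ = [
    "SleepEpisode",
    "FlyDailyProfile",
    "FlyDayNightSummary",
    "detect_sleep_episodes",
    "sleep_minute_mask",
    "remove_dead_flies",
    "fold_to_daily_profile",
    "summarize_day_night",
    "group_profile_with_ci",
]


@dataclass(frozen=True)
class SleepEpisode:
    """A maximal immobile run scored as sleep.  ``start`` is a minute index."""

    fly_id: str
    start: int
    duration_min: int


@dataclass
class FlyDailyProfile:
    """One fly's 6-day record folded onto a binned 24-h cycle.

    ``bin_starts`` are minute offsets from lights-on; activity is mean
    crossings/min and sleep is mean sleep minutes per bin (0..bin width).
    """

    fly_id: str
    group: str
    bin_starts: np.ndarray
    activity_per_bin: np.ndarray
    sleep_per_bin: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.bin_starts) == len(self.activity_per_bin) == len(self.sleep_per_bin)):
            raise ValueError("profile arrays differ in length")


@dataclass(frozen=True)
class FlyDayNightSummary:
    fly_id: str
    group: str
    day_activity: float  # crossings/min
    night_activity: float
    day_sleep: float  # minutes per 30-min bin
    night_sleep: float


def _zero_run_bounds(
    counts: np.ndarray, bridge_gaps_min: int = 0
) -> list[tuple[int, int]]:
    """(start, stop) bounds of maximal zero runs; NaNs break runs unless bridged."""
    is_zero = counts == 0  # NaN compares False
    if bridge_gaps_min > 0:
        missing = ~np.isfinite(counts)
        padded = np.concatenate([[False], missing, [False]]).astype(int)
        edges = np.flatnonzero(np.diff(padded))
        for s, e in zip(edges[::2], edges[1::2]):
            if (
                e - s <= bridge_gaps_min
                and s > 0
                and e < len(counts)
                and counts[s - 1] == 0
                and counts[e] == 0
            ):
                is_zero[s:e] = True
    padded = np.concatenate([[False], is_zero, [False]]).astype(int)
    edges = np.flatnonzero(np.diff(padded))
    return list(zip(edges[::2], edges[1::2]))


def detect_sleep_episodes(
    series: BeamCountSeries,
    min_duration: int = 5,
    bridge_gaps_min: int = 0,
) -> list[SleepEpisode]:
    """All maximal zero-count runs of at least ``min_duration`` minutes.

    Runs touching the start or end of the record count if long enough.
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    return [
        SleepEpisode(series.fly_id, int(s), int(e - s))
        for s, e in _zero_run_bounds(series.counts, bridge_gaps_min)
        if e - s >= min_duration
    ]


def sleep_minute_mask(
    series: BeamCountSeries,
    min_duration: int = 5,
    bridge_gaps_min: int = 0,
) -> np.ndarray:
    """Boolean per-minute asleep mask implied by the episode definition."""
    mask = np.zeros(series.n_minutes, dtype=bool)
    for ep in detect_sleep_episodes(series, min_duration, bridge_gaps_min):
        mask[ep.start : ep.start + ep.duration_min] = True
    return mask


def remove_dead_flies(
    series: Iterable[BeamCountSeries],
    death_threshold_h: float = 24.0,
) -> tuple[list[BeamCountSeries], list[str]]:
    """Drop flies with >= ``death_threshold_h`` consecutive inactive hours.

    The boundary is inclusive (exactly 24 h of zeros removes the fly); the
    kept flies are returned untouched.  Idempotent.
    """
    if death_threshold_h <= 0:
        raise ValueError("death_threshold_h must be positive")
    threshold_min = int(round(death_threshold_h * 60))
    kept: list[BeamCountSeries] = []
    removed: list[str] = []
    for s in series:
        runs = _zero_run_bounds(s.counts)
        longest = max((e - b for b, e in runs), default=0)
        if longest >= threshold_min:
            removed.append(s.fly_id)
        else:
            kept.append(s)
    return kept, removed


def fold_to_daily_profile(
    series: BeamCountSeries,
    bin_width: int = 30,
    min_duration: int = 5,
) -> FlyDailyProfile:
    """Average the multi-day record into one binned 24-h cycle.

    Bin 0 starts at lights-on.  Per cycle bin, activity is the mean
    crossings/min over every observed minute falling in the bin and sleep is
    the mean number of asleep minutes per pass through the bin (range 0 to
    ``bin_width``).
    """
    if bin_width < 1 or 1440 % bin_width:
        raise ValueError("bin_width must divide 1440")
    if series.n_minutes < 1440:
        raise ValueError("record must span at least one full day")
    n_bins = 1440 // bin_width
    bin_of_minute = series.cycle_minute // bin_width
    observed = np.isfinite(series.counts)
    asleep = sleep_minute_mask(series, min_duration)

    activity = np.full(n_bins, np.nan)
    sleep = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = (bin_of_minute == b) & observed
        n_obs = int(sel.sum())
        if n_obs == 0:
            continue
        activity[b] = series.counts[sel].mean()
        sleep[b] = asleep[sel].sum() * bin_width / n_obs
    return FlyDailyProfile(
        fly_id=series.fly_id,
        group=series.group,
        bin_starts=np.arange(n_bins) * bin_width,
        activity_per_bin=activity,
        sleep_per_bin=sleep,
    )


def summarize_day_night(
    series: BeamCountSeries,
    min_duration: int = 5,
    bin_width: int = 30,
) -> FlyDayNightSummary:
    """Whole-record day and night activity (crossings/min) and sleep (min/30 min)."""
    observed = np.isfinite(series.counts)
    day = series.is_day & observed
    night = ~series.is_day & observed
    if day.sum() == 0 or night.sum() == 0:
        raise ValueError("record must contain observed minutes in both phases")
    asleep = sleep_minute_mask(series, min_duration)
    day_act = float(series.counts[day].sum() / day.sum())
    night_act = float(series.counts[night].sum() / night.sum())
    day_sleep = float(asleep[day].sum() * bin_width / day.sum())
    night_sleep = float(asleep[night].sum() * bin_width / night.sum())
    return FlyDayNightSummary(
        fly_id=series.fly_id,
        group=series.group,
        day_activity=day_act,
        night_activity=night_act,
        day_sleep=day_sleep,
        night_sleep=night_sleep,
    )


def group_profile_with_ci(
    profiles: Sequence[FlyDailyProfile],
    group: str,
    metric: str = "activity",
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Across-fly per-bin mean with a percentile-bootstrap CI.

    Flies — the experimental unit — are resampled, not minutes or bins.
    Returns a frame with columns bin_start, mean, ci_low, ci_high, n_flies.
    """
    if metric not in ("activity", "sleep"):
        raise ValueError("metric must be 'activity' or 'sleep'")
    chosen = [p for p in profiles if p.group == group]
    if not chosen:
        raise ValueError(f"no profiles for group {group!r}")
    attr = "activity_per_bin" if metric == "activity" else "sleep_per_bin"
    mat = np.vstack([getattr(p, attr) for p in chosen])  # (flies, bins)
    bin_starts = chosen[0].bin_starts
    mean = np.nanmean(mat, axis=0)
    if len(chosen) == 1:
        warnings.warn("single fly: degenerate zero-width confidence band")
        low = high = mean.copy()
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.integers(0, mat.shape[0], size=(n_boot, mat.shape[0]))
        boot_means = np.nanmean(mat[idx], axis=1)  # (n_boot, bins)
        alpha = 1.0 - ci_level
        low, high = np.nanquantile(boot_means, [alpha / 2, 1 - alpha / 2], axis=0)
    return pd.DataFrame(
        {
            "bin_start": bin_starts,
            "mean": mean,
            "ci_low": low,
            "ci_high": high,
            "n_flies": len(chosen),
        }
    )
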