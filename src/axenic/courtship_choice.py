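"""Two-choice courtship preference (conventional vs. germ-free female targets).

A socially naive male is offered two decapitated female bodies and observed
for an hour.  Preference is the ratio of courtship time directed at target A
(the conventional female, under the package-wide orientation) to the total
courtship time toward either target — non-courtship time does not enter the
denominator.  Trials with less than one minute of total courtship are omitted
(the boundary is inclusive: exactly 60 s stays in).  The group summary is the
sample median with a smoothed-bootstrap percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .estimation_stats import (
    EffectEstimate,
    EstimationError,
    smoothed_bootstrap_median,
)

__all__ = ["CourtshipTrial", "preference", "group_median_preference"]


@dataclass(frozen=True)
class CourtshipTrial:
    """Seconds of courtship toward each target within one observation.

    Target A is the conventional (CV) female and target B the germ-free (GF)
    female, so a preference above 0.5 means the CV female was preferred.
    """

    trial_id: str
    t_target_a: float
    t_target_b: float
    observation_s: float = 3600.0
    generation: str = ""

    def __post_init__(self) -> None:
        if self.t_target_a < 0 or self.t_target_b < 0:
            raise ValueError("courtship durations must be non-negative")
        if self.observation_s <= 0:
            raise ValueError("observation_s must be positive")
        if self.t_target_a + self.t_target_b > self.observation_s * (1 + 1e-9):
            raise ValueError("courtship time exceeds the observation window")

    @property
    def total_courtship_s(self) -> float:
        return self.t_target_a + self.t_target_b


def preference(trial: CourtshipTrial, min_total_s: float = 60.0) -> float | None:
    """t_a / (t_a + t_b), or None when the trial is excluded (< ``min_total_s``)."""
    total = trial.total_courtship_s
    if total < min_total_s:
        return None
    return float(trial.t_target_a / total)


def group_median_preference(
    trials: Iterable[CourtshipTrial],
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    min_total_s: float = 60.0,
) -> EffectEstimate:
    """Median preference of the included trials with a smoothed-bootstrap CI.

    The number of excluded trials is recorded in ``flags`` as
    ``"excluded=<k>"``.
    """
    prefs: list[float] = []
    n_excluded = 0
    for trial in trials:
        p = preference(trial, min_total_s=min_total_s)
        if p is None:
            n_excluded += 1
        else:
            prefs.append(p)
    if len(prefs) < 2:
        raise EstimationError(
            f"need >= 2 included trials, have {len(prefs)} ({n_excluded} excluded)"
        )
    med, low, high = smoothed_bootstrap_median(
        prefs, n_boot=n_boot, ci_level=ci_level, seed=seed
    )
    # kernel noise can push resampled medians a hair outside [0, 1]
    low, high = max(low, 0.0), min(high, 1.0)
    return EffectEstimate(
        kind="median_proportion",
        estimate=med,
        ci_low=min(low, med),
        ci_high=max(high, med),
        ci_level=ci_level,
        n1=len(prefs),
        n2=None,
        n_boot=n_boot,
        orientation="time toward CV / total courtship",
        flags=(f"excluded={n_excluded}",),
    )
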