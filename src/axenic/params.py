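"""Analysis thresholds and conventions shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

from .estimation_stats import EffectBands


@dataclass(frozen=True)
class AnalysisParams:
    """Every threshold the pipeline uses, in one place.

    Attributes
    ----------
    sleep_min_duration_min
        Minimum run of zero-count minutes scored as sleep (minutes).
    death_inactivity_h
        A fly with at least this many consecutive inactive hours is treated
        as dead and removed.
    bin_width_min
        Width of the bins the folded 24-h profiles use (minutes; must divide
        1440).
    n_boot
        Bootstrap resamples for reported confidence intervals.
    ci_level
        Confidence level of all intervals.
    bands
        Descriptive |g| bands (trivial/small/moderate/large).
    courtship_min_total_s
        Trials with less total courtship than this are omitted (seconds).
    session_length_s
        Nominal arena session length (seconds).
    min_session_fraction
        Sessions shorter than this fraction of ``session_length_s`` are
        excluded from trajectory summaries.
    """

    sleep_min_duration_min: int = 5
    death_inactivity_h: float = 24.0
    bin_width_min: int = 30
    n_boot: int = 10_000
    ci_level: float = 0.95
    bands: EffectBands = field(default_factory=EffectBands)
    courtship_min_total_s: float = 60.0
    session_length_s: float = 600.0
    min_session_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.sleep_min_duration_min < 1:
            raise ValueError("sleep_min_duration_min must be >= 1")
        if self.death_inactivity_h <= 0:
            raise ValueError("death_inactivity_h must be positive")
        if self.bin_width_min < 1 or 1440 % self.bin_width_min:
            raise ValueError("bin_width_min must divide 1440")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")
        if self.courtship_min_total_s < 0:
            raise ValueError("courtship_min_total_s must be non-negative")
        if self.session_length_s <= 0:
            raise ValueError("session_length_s must be positive")
        if not (0.0 < self.min_session_fraction <= 1.0):
            raise ValueError("min_session_fraction must be in (0, 1]")
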