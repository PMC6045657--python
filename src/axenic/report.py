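"""End-to-end study orchestration and summary-table reporting.

Runs every assay the inputs provide, routes each contrast through the
estimation-statistics layer, and emits one effect-size row per metric per
contrast — the study-summary matrix: assay, metric, contrast, housing,
estimate kind, point estimate, 95% CI, group sizes, descriptive label, and a
``moderate_or_larger`` flag (the rows a summary table would set in bold).

Every number in the report is an :class:`~axenic.estimation_stats.EffectEstimate`
produced by the statistics core; the reporting layer computes nothing of its
own.  All filtering (dead flies, excluded courtship trials, short sessions)
is logged with identities and counts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import chc_abundance, courtship_choice, sleep_activity, trajectory_metrics
from .dams_io import BeamCountSeries
from .estimation_stats import EffectEstimate, classify_effect, two_sample_estimate
from .params import AnalysisParams
from .synthetic_data import (
    ArenaSimConfig,
    ChcSimConfig,
    CourtshipSimConfig,
    DamsSimConfig,
    PupationSimConfig,
    simulate_chc_tables,
    simulate_courtship,
    simulate_dams,
    simulate_pupation_days,
    simulate_trajectories,
)

__all__ = ["StudyReport", "run_synthetic_study", "analyze_dams", "analyze_trajectories",
           "analyze_courtship", "analyze_chc", "rows_to_frame", "plot_group_profiles"]

logger = logging.getLogger("axenic")

_ROW_COLUMNS = [
    "assay", "metric", "contrast", "housing", "kind", "estimate",
    "ci_low", "ci_high", "n1", "n2", "label", "moderate_or_larger", "p_value",
]


@dataclass
class StudyReport:
    """Bundle of effect rows plus a log of every filtering action."""

    rows: pd.DataFrame
    filter_log: dict[str, list[str]] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.rows.to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "filter_log": self.filter_log,
        }
        path.write_text(json.dumps(payload, indent=2, default=float))
        return path


def _row(assay: str, metric: str, contrast: str, housing: str, est: EffectEstimate) -> dict:
    label = est.label
    if label is None and est.kind == "hedges_g":
        label = classify_effect(est.estimate)
    return {
        "assay": assay,
        "metric": metric,
        "contrast": contrast,
        "housing": housing,
        "kind": est.kind,
        "estimate": est.estimate,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n1": est.n1,
        "n2": est.n2,
        "label": label,
        "moderate_or_larger": label in ("moderate", "large") if label else False,
        "p_value": est.p_value,
    }


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def analyze_dams(
    series: Sequence[BeamCountSeries],
    params: AnalysisParams,
    control: str,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[dict], dict[str, list[str]]]:
    """Day/night activity and sleep contrasts (g and mean difference) per group."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kept, removed = sleep_activity.remove_dead_flies(series, params.death_inactivity_h)
    if removed:
        logger.info("removed %d dead flies: %s", len(removed), removed)
    summaries = [
        sleep_activity.summarize_day_night(
            s, min_duration=params.sleep_min_duration_min, bin_width=params.bin_width_min
        )
        for s in kept
    ]
    groups = sorted({s.group for s in summaries})
    if control not in groups:
        raise ValueError(f"control group {control!r} absent from monitor data")
    rows: list[dict] = []
    metrics = {
        "activity_day": lambda s: s.day_activity,
        "activity_night": lambda s: s.night_activity,
        "sleep_day": lambda s: s.day_sleep,
        "sleep_night": lambda s: s.night_sleep,
    }
    ctrl_by_metric = {
        m: np.array([f(s) for s in summaries if s.group == control]) for m, f in metrics.items()
    }
    for group in groups:
        if group == control:
            continue
        for metric, f in metrics.items():
            x = np.array([f(s) for s in summaries if s.group == group])
            y = ctrl_by_metric[metric]
            for kind in ("hedges_g", "mean_difference"):
                est = two_sample_estimate(
                    x, y, kind=kind, n_boot=params.n_boot,
                    ci_level=params.ci_level, seed=_sub_seed(rng), bands=params.bands,
                )
                rows.append(_row("dams", metric, f"{group}-{control}", "GH", est))
    return rows, {"dead_flies_removed": removed}


def analyze_trajectories(
    trajectories: Sequence[trajectory_metrics.Trajectory],
    params: AnalysisParams,
    control: str,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[dict], dict[str, list[str]]]:
    """Wall-following and locomotion contrasts, split by housing condition."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table = trajectory_metrics.session_summaries(
            trajectories,
            session_length_s=params.session_length_s,
            min_fraction=params.min_session_fraction,
        )
    dropped = [str(w.message) for w in caught if "excluded" in str(w.message)]
    for msg in dropped:
        logger.info("%s", msg)
    rows: list[dict] = []
    for housing, sub in table.groupby("housing"):
        groups = sorted(sub["group"].unique())
        if control not in groups:
            raise ValueError(f"control group {control!r} absent from trajectories ({housing})")
        for group in groups:
            if group == control:
                continue
            for metric, col in (("wafo", "wafo_mm"), ("locomotion", "speed_mm_s")):
                x = sub.loc[sub["group"] == group, col].to_numpy()
                y = sub.loc[sub["group"] == control, col].to_numpy()
                est = two_sample_estimate(
                    x, y, kind="hedges_g", n_boot=params.n_boot,
                    ci_level=params.ci_level, seed=_sub_seed(rng), bands=params.bands,
                )
                rows.append(_row("arena", metric, f"{group}-{control}", str(housing), est))
    return rows, {"short_sessions_dropped": dropped}


def analyze_courtship(
    trials: Sequence[courtship_choice.CourtshipTrial],
    params: AnalysisParams,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[dict], dict[str, list[str]]]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: list[dict] = []
    log: dict[str, list[str]] = {}
    generations = sorted({t.generation for t in trials})
    for gen in generations:
        sub = [t for t in trials if t.generation == gen]
        est = courtship_choice.group_median_preference(
            sub, n_boot=params.n_boot, ci_level=params.ci_level,
            seed=_sub_seed(rng), min_total_s=params.courtship_min_total_s,
        )
        excluded = [
            t.trial_id for t in sub
            if courtship_choice.preference(t, params.courtship_min_total_s) is None
        ]
        if excluded:
            logger.info("courtship %s: excluded %d trials under %.0f s: %s",
                        gen, len(excluded), params.courtship_min_total_s, excluded)
        log[f"courtship_excluded_{gen or 'all'}"] = excluded
        rows.append(_row("courtship", "preference", "CV/GF targets", gen, est))
    return rows, log


def analyze_chc(
    tables: Sequence[chc_abundance.ChcPeakTable],
    class_map: Mapping[str, str],
    params: AnalysisParams,
    control: str = "CV",
    seed: int | np.random.Generator | None = None,
) -> tuple[list[dict], dict[str, list[str]]]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = sorted({t.group for t in tables})
    rows: list[dict] = []
    for group in groups:
        if group == control:
            continue
        contrasts = chc_abundance.class_contrasts(
            tables, class_map, group_exp=group, group_ctrl=control,
            n_boot=params.n_boot, ci_level=params.ci_level, seed=_sub_seed(rng),
        )
        for cls, est in contrasts.items():
            rows.append(_row("chc", cls, f"{group}-{control}", "", est))
    return rows, {}


def rows_to_frame(rows: Iterable[dict]) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=_ROW_COLUMNS)


def plot_group_profiles(
    profiles: Sequence[sleep_activity.FlyDailyProfile],
    metric: str = "activity",
    n_boot: int = 1000,
    seed: int | None = None,
    path: str | Path | None = None,
):
    """Optional line plot of per-group folded daily profiles with CI ribbons.

    Returns the matplotlib figure; CSV/JSON remain the report contract and
    this is purely a convenience view.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    rng = np.random.default_rng(seed)
    for group in sorted({p.group for p in profiles}):
        frame = sleep_activity.group_profile_with_ci(
            profiles, group, metric=metric, n_boot=n_boot, seed=rng
        )
        hours = frame["bin_start"] / 60.0
        ax.plot(hours, frame["mean"], label=group)
        ax.fill_between(hours, frame["ci_low"], frame["ci_high"], alpha=0.25)
    ax.axvspan(12, 24, color="0.85", zorder=0)  # dark phase
    ax.set_xlabel("hours since lights-on")
    ax.set_ylabel("crossings/min" if metric == "activity" else "sleep min / 30 min")
    ax.set_xlim(0, 24)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def run_synthetic_study(
    seed: int = 0,
    params: AnalysisParams | None = None,
    control: str = "CV",
    dams: DamsSimConfig | None = None,
    arena_ih: ArenaSimConfig | None = None,
    arena_gh: ArenaSimConfig | None = None,
    courtship: CourtshipSimConfig | None = None,
    chc: ChcSimConfig | None = None,
    pupation: PupationSimConfig | None = None,
    include: tuple[str, ...] = ("dams", "arena", "courtship", "chc", "pupation"),
) -> StudyReport:
    """Generate all assays synthetically and produce the study-summary matrix.

    Generator configs default to the study conditions (two groups, no true
    group differences except the courtship preference and the pupation
    delay); pass explicit configs to inject effects.  Deterministic given
    ``seed`` — generator seeds are derived from it unless a config carries
    its own.
    """
    params = params or AnalysisParams()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    log: dict[str, list[str]] = {}

    def _seeded(cfg, default_cls):
        if cfg is None:
            return default_cls(seed=_sub_seed(rng))
        _sub_seed(rng)  # keep the seed stream aligned whether or not cfg given
        return cfg

    dams_cfg = _seeded(dams, DamsSimConfig)
    ih_cfg = _seeded(arena_ih, lambda seed: ArenaSimConfig(housing="IH", seed=seed))
    gh_cfg = _seeded(arena_gh, lambda seed: ArenaSimConfig(housing="GH", seed=seed))
    court_cfg = _seeded(courtship, CourtshipSimConfig)
    chc_cfg = _seeded(chc, ChcSimConfig)
    pup_cfg = _seeded(pupation, PupationSimConfig)

    if "dams" in include:
        r, lg = analyze_dams(simulate_dams(dams_cfg), params, control, seed=rng)
        rows += r
        log.update(lg)
    if "arena" in include:
        trajs = simulate_trajectories(ih_cfg) + simulate_trajectories(gh_cfg)
        r, lg = analyze_trajectories(trajs, params, control, seed=rng)
        rows += r
        log.update(lg)
    if "courtship" in include:
        r, lg = analyze_courtship(simulate_courtship(court_cfg), params, seed=rng)
        rows += r
        log.update(lg)
    if "chc" in include:
        r, lg = analyze_chc(
            simulate_chc_tables(chc_cfg), chc_cfg.class_map, params, control, seed=rng
        )
        rows += r
        log.update(lg)
    if "pupation" in include:
        samples = simulate_pupation_days(pup_cfg)
        ctrl_label, exp_label = pup_cfg.group_labels
        est = two_sample_estimate(
            samples[exp_label], samples[ctrl_label], kind="mean_difference",
            n_boot=params.n_boot, ci_level=params.ci_level, seed=_sub_seed(rng),
        )
        rows.append(_row("development", "pupation_day", f"{exp_label}-{ctrl_label}", "", est))

    return StudyReport(rows=rows_to_frame(rows), filter_log=log)
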