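"""Synthetic stand-ins for the four raw input kinds, with known ground truth.

The study's raw recordings are not deposited, so every downstream stage is
exercised on generated data whose true parameters are known:

* **Activity monitors** — each fly is a two-state (wake/sleep) Markov chain at
  1-minute resolution.  While awake the fly emits Poisson beam-crossing
  counts at a phase-specific rate; while asleep it emits exactly zero.  The
  5-minute sleep rule operates on runs of zero counts, so ground-truth sleep
  is known exactly.  A configurable fraction of flies "die": they emit zeros
  from a random onset in the first half of the recording to the end, which
  guarantees at least 24 inactive hours on records of two days or more.
* **Arena trajectories** — a correlated random walk (heading persistence with
  Gaussian turning) plus a radial drift proportional to ``wall_bias``,
  reflected specularly at the circular boundary.  With ``wall_bias = 0`` the
  walk is isotropic and its stationary radial mean approaches the uniform
  disc expectation 2R/3; large ``wall_bias`` concentrates flies at the wall.
* **Courtship trials** — bouts arrive as a Poisson process with
  gamma-distributed per-trial vigor, bout durations are exponential, and
  each bout is directed at the conventional female with probability
  ``preference_p``.  Low-vigor trials can fall under the 60-s inclusion
  threshold, exercising the downstream filter.
* **GC/MS peak tables** — per-compound lognormal peak areas around
  class-typical means, with an internal-standard column and optional additive
  group shifts per class.
* **Pupation days** — a normal sampler for the developmental-delay contrast.

Reproducibility: one global seed expands into per-fly substreams by
counter-based spawn keys, so adding flies (or groups) never perturbs the
streams of earlier flies.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chc_abundance import CHC_CLASSES, ChcPeakTable
from .courtship_choice import CourtshipTrial
from .dams_io import BeamCountSeries
from .trajectory_metrics import Trajectory

__all__ = [
    "DamsSimConfig",
    "ArenaSimConfig",
    "CourtshipSimConfig",
    "ChcSimConfig",
    "PupationSimConfig",
    "simulate_dams",
    "simulate_trajectories",
    "simulate_courtship",
    "simulate_chc_tables",
    "simulate_pupation_days",
]

GroupParam = float | Mapping[str, float] | Mapping[str, Mapping[str, float]]


def _fly_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: stable under changes to fly/group counts."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _resolve(value: GroupParam, group: str, phase: str | None = None) -> float:
    if isinstance(value, Mapping) and group in value:
        value = value[group]
    if isinstance(value, Mapping) and phase is not None and phase in value:
        value = value[phase]
    if isinstance(value, Mapping):
        raise ValueError(f"cannot resolve parameter {value!r} for group={group} phase={phase}")
    return float(value)


def _leaves(value: GroupParam):
    if isinstance(value, Mapping):
        for v in value.values():
            yield from _leaves(v)
    else:
        yield float(value)


def _check_prob(value: GroupParam, name: str) -> None:
    for v in _leaves(value):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be a probability in [0, 1], got {v}")


def _check_nonneg(value: GroupParam, name: str) -> None:
    for v in _leaves(value):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")


# ---------------------------------------------------------------------------
# activity monitors


@dataclass(frozen=True)
class DamsSimConfig:
    """Conditions of the 6-day 12:12 LD activity-monitor experiment.

    Rates are expected beam crossings per *awake* minute; the sleep chain's
    per-minute entry/exit probabilities may differ by group and by phase
    (keys ``"day"``/``"night"``).  Defaults emulate a normally sleeping
    laboratory fly: mostly awake by day (stationary sleep fraction 0.25,
    ~7.5 sleep minutes per 30) and mostly asleep by night (fraction 0.8,
    ~24/30), with daytime activity around one crossing per minute.
    """

    n_flies_per_group: int = 56
    n_days: int = 6
    group_labels: tuple[str, ...] = ("CV", "GF")
    day_rate: GroupParam = 1.8
    night_rate: GroupParam = 1.0
    sleep_entry_prob: GroupParam = field(
        default_factory=lambda: {"day": 0.05, "night": 0.12}
    )
    sleep_exit_prob: GroupParam = field(
        default_factory=lambda: {"day": 0.15, "night": 0.03}
    )
    dead_fraction: float = 0.0
    lights_on: _dt.time = _dt.time(8, 0)
    start_date: str = "2018-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies_per_group < 1:
            raise ValueError("need at least one fly per group")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if len(set(self.group_labels)) != len(self.group_labels) or not self.group_labels:
            raise ValueError("group labels must be unique and non-empty")
        _check_nonneg(self.day_rate, "day_rate")
        _check_nonneg(self.night_rate, "night_rate")
        _check_prob(self.sleep_entry_prob, "sleep_entry_prob")
        _check_prob(self.sleep_exit_prob, "sleep_exit_prob")
        if not (0.0 <= self.dead_fraction <= 1.0):
            raise ValueError("dead_fraction must be in [0, 1]")
        if self.dead_fraction > 0 and self.n_days < 2:
            raise ValueError("dead_fraction > 0 requires n_days >= 2 (24-h criterion)")


def simulate_dams(config: DamsSimConfig) -> list[BeamCountSeries]:
    """One :class:`BeamCountSeries` per fly; fully reproducible from the seed."""
    t_total = config.n_days * 1440
    day_mask = (np.arange(t_total) % 1440) < 720  # recording starts at lights-on
    start = pd.Timestamp(f"{config.start_date} {config.lights_on.strftime('%H:%M')}")
    grid = pd.date_range(start, periods=t_total, freq="min")

    out: list[BeamCountSeries] = []
    for gi, group in enumerate(config.group_labels):
        rate = np.where(
            day_mask,
            _resolve(config.day_rate, group, "day"),
            _resolve(config.night_rate, group, "night"),
        )
        entry = np.where(
            day_mask,
            _resolve(config.sleep_entry_prob, group, "day"),
            _resolve(config.sleep_entry_prob, group, "night"),
        )
        exit_ = np.where(
            day_mask,
            _resolve(config.sleep_exit_prob, group, "day"),
            _resolve(config.sleep_exit_prob, group, "night"),
        )

        n = config.n_flies_per_group
        u = np.empty((n, t_total))
        raw = np.empty((n, t_total), dtype=np.int64)
        dead_onset = np.full(n, -1, dtype=np.int64)
        for fi in range(n):
            rng = _fly_rng(config.seed, gi, fi)
            u[fi] = rng.random(t_total)
            raw[fi] = rng.poisson(rate)
            if rng.random() < config.dead_fraction:
                dead_onset[fi] = rng.integers(0, t_total // 2)

        # state scan: transition applied before each minute's emission
        asleep = np.empty((n, t_total), dtype=bool)
        cur = np.zeros(n, dtype=bool)  # start awake
        for t in range(t_total):
            cur = np.where(cur, u[:, t] >= exit_[t], u[:, t] < entry[t])
            asleep[:, t] = cur

        counts = np.where(asleep, 0, raw).astype(float)
        for fi in range(n):
            if dead_onset[fi] >= 0:
                counts[fi, dead_onset[fi] :] = 0.0

        for fi in range(n):
            out.append(
                BeamCountSeries(
                    fly_id=f"{group}-{fi + 1:03d}",
                    group=group,
                    timestamps=grid,
                    counts=counts[fi],
                    lights_on=config.lights_on,
                )
            )
    return out


# ---------------------------------------------------------------------------
# arena trajectories


@dataclass(frozen=True)
class ArenaSimConfig:
    """Conditions of the 10-minute circular-arena session.

    ``wall_bias`` is the strength of the outward radial drift relative to the
    walking speed (0 = isotropic walk); ``speed_cv`` is the between-fly
    coefficient of variation of walking speed, so a zero group mean yields
    stationary flies.  ``turn_sd_rad`` is the per-frame heading diffusion.
    """

    n_flies_per_group: int = 56
    duration_s: float = 600.0
    dt_s: float = 0.1
    arena_radius_mm: float = 10.0
    wall_bias: GroupParam = 0.0
    speed_mean_mm_s: GroupParam = 1.3
    speed_cv: float = 0.2
    turn_sd_rad: float = 0.6
    group_labels: tuple[str, ...] = ("CV", "GF")
    housing: str = "IH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies_per_group < 1:
            raise ValueError("need at least one fly per group")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.arena_radius_mm <= 0:
            raise ValueError("arena_radius_mm must be positive")
        _check_nonneg(self.wall_bias, "wall_bias")
        _check_nonneg(self.speed_mean_mm_s, "speed_mean_mm_s")
        if self.speed_cv < 0 or self.turn_sd_rad < 0:
            raise ValueError("speed_cv and turn_sd_rad must be non-negative")
        if len(set(self.group_labels)) != len(self.group_labels) or not self.group_labels:
            raise ValueError("group labels must be unique and non-empty")


def simulate_trajectories(config: ArenaSimConfig) -> list[Trajectory]:
    """Correlated random walks in a reflecting circular arena."""
    n_steps = int(round(config.duration_s / config.dt_s))
    t = np.arange(n_steps + 1) * config.dt_s
    radius = config.arena_radius_mm

    out: list[Trajectory] = []
    for gi, group in enumerate(config.group_labels):
        bias = _resolve(config.wall_bias, group)
        mean_speed = _resolve(config.speed_mean_mm_s, group)
        n = config.n_flies_per_group

        speeds = np.empty(n)
        phi = np.empty(n)
        x = np.empty(n)
        y = np.empty(n)
        turns = np.empty((n, n_steps))
        for fi in range(n):
            rng = _fly_rng(config.seed, 100 + gi, fi)
            speeds[fi] = max(0.0, rng.normal(mean_speed, config.speed_cv * mean_speed))
            phi[fi] = rng.uniform(0.0, 2.0 * np.pi)
            r0 = radius * np.sqrt(rng.random())
            th0 = rng.uniform(0.0, 2.0 * np.pi)
            x[fi], y[fi] = r0 * np.cos(th0), r0 * np.sin(th0)
            turns[fi] = rng.normal(0.0, config.turn_sd_rad, n_steps)

        xs = np.empty((n, n_steps + 1))
        ys = np.empty((n, n_steps + 1))
        xs[:, 0], ys[:, 0] = x, y
        step = speeds * config.dt_s
        for k in range(n_steps):
            phi = phi + turns[:, k]
            r = np.hypot(x, y)
            with np.errstate(invalid="ignore", divide="ignore"):
                rx = np.where(r > 0, x / r, 0.0)
                ry = np.where(r > 0, y / r, 0.0)
            nx = x + step * (np.cos(phi) + bias * rx)
            ny = y + step * (np.sin(phi) + bias * ry)
            rn = np.hypot(nx, ny)
            outb = rn > radius
            if outb.any():
                # specular reflection: fold radially, mirror heading off the tangent
                ux, uy = nx[outb] / rn[outb], ny[outb] / rn[outb]
                vx, vy = np.cos(phi[outb]), np.sin(phi[outb])
                dot = vx * ux + vy * uy
                phi[outb] = np.arctan2(vy - 2 * dot * uy, vx - 2 * dot * ux)
                fold = np.clip(2 * radius - rn[outb], 0.0, radius)
                nx[outb], ny[outb] = ux * fold, uy * fold
            x, y = nx, ny
            xs[:, k + 1], ys[:, k + 1] = x, y

        for fi in range(n):
            out.append(
                Trajectory(
                    fly_id=f"{group}-{config.housing}-{fi + 1:03d}",
                    t=t,
                    x=xs[fi],
                    y=ys[fi],
                    arena_radius=radius,
                    group=group,
                    housing=config.housing,
                )
            )
    return out


# ---------------------------------------------------------------------------
# courtship


@dataclass(frozen=True)
class CourtshipSimConfig:
    """Conditions of the 60-minute two-choice courtship assay.

    ``preference_p`` is the probability a bout is directed at the
    conventional female (0.7 by default — the preference magnitude the assay
    is built to resolve).  Bout arrival uses a gamma-distributed per-trial
    vigor multiplier (shape ``rate_dispersion``) so that sluggish trials can
    fall below the one-minute inclusion threshold; inter-bout statistics are
    free parameters of the generator, not calibrated quantities.
    """

    n_trials: int = 92
    preference_p: float = 0.7
    bout_rate: float = 20.0 / 3600.0  # bouts per second
    bout_duration_s: float = 30.0
    rate_dispersion: float = 1.5
    observation_s: float = 3600.0
    generation: str = "F1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.0 <= self.preference_p <= 1.0):
            raise ValueError("preference_p must be in [0, 1]")
        if self.bout_rate < 0 or self.bout_duration_s <= 0 or self.rate_dispersion <= 0:
            raise ValueError("bout parameters must be positive (rate may be zero)")
        if self.observation_s <= 0:
            raise ValueError("observation_s must be positive")


def simulate_courtship(config: CourtshipSimConfig) -> list[CourtshipTrial]:
    out: list[CourtshipTrial] = []
    for ti in range(config.n_trials):
        rng = _fly_rng(config.seed, 200, ti)
        vigor = rng.gamma(config.rate_dispersion, 1.0 / config.rate_dispersion)
        n_bouts = rng.poisson(config.bout_rate * vigor * config.observation_s)
        if n_bouts == 0:
            t_a = t_b = 0.0
        else:
            durations = rng.exponential(config.bout_duration_s, n_bouts)
            toward_a = rng.random(n_bouts) < config.preference_p
            t_a = float(durations[toward_a].sum())
            t_b = float(durations[~toward_a].sum())
            total = t_a + t_b
            if total > config.observation_s:  # bouts cannot overrun the hour
                scale = config.observation_s / total
                t_a, t_b = t_a * scale, t_b * scale
        out.append(
            CourtshipTrial(
                trial_id=f"{config.generation}-{ti + 1:03d}",
                t_target_a=t_a,
                t_target_b=t_b,
                observation_s=config.observation_s,
                generation=config.generation,
            )
        )
    return out


# ---------------------------------------------------------------------------
# GC/MS peak tables

_DEFAULT_PANEL: dict[str, tuple[str, float]] = {
    # compound -> (class, typical relative abundance in a.u.)
    "n-tricosane": ("linear alkane", 2.5),
    "n-pentacosane": ("linear alkane", 3.0),
    "2-methyltetracosane": ("branched alkane", 1.5),
    "2-methylhexacosane": ("branched alkane", 2.0),
    "7,11-heptacosadiene": ("diene", 8.0),
    "7,11-nonacosadiene": ("diene", 4.0),
    "7-tricosene": ("monoene", 3.5),
    "7-pentacosene": ("monoene", 2.5),
}


@dataclass(frozen=True)
class ChcSimConfig:
    """Synthetic GC/MS replicate sets (default three vials of 8 females/group).

    ``class_shift`` adds a per-class offset to the experimental group's
    compound abundances (split evenly across the class's compounds); the
    default is no difference.  Areas are lognormal around compound-typical
    means with coefficient of variation ``cv``; the internal-standard area
    sets the arbitrary-unit scale.
    """

    n_samples_per_group: int = 3
    group_labels: tuple[str, str] = ("CV", "GF")
    class_shift: Mapping[str, float] = field(default_factory=dict)
    cv: float = 0.25
    standard_area: float = 1.0e6
    panel: Mapping[str, tuple[str, float]] = field(default_factory=lambda: dict(_DEFAULT_PANEL))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        if self.cv < 0 or self.standard_area <= 0:
            raise ValueError("cv must be >= 0 and standard_area positive")
        for cls in self.class_shift:
            if cls not in CHC_CLASSES:
                raise ValueError(f"unknown CHC class in class_shift: {cls!r}")

    @property
    def class_map(self) -> dict[str, str]:
        return {compound: cls for compound, (cls, _) in self.panel.items()}


def simulate_chc_tables(config: ChcSimConfig) -> list[ChcPeakTable]:
    tables: list[ChcPeakTable] = []
    exp_group = config.group_labels[1]
    per_class_n = {cls: sum(1 for _, (c, _) in config.panel.items() if c == cls) for cls in CHC_CLASSES}
    sigma = np.sqrt(np.log1p(config.cv**2))
    for gi, group in enumerate(config.group_labels):
        for si in range(config.n_samples_per_group):
            rng = _fly_rng(config.seed, 300 + gi, si)
            areas: dict[str, float] = {}
            for compound, (cls, mean_rel) in config.panel.items():
                rel = mean_rel
                if group == exp_group and cls in config.class_shift:
                    rel = rel + config.class_shift[cls] / per_class_n[cls]
                rel = max(rel, 0.0)
                noise = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
                areas[compound] = rel * noise * config.standard_area
            tables.append(
                ChcPeakTable(
                    sample_id=f"{group}-{si + 1}",
                    group=group,
                    areas=areas,
                    internal_standard_area=config.standard_area,
                )
            )
    return tables


# ---------------------------------------------------------------------------
# pupation


@dataclass(frozen=True)
class PupationSimConfig:
    """Normal sampler for days-to-pupation; the germ-free group develops
    ``delay_days`` later (1.33 days by default, a realistic germ-free delay
    on rich food)."""

    n_ctrl: int = 213
    n_exp: int = 112
    mean_days_ctrl: float = 5.0
    delay_days: float = 1.33
    sd_days: float = 0.9
    group_labels: tuple[str, str] = ("CV", "GF")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ctrl < 1 or self.n_exp < 1:
            raise ValueError("need at least one observation per group")
        if self.sd_days <= 0:
            raise ValueError("sd_days must be positive")


def simulate_pupation_days(config: PupationSimConfig) -> dict[str, np.ndarray]:
    """Returns {group_label: per-individual days to pupation}."""
    ctrl, exp = config.group_labels
    rng_c = _fly_rng(config.seed, 400, 0)
    rng_e = _fly_rng(config.seed, 400, 1)
    return {
        ctrl: rng_c.normal(config.mean_days_ctrl, config.sd_days, config.n_ctrl),
        exp: rng_e.normal(config.mean_days_ctrl + config.delay_days, config.sd_days, config.n_exp),
    }


# ---------------------------------------------------------------------------
# file export helpers (CSV dialects consumed by the CLI)


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Long CSV dialect: fly_id, group, housing, t, x, y."""
    parts = [
        pd.DataFrame(
            {
                "fly_id": tr.fly_id,
                "group": tr.group,
                "housing": tr.housing,
                "t": tr.t,
                "x": tr.x,
                "y": tr.y,
            }
        )
        for tr in trajectories
    ]
    return pd.concat(parts, ignore_index=True)


def courtship_to_frame(trials: Sequence[CourtshipTrial]) -> pd.DataFrame:
    """CSV dialect: trial_id, generation, t_cv_s, t_gf_s, observation_s."""
    return pd.DataFrame(
        {
            "trial_id": [tr.trial_id for tr in trials],
            "generation": [tr.generation for tr in trials],
            "t_cv_s": [tr.t_target_a for tr in trials],
            "t_gf_s": [tr.t_target_b for tr in trials],
            "observation_s": [tr.observation_s for tr in trials],
        }
    )


def chc_to_frame(tables: Sequence[ChcPeakTable]) -> pd.DataFrame:
    """Wide CSV dialect: sample_id, group, standard_area, one column per compound."""
    rows = []
    for tb in tables:
        row = {"sample_id": tb.sample_id, "group": tb.group, "standard_area": tb.internal_standard_area}
        row.update(tb.areas)
        rows.append(row)
    return pd.DataFrame(rows)
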