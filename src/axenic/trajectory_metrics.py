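"""Wall-following and locomotion metrics from arena centroid trajectories.

The wall-following (WAFO) statistic is thigmotaxis quantified the simple way:
the arithmetic mean, over frames, of the fly centroid's Euclidean distance
from the arena center, in millimetres.  Mean walking speed is the mean over
consecutive frame pairs of displacement divided by the frame interval.  Both
are computed exactly as defined — no smoothing or jump filtering by default;
an optional maximum-displacement filter is available for tracking glitches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "wafo_metric",
    "mean_speed",
    "session_summaries",
    "minimum_enclosing_circle",
]


@dataclass
class Trajectory:
    """Per-fly centroid positions in a circular arena.

    ``x``/``y`` and ``arena_center``/``arena_radius`` share one raw unit
    (pixels or mm); ``mm_per_pixel`` converts metrics to millimetres (1.0 if
    the positions are already calibrated).  Missing frames are NaN positions.
    """

    fly_id: str
    t: np.ndarray  # seconds, strictly increasing
    x: np.ndarray
    y: np.ndarray
    arena_radius: float
    arena_center: tuple[float, float] = (0.0, 0.0)
    mm_per_pixel: float = 1.0
    group: str = ""
    housing: str = ""  # "IH" (individually housed) | "GH" (group housed)
    _containment_tol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y differ in length")
        if len(self.t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.arena_radius <= 0:
            raise ValueError("arena_radius must be positive")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        r = self._radial_raw()
        r = r[np.isfinite(r)]
        if r.size and r.max() > self.arena_radius * (1 + self._containment_tol):
            raise ValueError(
                f"fly {self.fly_id!r}: positions fall outside the arena "
                f"(max r={r.max():.3f} > R={self.arena_radius:.3f})"
            )
        dt = np.diff(self.t)
        if dt.size > 1 and (dt.max() - dt.min()) > 0.05 * dt.mean():
            warnings.warn(f"fly {self.fly_id!r}: frame interval varies by more than 5%")

    def _radial_raw(self) -> np.ndarray:
        cx, cy = self.arena_center
        return np.hypot(self.x - cx, self.y - cy)

    @property
    def arena_radius_mm(self) -> float:
        return self.arena_radius * self.mm_per_pixel

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


def wafo_metric(traj: Trajectory) -> float:
    """Mean distance of the centroid from the arena center, in mm."""
    r = traj._radial_raw()
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no observed positions")
    return float(r.mean() * traj.mm_per_pixel)


def mean_speed(traj: Trajectory, max_step_mm: float | None = None) -> float:
    """Mean over consecutive valid frame pairs of displacement / dt, in mm/s.

    Pairs with a missing endpoint are dropped from numerator and denominator.
    ``max_step_mm`` optionally discards glitch pairs whose displacement
    exceeds the limit.
    """
    valid = np.isfinite(traj.x) & np.isfinite(traj.y)
    pair = valid[:-1] & valid[1:]
    if not pair.any():
        raise ValueError("no consecutive pair of observed positions")
    dx = np.diff(traj.x) * traj.mm_per_pixel
    dy = np.diff(traj.y) * traj.mm_per_pixel
    dt = np.diff(traj.t)
    step = np.hypot(dx, dy)
    if max_step_mm is not None:
        pair = pair & (step <= max_step_mm)
        if not pair.any():
            raise ValueError("all frame pairs exceeded max_step_mm")
    return float((step[pair] / dt[pair]).mean())


def session_summaries(
    trajectories: Iterable[Trajectory],
    session_length_s: float = 600.0,
    min_fraction: float = 0.9,
    max_step_mm: float | None = None,
) -> pd.DataFrame:
    """Per-fly (wafo_mm, speed_mm_s) records for a fixed-length test session.

    Trajectories longer than the session are trimmed to ``session_length_s``
    from their first frame; sessions shorter than ``min_fraction`` of the
    nominal length are excluded with a warning.
    """
    rows = []
    excluded: list[str] = []
    for traj in trajectories:
        if traj.duration_s < min_fraction * session_length_s:
            excluded.append(traj.fly_id)
            continue
        keep = traj.t <= traj.t[0] + session_length_s
        trimmed = Trajectory(
            fly_id=traj.fly_id,
            t=traj.t[keep],
            x=traj.x[keep],
            y=traj.y[keep],
            arena_radius=traj.arena_radius,
            arena_center=traj.arena_center,
            mm_per_pixel=traj.mm_per_pixel,
            group=traj.group,
            housing=traj.housing,
        )
        rows.append(
            {
                "fly_id": trimmed.fly_id,
                "group": trimmed.group,
                "housing": trimmed.housing,
                "wafo_mm": wafo_metric(trimmed),
                "speed_mm_s": mean_speed(trimmed, max_step_mm=max_step_mm),
            }
        )
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} session(s) shorter than "
            f"{min_fraction:.0%} of {session_length_s:.0f} s: {excluded}"
        )
    return pd.DataFrame(rows, columns=["fly_id", "group", "housing", "wafo_mm", "speed_mm_s"])


def minimum_enclosing_circle(
    points: Sequence[tuple[float, float]] | np.ndarray,
) -> tuple[float, float, float]:
    """Smallest circle containing all points: (cx, cy, radius).

    Fallback arena estimator for recordings whose chamber geometry was not
    logged.  Expected-linear-time incremental construction (Welzl-style
    move-to-front over at most three support points).
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.shape[0] == 0:
        raise ValueError("no finite points")
    # deterministic shuffle: the algorithm's expected-linear bound needs a
    # random order, but results are order-independent
    pts = pts[np.random.default_rng(0).permutation(pts.shape[0])]

    def circle_two(a, b):
        c = (a + b) / 2.0
        return c[0], c[1], float(np.hypot(*(a - b)) / 2.0)

    def circle_three(a, b, c):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
        center = np.array([ux, uy])
        return ux, uy, float(np.hypot(*(a - center)))

    def inside(circ, p, eps=1e-9):
        cx, cy, r = circ
        return np.hypot(p[0] - cx, p[1] - cy) <= r * (1 + eps) + eps

    circ = (pts[0][0], pts[0][1], 0.0)
    for i in range(1, len(pts)):
        if inside(circ, pts[i]):
            continue
        circ = (pts[i][0], pts[i][1], 0.0)
        for j in range(i):
            if inside(circ, pts[j]):
                continue
            circ = circle_two(pts[i], pts[j])
            for k in range(j):
                if inside(circ, pts[k]):
                    continue
                c3 = circle_three(pts[i], pts[j], pts[k])
                if c3 is not None:
                    circ = c3
    return circ
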