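"""Reading and writing activity-monitor files (TriKinetics DAM dialect).

A monitor file is tab-delimited with one row per minute.  The full dialect
has 42 columns: reading index, date (``"1 Jan 18"``), time (``HH:MM:SS``), a
status field (1 = OK), six device fields, then 32 beam-count columns, one per
channel.  A reduced variant with fewer columns (index, date, time, status,
then N count columns) is accepted behind the same interface.

The in-memory model is :class:`BeamCountSeries`: one fly's gap-free 1-minute
grid of beam-crossing counts, annotated day/night from the lights-on clock
time under a 12:12 light-dark cycle.  Missing minutes (grid gaps or rows with
an error status) are stored as NaN — *missing*, not zero, because a zero is a
meaningful observation (possible sleep) while an unobserved minute is not.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeamCountSeries",
    "DamsParseError",
    "read_monitor_file",
    "write_monitor_file",
    "to_long_frame",
    "parse_lights_on",
]

N_CHANNELS = 32
_FULL_COLUMNS = 42  # index, date, time, status, 6 device fields, 32 counts
_DATE_FORMAT = "%d %b %y"


class DamsParseError(ValueError):
    """Malformed monitor file; the message names the offending line."""


def parse_lights_on(value: str | _dt.time) -> _dt.time:
    """Accept ``datetime.time`` or an ``HH:MM`` string."""
    if isinstance(value, _dt.time):
        return value
    try:
        h, m = value.split(":")
        return _dt.time(int(h), int(m))
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse lights-on time {value!r}; expected HH:MM") from exc


@dataclass
class BeamCountSeries:
    """Per-fly 1-minute beam-crossing counts with light-phase annotation."""

    fly_id: str
    group: str
    timestamps: pd.DatetimeIndex
    counts: np.ndarray  # float; NaN marks a missing minute
    lights_on: _dt.time

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.timestamps) != len(self.counts):
            raise ValueError("timestamps and counts differ in length")
        if len(self.timestamps) == 0:
            raise ValueError("empty series")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8)
            if not np.all(deltas == 60_000_000_000):
                raise ValueError("timestamps must be a gap-free 1-minute grid")
        observed = self.counts[np.isfinite(self.counts)]
        if np.any(observed < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_minutes(self) -> int:
        return len(self.counts)

    @property
    def cycle_minute(self) -> np.ndarray:
        """Minutes since the most recent lights-on, in [0, 1440)."""
        mins = self.timestamps.hour * 60 + self.timestamps.minute
        on = self.lights_on.hour * 60 + self.lights_on.minute
        return np.asarray((mins - on) % 1440, dtype=int)

    @property
    def is_day(self) -> np.ndarray:
        """True during the half-open window [lights_on, lights_on + 12 h)."""
        return self.cycle_minute < 720

    @property
    def light_phase(self) -> np.ndarray:
        return np.where(self.is_day, "day", "night")


def read_monitor_file(
    path: str | Path,
    channel_map: Mapping[int, tuple[str, str]],
    lights_on: str | _dt.time,
) -> list[BeamCountSeries]:
    """Parse a monitor file into one :class:`BeamCountSeries` per mapped channel.

    Parameters
    ----------
    path
        Tab-delimited monitor file (full 42-column or reduced dialect).
    channel_map
        ``{channel_number (1-based): (fly_id, group)}``; unmapped channels are
        skipped with a warning.
    lights_on
        Lights-on clock time (``HH:MM`` or ``datetime.time``); there is no
        default because the recording schedule is experiment-specific.
    """
    lights_on = parse_lights_on(lights_on)
    path = Path(path)
    times: list[pd.Timestamp] = []
    rows: list[np.ndarray] = []
    status_bad: list[bool] = []
    n_counts: int | None = None

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == _FULL_COLUMNS:
                count_fields = fields[10:42]
            elif len(fields) >= 5:
                count_fields = fields[4:]
            else:
                raise DamsParseError(
                    f"{path.name} line {lineno}: expected >=5 tab-separated fields, got {len(fields)}"
                )
            if n_counts is None:
                n_counts = len(count_fields)
            elif len(count_fields) != n_counts:
                raise DamsParseError(
                    f"{path.name} line {lineno}: inconsistent column count"
                )
            try:
                ts = pd.Timestamp(
                    _dt.datetime.strptime(f"{fields[1]} {fields[2]}", f"{_DATE_FORMAT} %H:%M:%S")
                )
            except ValueError as exc:
                raise DamsParseError(f"{path.name} line {lineno}: bad date/time ({exc})") from exc
            try:
                counts = np.array([int(c) for c in count_fields], dtype=float)
            except ValueError as exc:
                raise DamsParseError(f"{path.name} line {lineno}: non-integer count ({exc})") from exc
            if np.any(counts < 0):
                raise DamsParseError(f"{path.name} line {lineno}: negative count")
            try:
                status = int(fields[3])
            except ValueError as exc:
                raise DamsParseError(f"{path.name} line {lineno}: bad status field") from exc
            times.append(ts)
            rows.append(counts)
            status_bad.append(status != 1)

    if not times:
        raise DamsParseError(f"{path.name}: no data rows")
    index = pd.DatetimeIndex(times)
    if not index.is_monotonic_increasing or index.has_duplicates:
        raise DamsParseError(f"{path.name}: timestamps are not strictly increasing")

    matrix = np.vstack(rows)
    matrix[np.asarray(status_bad)] = np.nan  # error-status rows become missing
    frame = pd.DataFrame(matrix, index=index)
    # fill grid gaps as missing, never as zero
    full = pd.date_range(index[0], index[-1], freq="min")
    frame = frame.reindex(full)

    series: list[BeamCountSeries] = []
    for channel, (fly_id, group) in channel_map.items():
        if not (1 <= channel <= frame.shape[1]):
            warnings.warn(f"channel {channel} not present in {path.name}; skipped")
            continue
        series.append(
            BeamCountSeries(
                fly_id=fly_id,
                group=group,
                timestamps=pd.DatetimeIndex(frame.index),
                counts=frame[channel - 1].to_numpy(),
                lights_on=lights_on,
            )
        )
    unmapped = set(range(1, frame.shape[1] + 1)) - set(channel_map)
    if unmapped and any(np.nansum(matrix[:, c - 1]) > 0 for c in unmapped):
        warnings.warn(f"{path.name}: unmapped channels with activity: {sorted(unmapped)}")
    return series


def write_monitor_file(series: Sequence[BeamCountSeries], path: str | Path) -> Path:
    """Emit the full 42-column dialect that :func:`read_monitor_file` accepts.

    All series must share one time grid; unused channels are written as zero.
    Missing minutes cannot be represented in the dialect and are rejected.
    """
    series = list(series)
    if not series:
        raise ValueError("refusing to write a monitor file with no series")
    if len(series) > N_CHANNELS:
        raise ValueError(f"monitor files carry at most {N_CHANNELS} channels")
    grid = series[0].timestamps
    for s in series[1:]:
        if len(s.timestamps) != len(grid) or not (s.timestamps == grid).all():
            raise ValueError("all series must share a common time grid")
    for s in series:
        if not np.all(np.isfinite(s.counts)):
            raise ValueError(
                f"series {s.fly_id!r} has missing minutes; the monitor dialect cannot express them"
            )

    path = Path(path)
    counts = np.zeros((len(grid), N_CHANNELS), dtype=int)
    for ch, s in enumerate(series):
        counts[:, ch] = s.counts.astype(int)
    with path.open("w") as fh:
        for i, ts in enumerate(grid):
            date_full = f"{ts.day} {ts.strftime('%b %y')}"
            time_s = ts.strftime("%H:%M:%S")
            fields = [str(i + 1), date_full, time_s, "1"] + ["0"] * 6
            fields += [str(c) for c in counts[i]]
            fh.write("\t".join(fields) + "\n")
    return path


def to_long_frame(series: Iterable[BeamCountSeries]) -> pd.DataFrame:
    """Long-format export: fly_id, group, timestamp, count, phase."""
    parts = []
    for s in series:
        parts.append(
            pd.DataFrame(
                {
                    "fly_id": s.fly_id,
                    "group": s.group,
                    "timestamp": s.timestamps,
                    "count": s.counts,
                    "phase": s.light_phase,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=["fly_id", "group", "timestamp", "count", "phase"])
    return pd.concat(parts, ignore_index=True)
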