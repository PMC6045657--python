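"""Cuticular-hydrocarbon relative abundance from GC/MS peak tables.

Each sample is one replicate vial of extracted females run on GC/MS with a
hexacosane internal standard.  The relative abundance of a compound is its
peak area divided by the internal-standard peak area (arbitrary units), which
cancels injection-volume and detector-response drift.  Compounds are grouped
into the four CHC chemical classes (linear alkane, branched alkane, diene,
monoene) and group contrasts are reported as mean differences with bootstrap
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation_stats import EffectEstimate, two_sample_estimate

__all__ = [
    "CHC_CLASSES",
    "ChcPeakTable",
    "relative_abundance",
    "class_totals",
    "class_contrasts",
    "read_peak_table_csv",
    "read_class_map_csv",
]

CHC_CLASSES = ("linear alkane", "branched alkane", "diene", "monoene")


@dataclass
class ChcPeakTable:
    """Raw peak areas for one replicate sample, plus the internal standard."""

    sample_id: str
    group: str
    areas: Mapping[str, float]
    internal_standard_area: float

    def __post_init__(self) -> None:
        self.areas = dict(self.areas)
        if not self.areas:
            raise ValueError("peak table has no compounds")
        if any(v < 0 for v in self.areas.values()):
            raise ValueError("peak areas must be non-negative")
        if self.internal_standard_area <= 0:
            raise ValueError("internal standard peak area must be positive")


def relative_abundance(table: ChcPeakTable) -> pd.Series:
    """Per-compound area / internal-standard area (a.u.)."""
    return pd.Series(table.areas, dtype=float) / table.internal_standard_area


def class_totals(rel_abundances: pd.Series, class_map: Mapping[str, str]) -> pd.Series:
    """Sum of relative abundances within each CHC class.

    Every compound must be mapped to exactly one known class.
    """
    unmapped = [c for c in rel_abundances.index if c not in class_map]
    if unmapped:
        raise KeyError(f"compounds missing from the class map: {unmapped}")
    bad = {c: cls for c, cls in class_map.items() if cls not in CHC_CLASSES}
    if bad:
        raise ValueError(f"unknown CHC classes: {bad}")
    totals = pd.Series(0.0, index=list(CHC_CLASSES))
    for compound, value in rel_abundances.items():
        totals[class_map[compound]] += float(value)
    return totals


def class_contrasts(
    samples: Iterable[ChcPeakTable],
    class_map: Mapping[str, str],
    group_exp: str = "GF",
    group_ctrl: str = "CV",
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> dict[str, EffectEstimate]:
    """Per-class mean difference (experimental - control) with bootstrap CI.

    With the handful of replicate sets typical of GC/MS work, estimates carry
    a ``low_n`` flag; a group of one yields a degenerate (point) interval.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_group: dict[str, list[pd.Series]] = {group_exp: [], group_ctrl: []}
    for table in samples:
        if table.group in per_group:
            per_group[table.group].append(class_totals(relative_abundance(table), class_map))
    for label, rows in per_group.items():
        if not rows:
            raise ValueError(f"no samples for group {label!r}")
    out: dict[str, EffectEstimate] = {}
    for cls in CHC_CLASSES:
        x = np.array([row[cls] for row in per_group[group_exp]])
        y = np.array([row[cls] for row in per_group[group_ctrl]])
        out[cls] = two_sample_estimate(
            x, y, kind="mean_difference", n_boot=n_boot, ci_level=ci_level, seed=rng
        )
    return out


def read_peak_table_csv(path: str | Path, standard_column: str = "standard_area") -> list[ChcPeakTable]:
    """Wide CSV: sample_id, group, standard_area, then one column per compound."""
    frame = pd.read_csv(path)
    required = {"sample_id", "group", standard_column}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"peak table is missing columns: {sorted(missing)}")
    compounds = [c for c in frame.columns if c not in required]
    tables = []
    for _, row in frame.iterrows():
        tables.append(
            ChcPeakTable(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                areas={c: float(row[c]) for c in compounds},
                internal_standard_area=float(row[standard_column]),
            )
        )
    return tables


def read_class_map_csv(path: str | Path) -> dict[str, str]:
    """Two-column CSV: compound, chc_class."""
    frame = pd.read_csv(path)
    if not {"compound", "chc_class"} <= set(frame.columns):
        raise ValueError("class map needs 'compound' and 'chc_class' columns")
    return dict(zip(frame["compound"].astype(str), frame["chc_class"].astype(str)))
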