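"""Two-period temporal taxonomy of yearly hotspot labels.

The study window is split into an early period T1 and a late period T2
(default: first half vs second half).  For each cell the hotspot-year counts
(c1, c2) are mapped to one of four categories:

* consistent — c1 ≥ 5 and c2 ≥ 3 (hot almost always early, at least half late)
* declining  — c1 ≥ 3 and c2 ≤ 2 (hot at least half early, at most a third late)
* emerging   — c1 ≤ 3 and c2 ≥ 4 (hot at most half early, at least two thirds late)
* inconsistent — everything else

The printed thresholds assume six-year periods; for other window lengths the
defaults scale proportionally (5/6, 3/6 of |T1|; 2/6, 4/6 of |T2|), rounded
to the nearest integer with ties rounding up.  The three named rules are
mutually exclusive for any period lengths under this scaling because the
consistent/emerging rules split on c1 and consistent/declining and
declining/emerging split on c2.  Coldspot trend categories are not defined;
yearly coldspot labels simply count as non-hotspot years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gistar import GiResult, LABEL_HOT

__all__ = [
    "PeriodSplit",
    "TrendThresholds",
    "TrendLabel",
    "count_hotspot_years",
    "classify_trend",
    "classify_trends",
    "CATEGORIES",
]

CAT_CONSISTENT = "consistent"
CAT_EMERGING = "emerging"
CAT_DECLINING = "declining"
CAT_INCONSISTENT = "inconsistent"
CATEGORIES = (CAT_CONSISTENT, CAT_EMERGING, CAT_DECLINING, CAT_INCONSISTENT)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class PeriodSplit:
    """Disjoint ordered year sets T1 (early) and T2 (late) covering the window."""

    t1: tuple[int, ...]
    t2: tuple[int, ...]

    def __post_init__(self) -> None:
        t1, t2 = tuple(self.t1), tuple(self.t2)
        if not t1 or not t2:
            raise ValueError("both periods must be non-empty")
        if set(t1) & set(t2):
            raise ValueError("periods must be disjoint")
        object.__setattr__(self, "t1", t1)
        object.__setattr__(self, "t2", t2)

    @classmethod
    def halves(cls, years: tuple[int, ...]) -> "PeriodSplit":
        """Default split: first half vs second half of the ordered window."""
        years = tuple(years)
        if len(years) < 2:
            raise ValueError("need at least two years to split")
        mid = len(years) // 2
        return cls(t1=years[:mid], t2=years[mid:])

    @property
    def all_years(self) -> tuple[int, ...]:
        return self.t1 + self.t2


@dataclass(frozen=True)
class TrendThresholds:
    """Count thresholds of the four-way taxonomy (defaults for 6+6 windows)."""

    consistent_t1_min: int = 5
    consistent_t2_min: int = 3
    declining_t1_min: int = 3
    declining_t2_max: int = 2
    emerging_t1_max: int = 3
    emerging_t2_min: int = 4

    @classmethod
    def for_split(cls, split: PeriodSplit) -> "TrendThresholds":
        """Printed thresholds for 6+6; proportional scaling otherwise."""
        n1, n2 = len(split.t1), len(split.t2)
        if n1 == 6 and n2 == 6:
            return cls()
        return cls(
            consistent_t1_min=_round_half_up(5 * n1 / 6),
            consistent_t2_min=_round_half_up(3 * n2 / 6),
            declining_t1_min=_round_half_up(3 * n1 / 6),
            declining_t2_max=_round_half_up(2 * n2 / 6),
            emerging_t1_max=_round_half_up(3 * n1 / 6),
            emerging_t2_min=_round_half_up(4 * n2 / 6),
        )


@dataclass(frozen=True)
class TrendLabel:
    cell_id: int
    c1: int
    c2: int
    category: str


def count_hotspot_years(result: GiResult, split: PeriodSplit) -> pd.DataFrame:
    """Per-cell hotspot-year counts (c1, c2) over the two periods.

    Coldspot and ns years both count as non-hotspot.  Raises if the split
    references a year absent from the yearly labels.
    """
    table = result.table
    have = set(int(y) for y in pd.unique(table["year"]))
    missing = set(split.all_years) - have
    if missing:
        raise ValueError(f"split references years absent from labels: {sorted(missing)}")
    hot = table.assign(is_hot=(table["label"] == LABEL_HOT).astype(int))
    c1 = (
        hot[hot["year"].isin(split.t1)].groupby("cell_id")["is_hot"].sum().rename("c1")
    )
    c2 = (
        hot[hot["year"].isin(split.t2)].groupby("cell_id")["is_hot"].sum().rename("c2")
    )
    out = pd.concat([c1, c2], axis=1).fillna(0).astype(int).reset_index()
    return out.sort_values("cell_id", ignore_index=True)


def classify_trend(
    c1: np.ndarray | int,
    c2: np.ndarray | int,
    split: PeriodSplit | None = None,
    thresholds: TrendThresholds | None = None,
) -> np.ndarray | str:
    """Map hotspot-year counts to the four-way category.

    Accepts scalars or aligned arrays; thresholds default to the split's
    (or the 6+6 printed values when no split is given).
    """
    if thresholds is None:
        thresholds = TrendThresholds.for_split(split) if split is not None else TrendThresholds()
    scalar = np.isscalar(c1) and np.isscalar(c2)
    c1 = np.atleast_1d(np.asarray(c1, dtype=int))
    c2 = np.atleast_1d(np.asarray(c2, dtype=int))
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("negative hotspot-year count")
    if split is not None and ((c1 > len(split.t1)).any() or (c2 > len(split.t2)).any()):
        raise ValueError("hotspot-year count exceeds period length")
    t = thresholds
    cat = np.select(
        [
            (c1 >= t.consistent_t1_min) & (c2 >= t.consistent_t2_min),
            (c1 >= t.declining_t1_min) & (c2 <= t.declining_t2_max),
            (c1 <= t.emerging_t1_max) & (c2 >= t.emerging_t2_min),
        ],
        [CAT_CONSISTENT, CAT_DECLINING, CAT_EMERGING],
        default=CAT_INCONSISTENT,
    )
    return str(cat[0]) if scalar else cat


def classify_trends(
    result: GiResult,
    split: PeriodSplit,
    thresholds: TrendThresholds | None = None,
) -> pd.DataFrame:
    """Full trend table: cell_id, c1, c2, category."""
    counts = count_hotspot_years(result, split)
    counts["category"] = classify_trend(
        counts["c1"].to_numpy(), counts["c2"].to_numpy(), split, thresholds
    )
    return counts
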