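"""Downing cohort reconstruction of brown bear abundance from harvest-at-age data.

Downing reconstruction is a deterministic virtual-population method: a
cohort's minimum abundance in a year is the sum of its future observed
harvests, so working backward in time N_{i,t} = H_{i,t} + N_{i+1,t+1} for
all but the two oldest age classes. Those two classes are closed by the
assumption that their harvest mortality rates are equal in every year,
which reduces to pooling — the two oldest classes in year t jointly contain
the class-m survivors of year t+1 plus their own year-t harvests, split in
proportion to the two harvests. The method assumes harvest (here, all known
mortalities) is the dominant mortality source and yields a minimum
abundance estimate; the last m−1 data years are unreliable and are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: default ages spanned by the five collapsed classes (class 5 open-ended)
DEFAULT_CLASS_BOUNDS_5 = (0, 2, 5, 9, 14)


@dataclass
class HarvestAtAgeTable:
    """Year × age-class mortality counts.

    `counts` has one row per year (index) and one column per class
    (1..m, youngest first), already scaled so each row sums to that year's
    total known mortalities. `proportion_aged` records A_t, the fraction of
    each year's mortalities that were age-determined.
    """

    counts: pd.DataFrame
    proportion_aged: pd.Series

    @property
    def n_classes(self) -> int:
        return self.counts.shape[1]

    @property
    def years(self) -> np.ndarray:
        return self.counts.index.to_numpy()


@dataclass
class ReconstructionResult:
    """Per-class and total reconstructed abundance, with truncation record."""

    per_class: pd.DataFrame
    total: pd.Series
    truncated_years: list[int] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def build_harvest_matrix(
    mortality_records: pd.DataFrame,
    n_classes: int = 5,
    class_bounds: tuple[int, ...] = DEFAULT_CLASS_BOUNDS_5,
    unaged_allocation: str = "proportional",
) -> HarvestAtAgeTable:
    """Bin aged mortalities into classes and allocate un-aged ones.

    Parameters
    ----------
    mortality_records : one row per year with columns ``year``,
        ``total_mortalities``, and either per-class counts ``class_1..class_m``
        or per-age counts ``age_<k>``.
    class_bounds : lower age bound of each class; ages ≥ the last bound fall
        in the oldest class.
    unaged_allocation : "proportional" spreads each year's un-aged animals
        over that year's aged class distribution (row sums then equal the
        total known mortalities); "uniform" spreads them evenly; "error"
        raises when a year has mortalities but no aged animals.
    """
    if len(class_bounds) != n_classes:
        raise ValueError("class_bounds must have one lower bound per class")
    recs = mortality_records.set_index("year").sort_index()
    class_cols = [f"class_{i}" for i in range(1, n_classes + 1)]
    if all(c in recs.columns for c in class_cols):
        aged = recs[class_cols].to_numpy(dtype=float)
    else:
        age_cols = sorted(
            (c for c in recs.columns if c.startswith("age_")),
            key=lambda c: int(c.split("_")[1]),
        )
        if not age_cols:
            raise ValueError("need class_1..class_m or age_<k> columns")
        ages = np.array([int(c.split("_")[1]) for c in age_cols])
        cls = np.searchsorted(np.asarray(class_bounds), ages, side="right") - 1
        if (cls < 0).any():
            raise ValueError("age below the first class bound")
        aged = np.zeros((len(recs), n_classes))
        raw = recs[age_cols].to_numpy(dtype=float)
        for j, c in enumerate(cls):
            aged[:, c] += raw[:, j]

    totals = recs["total_mortalities"].to_numpy(dtype=float)
    aged_sums = aged.sum(axis=1)
    if (aged_sums - totals > 1e-9).any():
        raise ValueError("aged counts exceed total mortalities in some year")
    alloc = np.array(aged, dtype=float)
    for i, (s, tot) in enumerate(zip(aged_sums, totals)):
        extra = tot - s
        if extra <= 0:
            continue
        if s > 0:
            alloc[i] += extra * aged[i] / s
        elif unaged_allocation == "uniform":
            log.warning("year %s: no aged animals; uniform allocation",
                        recs.index[i])
            alloc[i] += extra / n_classes
        elif unaged_allocation == "proportional":
            raise ValueError(
                f"year {recs.index[i]}: un-aged mortalities but no aged animals"
            )
        else:
            raise ValueError(f"unknown allocation rule {unaged_allocation!r}")
    counts = pd.DataFrame(alloc, index=recs.index, columns=class_cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(totals > 0, aged_sums / totals, 1.0)
    return HarvestAtAgeTable(counts, pd.Series(prop, index=recs.index,
                                               name="proportion_aged"))


def downing_reconstruct(
    table: HarvestAtAgeTable, closure: str = "equal-rate"
) -> ReconstructionResult:
    """Reconstruct per-class and total abundance from a harvest-at-age table.

    `closure` selects how the two oldest classes are closed each year:
    "equal-rate" (equal harvest mortality rate in classes m−1 and m; the
    pooled old group is split in proportion to the two harvests) or
    "minimum-alive" (each class keeps only its own summed future harvests;
    old-group survivors are assigned to class m).

    The last m−1 data years are dropped from the output.
    """
    if closure not in ("equal-rate", "minimum-alive"):
        raise ValueError(f"unknown closure {closure!r}")
    H = table.counts.to_numpy(dtype=float)
    years = table.counts.index.to_numpy()
    T, m = H.shape
    if T < m + 1:
        raise ValueError(f"need at least {m + 1} consecutive years, got {T}")
    if not np.all(np.diff(years) == 1):
        raise ValueError("years must be consecutive")

    N = np.zeros_like(H)
    notes: list[str] = []
    # terminal year: minimum-alive, i.e. only the year's own harvest is known
    N[T - 1] = H[T - 1]
    for t in range(T - 2, -1, -1):
        # younger classes: cohort steps into class i+1 next year
        for i in range(m - 2):
            N[t, i] = H[t, i] + N[t + 1, i + 1]
        pool = N[t + 1, m - 1] + H[t, m - 2] + H[t, m - 1]
        h_pair = H[t, m - 2] + H[t, m - 1]
        if closure == "equal-rate" and h_pair > 0:
            N[t, m - 2] = pool * H[t, m - 2] / h_pair
            N[t, m - 1] = pool * H[t, m - 1] / h_pair
        else:
            if closure == "equal-rate":
                notes.append(
                    f"year {years[t]}: no old-class harvest; minimum-alive fallback"
                )
                log.warning(notes[-1])
            # minimum-alive: survivors stay in the oldest class
            N[t, m - 2] = H[t, m - 2]
            N[t, m - 1] = H[t, m - 1] + N[t + 1, m - 1]

    keep = T - (m - 1)
    per_class = pd.DataFrame(N[:keep], index=years[:keep],
                             columns=table.counts.columns)
    total = per_class.sum(axis=1)
    total.name = "total_abundance"
    truncated = [int(y) for y in years[keep:]]
    if truncated:
        log.info("dropped %d most recent years from reconstruction: %s",
                 len(truncated), truncated)
    return ReconstructionResult(per_class, total, truncated, notes)
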