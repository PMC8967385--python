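"""Per-copy methylation quantification, class labels and donor concordance.

The per-copy level is the unweighted mean of per-site methylation levels
(methylated reads / total reads) over CpGs with at least ``min_depth`` reads;
a copy is analyzable only when it holds at least ``min_cpgs`` such sites.
Analyzable copies are classified low (< 20%), medium (20–60%) or high
(>= 60%), and copies analyzable in two donors get a joint concordance label:
common high, common low, high-and-low (donor 1 high, donor 2 low) or other.
"""

from __future__ import annotations

import bisect
import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .copy_catalog import RepeatCopy
from .io_formats import CpGRecord, GenomicInterval


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Filter constants: class boundaries, depth and CpG-count floors.

    ``low_max``/``high_min`` are the class boundaries on the mean level,
    ``min_depth`` the per-site read floor, ``min_cpgs`` the per-copy count
    of passing sites below which the copy is not analyzable, and
    ``full_length_fraction`` the consensus-coverage floor for copy selection.
    """

    low_max: float = 0.20
    high_min: float = 0.60
    min_depth: int = 5
    min_cpgs: int = 10
    full_length_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.low_max < self.high_min < 1.0):
            raise ValueError("need 0 < low_max < high_min < 1")


@dataclasses.dataclass(frozen=True)
class CopyMethylation:
    """Per-copy mean level and analyzable-CpG count for one sample."""

    copy_id: str
    mean_level: float | None
    n_cpgs_analyzable: int

    @property
    def analyzable(self) -> bool:
        return self.mean_level is not None


class CpGIndex:
    """Sorted per-chromosome arrays of CpG positions and counts.

    Built once from a record list, then queried per copy interval by binary
    search; equivalent to filtering the flat record list for every copy.
    """

    def __init__(self, records: Iterable[CpGRecord]):
        by_chrom: dict[str, list[CpGRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        self._pos: dict[str, np.ndarray] = {}
        self._meth: dict[str, np.ndarray] = {}
        self._total: dict[str, np.ndarray] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r.pos)
            self._pos[chrom] = np.array([r.pos for r in recs], dtype=np.int64)
            self._meth[chrom] = np.array([r.meth_reads for r in recs], dtype=np.int64)
            self._total[chrom] = np.array([r.total_reads for r in recs], dtype=np.int64)

    def query(self, chrom: str, start: int, end: int):
        """(positions, meth, total) arrays for CpGs with start <= pos < end."""
        if chrom not in self._pos:
            empty = np.array([], dtype=np.int64)
            return empty, empty, empty
        pos = self._pos[chrom]
        lo = bisect.bisect_left(pos, start)
        hi = bisect.bisect_left(pos, end)
        return pos[lo:hi], self._meth[chrom][lo:hi], self._total[chrom][lo:hi]


def site_level(rec: CpGRecord, min_depth: int = 5) -> float | None:
    """Methylation level of one CpG, or ``None`` when below the depth floor."""
    if rec.total_reads < min_depth:
        return None
    return rec.meth_reads / rec.total_reads


def copy_methylation(
    copy: RepeatCopy,
    cpgs: Sequence[CpGRecord] | CpGIndex,
    thresholds: Thresholds = Thresholds(),
    region: GenomicInterval | None = None,
) -> CopyMethylation:
    """Mean methylation of the CpGs inside a copy, with the analyzability rule.

    Collects CpGs with position in [start, end) (or in ``region``, e.g. to
    restrict SVAs to their VNTR), keeps those at or above the depth floor and
    averages their levels without weighting.  Copies with fewer than
    ``min_cpgs`` passing sites are returned not-analyzable.
    """
    index = cpgs if isinstance(cpgs, CpGIndex) else CpGIndex(cpgs)
    iv = region if region is not None else copy.interval
    _, meth, total = index.query(iv.chrom, iv.start, iv.end)
    keep = total >= thresholds.min_depth
    n = int(keep.sum())
    if n < thresholds.min_cpgs:
        return CopyMethylation(copy.copy_id, None, n)
    levels = meth[keep] / total[keep]
    return CopyMethylation(copy.copy_id, float(levels.mean()), n)


def classify_methylation(level: float, thresholds: Thresholds = Thresholds()) -> str:
    """Three-way class label: low < 0.20 <= medium < 0.60 <= high."""
    if not (0.0 <= level <= 1.0):
        raise ValueError(f"methylation level {level} outside [0, 1]")
    if level < thresholds.low_max:
        return "low"
    if level < thresholds.high_min:
        return "medium"
    return "high"


def concordance_class(
    level_d1: float,
    level_d2: float,
    thresholds: Thresholds = Thresholds(),
    mirrored: bool = False,
) -> str:
    """Two-donor joint label for a copy analyzable in both donors.

    ``high_and_low`` is directional (donor 1 high, donor 2 low); with
    ``mirrored=True`` the opposite configuration is reported as
    ``low_and_high`` instead of ``other``.
    """
    hi1 = level_d1 >= thresholds.high_min
    hi2 = level_d2 >= thresholds.high_min
    lo1 = level_d1 < thresholds.low_max
    lo2 = level_d2 < thresholds.low_max
    if hi1 and hi2:
        return "common_high"
    if lo1 and lo2:
        return "common_low"
    if hi1 and lo2:
        return "high_and_low"
    if mirrored and lo1 and hi2:
        return "low_and_high"
    return "other"


def family_summary(
    copy_meth: Sequence[CopyMethylation],
    subtype_of: Mapping[str, str],
    thresholds: Thresholds = Thresholds(),
    reporting_floor: int = 30,
) -> pd.DataFrame:
    """Per-subtype copy count, median level and low/medium/high fractions.

    Subtypes with fewer analyzable copies than ``reporting_floor`` (default
    30, the floor used when reporting per-type distributions) are flagged in
    the ``below_floor`` column rather than dropped.
    """
    per_subtype: dict[str, list[float]] = {}
    for cm in copy_meth:
        if not cm.analyzable:
            continue
        per_subtype.setdefault(subtype_of[cm.copy_id], []).append(cm.mean_level)
    rows = []
    for subtype in sorted(per_subtype):
        levels = np.array(per_subtype[subtype])
        labels = [classify_methylation(l, thresholds) for l in levels]
        n = len(levels)
        rows.append(
            {
                "subtype": subtype,
                "n": n,
                "median_level": float(np.median(levels)),
                "frac_low": labels.count("low") / n,
                "frac_medium": labels.count("medium") / n,
                "frac_high": labels.count("high") / n,
                "below_floor": n < reporting_floor,
            }
        )
    return pd.DataFrame(rows)
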