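"""Two-sample differentially methylated region (DMR) calling.

The candidate stage is deliberately simple plumbing: sliding windows of
shared analyzable CpGs whose mean methylation difference exceeds a seed
threshold, merged when they overlap.  The normative step is the refinement
filter: a candidate survives only if it holds a run of at least
``min_successive`` consecutive CpGs analyzable (depth >= ``min_depth``) in
both samples and its analyzable-CpG mean levels differ by at least
``min_diff``.  Refined regions are then annotated for overlap with a repeat
family (SVA by default).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .copy_catalog import RepeatCopy
from .io_formats import CpGRecord, GenomicInterval


@dataclasses.dataclass(frozen=True)
class DMRegion:
    """A refined differentially methylated region between two donors."""

    interval: GenomicInterval
    mean_d1: float
    mean_d2: float
    n_cpgs_both: int
    overlaps_sva: bool = False

    @property
    def direction(self) -> str:
        return "d1_hyper" if self.mean_d1 > self.mean_d2 else "d2_hyper"

    @property
    def diff(self) -> float:
        return abs(self.mean_d1 - self.mean_d2)


def _aligned_arrays(
    cpgs_d1: Sequence[CpGRecord], cpgs_d2: Sequence[CpGRecord]
):
    """Per-chromosome union of CpG positions with per-sample counts.

    Returns {chrom: (pos, meth1, tot1, meth2, tot2)} where a missing site in
    a sample has zero total (so it never passes a depth filter).
    """
    d1 = {(r.chrom, r.pos): r for r in cpgs_d1}
    d2 = {(r.chrom, r.pos): r for r in cpgs_d2}
    out = {}
    keys = sorted(set(d1) | set(d2))
    from itertools import groupby

    for chrom, grp in groupby(keys, key=lambda k: k[0]):
        positions = [k[1] for k in grp]
        pos = np.array(positions, dtype=np.int64)
        m1 = np.zeros(pos.size, dtype=np.int64)
        t1 = np.zeros(pos.size, dtype=np.int64)
        m2 = np.zeros(pos.size, dtype=np.int64)
        t2 = np.zeros(pos.size, dtype=np.int64)
        for i, p in enumerate(positions):
            r1 = d1.get((chrom, p))
            r2 = d2.get((chrom, p))
            if r1 is not None:
                m1[i], t1[i] = r1.meth_reads, r1.total_reads
            if r2 is not None:
                m2[i], t2[i] = r2.meth_reads, r2.total_reads
        out[chrom] = (pos, m1, t1, m2, t2)
    return out


def candidate_dmrs(
    cpgs_d1: Sequence[CpGRecord],
    cpgs_d2: Sequence[CpGRecord],
    window_cpgs: int = 10,
    step: int = 1,
    seed_diff: float = 0.25,
    min_depth: int = 5,
) -> list[GenomicInterval]:
    """Candidate differential spans from a sliding CpG window.

    Windows of ``window_cpgs`` consecutive CpGs analyzable in both samples
    are slid ``step`` CpGs at a time; windows whose mean levels differ by at
    least ``seed_diff`` are merged when their genomic spans overlap, and each
    merged span is trimmed to the first and last CpG whose own difference
    reaches ``seed_diff`` (windows straddling a boundary otherwise drag
    flat flanking sites into the span).
    """
    aligned = _aligned_arrays(cpgs_d1, cpgs_d2)
    candidates: list[GenomicInterval] = []
    for chrom in sorted(aligned):
        pos, m1, t1, m2, t2 = aligned[chrom]
        ok = (t1 >= min_depth) & (t2 >= min_depth)
        pos, m1, t1, m2, t2 = (a[ok] for a in (pos, m1, t1, m2, t2))
        if pos.size < window_cpgs:
            continue
        l1 = m1 / t1
        l2 = m2 / t2
        csum = np.concatenate([[0.0], np.cumsum(l1 - l2)])
        n = pos.size - window_cpgs + 1
        starts = np.arange(0, n, step)
        diffs = np.abs(
            (csum[starts + window_cpgs] - csum[starts]) / window_cpgs
        )
        hot = starts[diffs >= seed_diff]
        merged: list[list[int]] = []
        for s in hot:
            lo_i, hi_i = int(s), int(s + window_cpgs - 1)
            if merged and lo_i <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi_i)
            else:
                merged.append([lo_i, hi_i])
        site_diff = np.abs(l1 - l2)
        for lo_i, hi_i in merged:
            strong = np.nonzero(site_diff[lo_i : hi_i + 1] >= seed_diff)[0]
            if strong.size == 0:
                continue
            a = int(pos[lo_i + strong[0]])
            b = int(pos[lo_i + strong[-1]]) + 1
            candidates.append(GenomicInterval(chrom, a, b))
    return candidates


def refine_dmrs(
    candidates: Sequence[GenomicInterval],
    cpgs_d1: Sequence[CpGRecord],
    cpgs_d2: Sequence[CpGRecord],
    min_depth: int = 5,
    min_successive: int = 10,
    min_diff: float = 0.40,
    successive: bool = True,
) -> list[DMRegion]:
    """Apply the confirmation filter to candidate regions.

    Within each candidate, a CpG is analyzable when its depth is at least
    ``min_depth`` in both samples.  The candidate is kept iff (a) the union
    of observed CpG positions contains a run of at least ``min_successive``
    consecutive analyzable sites uninterrupted by a non-analyzable one (or,
    with ``successive=False``, simply that many analyzable sites in total),
    and (b) the means over analyzable CpGs differ by at least ``min_diff``.
    """
    aligned = _aligned_arrays(cpgs_d1, cpgs_d2)
    out: list[DMRegion] = []
    for cand in candidates:
        if cand.chrom not in aligned:
            continue
        pos, m1, t1, m2, t2 = aligned[cand.chrom]
        sel = (pos >= cand.start) & (pos < cand.end)
        if not sel.any():
            continue
        ok = (t1[sel] >= min_depth) & (t2[sel] >= min_depth)
        n_ok = int(ok.sum())
        if n_ok == 0:
            continue
        if successive:
            best_run = run = 0
            for flag in ok:
                run = run + 1 if flag else 0
                best_run = max(best_run, run)
            if best_run < min_successive:
                continue
        elif n_ok < min_successive:
            continue
        mean1 = float((m1[sel][ok] / t1[sel][ok]).mean())
        mean2 = float((m2[sel][ok] / t2[sel][ok]).mean())
        if abs(mean1 - mean2) < min_diff:
            continue
        out.append(DMRegion(cand, mean1, mean2, n_ok))
    return out


def annotate_dmrs(
    dmrs: Sequence[DMRegion],
    repeats: Sequence[RepeatCopy],
    family: str = "SVA",
) -> tuple[list[DMRegion], pd.DataFrame]:
    """Flag DMRs overlapping a repeat family and summarise per direction.

    A DMR overlaps when it intersects any repeat of the family by >= 1 bp
    (half-open intervals, so abutting features do not count).  Returns the
    flagged DMR list and a per-direction summary table with the overlap
    fraction.
    """
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        if rep.family != family:
            continue
        iv = rep.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    flagged: list[DMRegion] = []
    for d in dmrs:
        tree = trees.get(d.interval.chrom)
        hit = bool(tree is not None and tree.overlap(d.interval.start, d.interval.end))
        flagged.append(dataclasses.replace(d, overlaps_sva=hit))
    rows = []
    for direction in ("d1_hyper", "d2_hyper"):
        members = [d for d in flagged if d.direction == direction]
        n = len(members)
        n_ov = sum(d.overlaps_sva for d in members)
        rows.append(
            {
                "direction": direction,
                "n_dmrs": n,
                "n_overlapping": n_ov,
                "fraction_overlapping": n_ov / n if n else 0.0,
            }
        )
    summary = pd.DataFrame(rows)
    return flagged, summary
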