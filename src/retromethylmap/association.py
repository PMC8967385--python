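"""Associations between methylation classes and binding peaks, motifs,
VNTR unit numbers, and gene expression, plus the statistical tests used
to compare them.

Motif occurrences are found by log-odds scanning of a position weight matrix
over both strands, with an exact match p-value computed by dynamic
programming over the integer-scaled score distribution under the background
model — the classical exact-scan construction, so hit sets are deterministic
and reproducible for a given p threshold.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .copy_catalog import RepeatCopy
from .io_formats import PWM, GenomicInterval

_SCORE_SCALE = 1000  # integer scaling of bit scores for the exact-p DP

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Motif scanning with exact p-values
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MotifHit:
    """One motif occurrence within a scanned sequence.

    ``offset`` is 0-based within the scanned (forward) sequence; a minus-
    strand hit means the motif matches the reverse complement of the window
    starting there.  ``score`` is the log2-odds score in bits.
    """

    copy_id: str
    offset: int
    strand: str
    score: float
    p_value: float


def _int_score_matrix(pwm: PWM) -> np.ndarray:
    """(w, 5) integer-scaled log2-odds; column 4 (N) contributes zero."""
    logodds = np.log2(pwm.matrix / pwm.background[np.newaxis, :])
    mat = np.rint(logodds * _SCORE_SCALE).astype(np.int64)
    return np.hstack([mat, np.zeros((mat.shape[0], 1), dtype=np.int64)])


def _score_survival(int_scores: np.ndarray, background: np.ndarray):
    """Exact null distribution of the integer window score.

    Dynamic programming over positions: the pmf of the partial sum lives on
    an integer grid, extended one motif position at a time with the four
    base probabilities of the background.  Returns ``(offset, sf)`` where
    ``sf[s - offset] = P(score >= s)``.
    """
    scores = int_scores[:, :4]
    lo = int(scores.min(axis=1).sum())
    hi = int(scores.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # start with the empty sum at 0, stored at index -lo
    pmf[-lo] = 1.0
    cur_lo = 0
    for i in range(scores.shape[0]):
        nxt = np.zeros_like(pmf)
        for b in range(4):
            s = int(scores[i, b])
            p = background[b]
            if s >= 0:
                nxt[s:] += p * (pmf[: pmf.size - s] if s else pmf)
            else:
                nxt[:s] += p * pmf[-s:]
        pmf = nxt
        cur_lo += int(scores[i].min())
    sf = np.cumsum(pmf[::-1])[::-1]
    return lo, sf


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter(
        (_BASE_INDEX.get(c, 4) for c in sequence.upper()),
        dtype=np.int64,
        count=len(sequence),
    )


def _scan_one_strand(
    seq_idx: np.ndarray, pwm: PWM, p_threshold: float, strand: str, copy_id: str
) -> list[MotifHit]:
    w = pwm.width
    n = seq_idx.size
    if n < w:
        return []
    smat = _int_score_matrix(pwm)
    lo, sf = _score_survival(smat, pwm.background)
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, w)
    scores = smat[np.arange(w), windows].sum(axis=1)
    idx = np.clip(scores - lo, 0, sf.size - 1)
    pvals = np.where(scores - lo >= sf.size, 0.0, sf[idx])
    pvals = np.where(scores - lo < 0, 1.0, pvals)
    hits = []
    for off in np.nonzero(pvals <= p_threshold)[0]:
        hits.append(
            MotifHit(
                copy_id=copy_id,
                offset=int(off),
                strand=strand,
                score=float(scores[off]) / _SCORE_SCALE,
                p_value=float(pvals[off]),
            )
        )
    return hits


def scan_motifs(
    sequence: str, pwm: PWM, p_threshold: float = 1e-4, copy_id: str = ""
) -> list[MotifHit]:
    """All motif hits on both strands with exact p-value <= ``p_threshold``.

    Positions containing N contribute zero log-odds.  Hits are sorted by
    offset (plus strand first at equal offsets).  A sequence shorter than
    the motif yields no hits.
    """
    seq_idx = _encode(sequence)
    hits = _scan_one_strand(seq_idx, pwm, p_threshold, "+", copy_id)
    hits += _scan_one_strand(seq_idx, pwm.reverse_complement(), p_threshold, "-", copy_id)
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg q-values for a flat list of p-values."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def motif_count_per_copy(
    copy_seq: str, pwm: PWM, p_threshold: float = 1e-4
) -> int:
    """Number of non-overlapping motif hits in a copy sequence.

    Hits are resolved greedily left to right; at equal offsets the best-
    scoring hit wins.  Tandem-repeat motifs therefore count once per unit
    rather than once per overlapping window.
    """
    hits = scan_motifs(copy_seq, pwm, p_threshold)
    hits.sort(key=lambda h: (h.offset, -h.score))
    count = 0
    cursor = -1
    for h in hits:
        if h.offset > cursor:
            count += 1
            cursor = h.offset + pwm.width - 1
    return count


# ---------------------------------------------------------------------------
# VNTR unit counting
# ---------------------------------------------------------------------------

def estimate_vntr_units(
    copy_seq: str, unit_consensus: str, min_identity: float = 0.8
) -> int:
    """Count tandem-repeat units by greedy consensus tiling.

    Walking left to right, a window of the unit length matching the unit
    consensus with identity >= ``min_identity`` counts as one unit and the
    cursor jumps a full unit; otherwise it advances one base.
    """
    unit = unit_consensus.upper()
    u = len(unit)
    if u < 10:
        raise ValueError("unit consensus must be at least 10 bp")
    seq = copy_seq.upper()
    count = 0
    i = 0
    while i + u <= len(seq):
        window = seq[i : i + u]
        matches = sum(a == b for a, b in zip(window, unit))
        if matches / u >= min_identity:
            count += 1
            i += u
        else:
            i += 1
    return count


# ---------------------------------------------------------------------------
# Peak overlap by methylation class
# ---------------------------------------------------------------------------

def _peak_tree(peaks: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def copy_overlaps_any(
    copy: RepeatCopy,
    trees: dict[str, IntervalTree],
    min_overlap_bp: int = 1,
) -> bool:
    iv = copy.interval
    tree = trees.get(iv.chrom)
    if tree is None:
        return False
    total_by_span: int = 0
    for hit in tree.overlap(iv.start, iv.end):
        ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
        if ov >= min_overlap_bp:
            return True
        total_by_span += ov
    # abutting sub-peaks may individually fall below the floor while their
    # union does not; the union of overlap lengths decides
    return total_by_span >= min_overlap_bp


def overlap_fraction(
    copies_by_class: Mapping[str, Sequence[RepeatCopy]],
    peaks: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Per class: copy count, number overlapping any peak, and the fraction.

    A copy counts as overlapping when peaks intersect it by at least
    ``min_overlap_bp`` in total.  Empty classes get a missing fraction.
    """
    trees = _peak_tree(peaks)
    rows = []
    for label, copies in copies_by_class.items():
        n = len(copies)
        n_overlap = sum(
            copy_overlaps_any(c, trees, min_overlap_bp) for c in copies
        )
        rows.append(
            {
                "class": label,
                "n_copies": n,
                "n_overlapping": n_overlap,
                "fraction": n_overlap / n if n else math.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Count-table tests
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AssociationTest:
    statistic: float
    df: int
    p_value: float
    method: str
    low_expected: bool  # any expected cell < 1


def class_association_test(
    table, continuity_correction: bool = False
) -> AssociationTest:
    """Test whether overlap status depends on methylation class.

    ``table`` is a classes x 2 array of (overlapping, non-overlapping)
    counts.  With two classes a two-proportion z-test is used; with more, a
    Pearson chi-square without continuity correction.  Results carry a flag
    when any expected cell count is below one.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a table with at least two classes")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    expected = np.outer(row, col) / counts.sum()
    low_expected = bool((expected < 1).any())
    if counts.shape == (2, 2):
        x = counts[:, 0]
        n = row
        p_pool = x.sum() / n.sum()
        se = math.sqrt(p_pool * (1 - p_pool) * (1 / n[0] + 1 / n[1]))
        diff = x[0] / n[0] - x[1] / n[1]
        if continuity_correction:
            diff = math.copysign(max(abs(diff) - 0.5 * (1 / n[0] + 1 / n[1]), 0), diff)
        z = diff / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        return AssociationTest(z, 1, float(p), "two_proportion_z", low_expected)
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    if (expected == 0).any():
        # a zero margin makes the test degenerate; flag rather than fail
        return AssociationTest(0.0, df, 1.0, "chi_square", True)
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return AssociationTest(float(chi2), int(df), float(p), "chi_square", low_expected)


# ---------------------------------------------------------------------------
# Metaprofiles over length-normalized copies
# ---------------------------------------------------------------------------

def metaprofile(
    copies: Sequence[RepeatCopy],
    signal: Sequence[GenomicInterval] | Mapping[str, np.ndarray],
    n_bins: int = 100,
) -> np.ndarray:
    """Mean binned signal along length-normalized copies, 5' end first.

    ``signal`` is either a peak interval list (binary per-base coverage) or
    a chrom -> per-base array mapping.  Each copy's span is cut into
    ``n_bins`` near-equal bins; minus-strand copies are reversed so bin 0 is
    the element's 5' end.  Copies shorter than ``n_bins`` are skipped with a
    warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    trees = None
    if not isinstance(signal, Mapping):
        trees = _peak_tree(signal)
    profiles = []
    for copy in copies:
        iv = copy.interval
        if len(iv) < n_bins:
            warnings.warn(f"{copy.copy_id}: shorter than n_bins, skipped")
            continue
        if trees is not None:
            vals = np.zeros(len(iv))
            tree = trees.get(iv.chrom)
            if tree is not None:
                for hit in tree.overlap(iv.start, iv.end):
                    a = max(hit.begin, iv.start) - iv.start
                    b = min(hit.end, iv.end) - iv.start
                    vals[a:b] = 1.0
        else:
            vals = np.asarray(signal[iv.chrom][iv.start : iv.end], dtype=float)
        if iv.strand == "-":
            vals = vals[::-1]
        profiles.append([seg.mean() for seg in np.array_split(vals, n_bins)])
    if not profiles:
        return np.full(n_bins, math.nan)
    return np.asarray(profiles).mean(axis=0)


# ---------------------------------------------------------------------------
# Expression (RPM) and group comparisons
# ---------------------------------------------------------------------------

def expression_rpm(
    gene_counts: pd.DataFrame, cell_types: Mapping[str, str]
) -> pd.DataFrame:
    """Mean reads-per-million per gene and cell type.

    ``gene_counts`` is genes x cells.  Each cell is normalised to RPM
    (count / cell total x 1e6), then cells of a type are averaged without
    weighting.
    """
    totals = gene_counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"cell {zero.index[0]!r} has zero total counts")
    rpm = gene_counts / totals * 1e6
    types = pd.Series({c: cell_types[c] for c in gene_counts.columns})
    return rpm.T.groupby(types).mean().T


def group_comparison(
    values_by_group: Mapping[str, Sequence[float]],
    style: str = "all_pairs",
) -> pd.DataFrame:
    """Pairwise adjusted p-values between groups of numeric values.

    ``all_pairs`` runs Tukey's HSD (studentized-range distribution);
    ``vs_control`` runs Dunnett's test against the first group in mapping
    order.  The method used is recorded in the output.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, g in zip(names, groups):
        if g.size < 2:
            raise ValueError(f"group {name!r} has fewer than two values")
    rows = []
    if style == "all_pairs":
        res = stats.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append(
                    {
                        "group1": names[i],
                        "group2": names[j],
                        "statistic": float(res.statistic[i, j]),
                        "p_adj": float(res.pvalue[i, j]),
                        "method": "tukey_hsd",
                    }
                )
    elif style == "vs_control":
        control, treatments = groups[0], groups[1:]
        res = stats.dunnett(*treatments, control=control)
        for name, statistic, p in zip(names[1:], res.statistic, res.pvalue):
            rows.append(
                {
                    "group1": name,
                    "group2": names[0],
                    "statistic": float(statistic),
                    "p_adj": float(p),
                    "method": "dunnett",
                }
            )
    else:
        raise ValueError(f"unknown style {style!r}")
    return pd.DataFrame(rows)
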