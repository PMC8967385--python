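"""Simulated-read mappability of repeat copies.

A read of fixed length is taken from every start position along a copy and
looked up in the whole genome; the copy's mappability is the fraction of its
reads that occur exactly once (both strands considered).  Occurrence
counting is an exact-match census over every genome window — a strict,
aligner-free definition of "properly mapped"; an optional Hamming-distance
mode admits mismatches for sensitivity checks.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

from .association import reverse_complement
from .copy_catalog import RepeatCopy


@dataclasses.dataclass(frozen=True)
class MappabilityResult:
    copy_id: str
    n_reads: int
    n_unique: int

    @property
    def mappability(self) -> float:
        return self.n_unique / self.n_reads


class GenomeIndex:
    """Exact k-mer occurrence counts over both strands of a genome.

    Observationally equivalent to comparing a read against every window of
    the genome: a window census is taken once, and a read's occurrence count
    is its plus-strand window count plus the count of its reverse
    complement, with a palindromic read counted once per locus.
    """

    def __init__(self, genome: Mapping[str, str], read_length: int):
        self.read_length = read_length
        self._counts: dict[str, int] = {}
        for seq in genome.values():
            s = seq.upper()
            for i in range(len(s) - read_length + 1):
                w = s[i : i + read_length]
                self._counts[w] = self._counts.get(w, 0) + 1

    def count_occurrences(self, read: str) -> int:
        read = read.upper()
        if len(read) != self.read_length:
            raise ValueError(
                f"read length {len(read)} != indexed length {self.read_length}"
            )
        if "N" in read:
            return 0  # N never matches
        rc = reverse_complement(read)
        n = self._counts.get(read, 0)
        if rc != read:  # palindromes hit the same locus on both strands
            n += self._counts.get(rc, 0)
        return n


def simulate_reads(
    copy: RepeatCopy, genome: Mapping[str, str], read_length: int = 100
) -> list[str]:
    """One read per start offset, fully contained in the copy span.

    Reads are genome plus-strand sequence.  A copy shorter than the read
    length defines no reads and raises ``ValueError``.
    """
    iv = copy.interval
    if copy.copy_length < read_length:
        raise ValueError(
            f"{copy.copy_id}: copy length {copy.copy_length} < read length "
            f"{read_length}"
        )
    seq = genome[iv.chrom][iv.start : iv.end].upper()
    return [seq[i : i + read_length] for i in range(len(seq) - read_length + 1)]


def count_occurrences(
    read: str, genome: Mapping[str, str], max_mismatches: int = 0
) -> int:
    """Occurrences of a read on either strand of the whole genome.

    With ``max_mismatches`` > 0 a window matches when its Hamming distance
    to the read (or its reverse complement) is within the allowance; a locus
    matching in both orientations still counts once.
    """
    read = read.upper()
    if not read:
        raise ValueError("empty read")
    if "N" in read:
        return 0
    rc = reverse_complement(read)
    L = len(read)
    total = 0
    for seq in genome.values():
        s = seq.upper()
        for i in range(len(s) - L + 1):
            window = s[i : i + L]
            if max_mismatches == 0:
                if window == read or (rc != read and window == rc):
                    total += 1
            else:
                d_fwd = sum(a != b for a, b in zip(window, read))
                if d_fwd <= max_mismatches:
                    total += 1
                elif rc != read:
                    d_rev = sum(a != b for a, b in zip(window, rc))
                    if d_rev <= max_mismatches:
                        total += 1
    return total


def copy_mappability(
    copy: RepeatCopy,
    genome: Mapping[str, str],
    read_length: int = 100,
    index: GenomeIndex | None = None,
) -> MappabilityResult:
    """Fraction of a copy's simulated reads occurring uniquely in the genome.

    A read is properly mapped iff its genome-wide occurrence count is
    exactly one.  Pass a prebuilt :class:`GenomeIndex` when scoring many
    copies against the same genome.
    """
    reads = simulate_reads(copy, genome, read_length)
    if index is None:
        index = GenomeIndex(genome, read_length)
    n_unique = sum(1 for r in reads if index.count_occurrences(r) == 1)
    return MappabilityResult(copy.copy_id, len(reads), n_unique)
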