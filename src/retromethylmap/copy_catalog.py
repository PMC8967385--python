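"""Full-length retroelement copy selection and genomic-context classification.

A repeat instance counts as full length when its genomic span covers at least
90% of its subtype's consensus length; solo LTRs are kept under the same rule
against the LTR consensus.  Context classification asks whether a copy sits
inside a gene body (any overlap of >= 1 bp with the transcript span, introns
included) and, if so, whether it points against the host gene's direction —
the antisense configuration that matters for transcription-directed
methylation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import GenomicInterval


class ConfigurationError(ValueError):
    """A required consensus length (or similar configuration) is missing."""


class ContextError(ValueError):
    """A context query that is undefined, e.g. an unstranded genic copy."""


CONTEXT_CATEGORIES = ("genic_antisense", "genic_sense", "non_genic")


@dataclasses.dataclass(frozen=True)
class RepeatCopy:
    """A genomic repeat instance.

    ``consensus_length`` may be unset (0) until :func:`select_full_length`
    resolves it from the per-subtype consensus table.
    """

    interval: GenomicInterval
    subtype: str
    family: str
    consensus_length: int = 0
    is_solo_ltr: bool = False

    @property
    def copy_length(self) -> int:
        return len(self.interval)

    @property
    def copy_id(self) -> str:
        iv = self.interval
        return f"{self.subtype}|{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"

    @property
    def consensus_fraction(self) -> float:
        if self.consensus_length <= 0:
            raise ConfigurationError(
                f"{self.copy_id}: consensus length not set"
            )
        return self.copy_length / self.consensus_length


@dataclasses.dataclass(frozen=True)
class GenomicContext:
    category: str
    host_gene: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CONTEXT_CATEGORIES:
            raise ValueError(f"bad context category {self.category!r}")
        genic = self.category.startswith("genic")
        if genic != (self.host_gene is not None):
            raise ValueError("host_gene must be present iff the context is genic")


def select_full_length(
    copies: Sequence[RepeatCopy],
    consensus_lengths: Mapping[str, int],
    min_fraction: float = 0.9,
    ltr_consensus_lengths: Mapping[str, int] | None = None,
) -> list[RepeatCopy]:
    """Keep copies whose span covers >= ``min_fraction`` of their consensus.

    For solo LTRs the LTR consensus length is consulted
    (``ltr_consensus_lengths`` when given, else the main table).  The 90%
    boundary is inclusive and input order is preserved.  Raises
    :class:`ConfigurationError` when a present subtype has no consensus length.
    """
    kept: list[RepeatCopy] = []
    for copy in copies:
        table = consensus_lengths
        if copy.is_solo_ltr and ltr_consensus_lengths is not None:
            table = ltr_consensus_lengths
        if copy.subtype not in table:
            raise ConfigurationError(
                f"no consensus length for subtype {copy.subtype!r}"
            )
        consensus = int(table[copy.subtype])
        if copy.copy_length >= min_fraction * consensus:
            kept.append(dataclasses.replace(copy, consensus_length=consensus))
    return kept


def classify_genomic_context(
    copy: RepeatCopy, genes: Sequence[GenomicInterval]
) -> GenomicContext:
    """Classify a copy as genic (sense/antisense) or non-genic.

    A copy is genic if it overlaps any gene body by >= 1 bp.  With several
    overlapping genes the one with the largest overlap wins; ties go to the
    gene with the smaller start.  The result does not depend on gene order.
    """
    best: GenomicInterval | None = None
    best_key: tuple[int, int] | None = None
    for gene in genes:
        if gene.strand not in ("+", "-"):
            raise ContextError(f"gene {gene.name!r} has no strand")
        ov = copy.interval.overlap_bp(gene)
        if ov >= 1:
            key = (-ov, gene.start)
            if best_key is None or key < best_key:
                best, best_key = gene, key
    if best is None:
        return GenomicContext("non_genic")
    if copy.interval.strand not in ("+", "-"):
        raise ContextError(
            f"{copy.copy_id}: unstranded copy overlaps gene {best.name!r}; "
            "sense/antisense is undefined"
        )
    category = (
        "genic_antisense" if copy.interval.strand != best.strand else "genic_sense"
    )
    return GenomicContext(category, host_gene=best.name or f"{best.chrom}:{best.start}")


def context_fraction_by_class(
    copies_with_context: Sequence[tuple[RepeatCopy, GenomicContext]],
    class_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per methylation class, the fractions of copies in each genomic context.

    Rows are class labels; columns ``genic_antisense``/``genic_sense``/
    ``non_genic`` plus the copy count ``n``.  Fractions sum to one per class;
    classes with no copies are omitted with a warning.
    """
    counts: dict[str, dict[str, int]] = {}
    for copy, ctx in copies_with_context:
        label = class_labels[copy.copy_id]
        counts.setdefault(label, {c: 0 for c in CONTEXT_CATEGORIES})
        counts[label][ctx.category] += 1
    for label in set(class_labels.values()) - set(counts):
        warnings.warn(f"class {label!r} has no copies; fraction row omitted")
    rows = []
    for label in sorted(counts):
        n = sum(counts[label].values())
        row = {"class": label, "n": n}
        row.update({c: counts[label][c] / n for c in CONTEXT_CATEGORIES})
        rows.append(row)
    return pd.DataFrame(rows)
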