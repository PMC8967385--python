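"""Readers and writers for the external file formats used by the pipeline.

All coordinates exposed by this module are 0-based half-open, whatever the
source dialect uses.  Methylation counts are authoritative: the percent
column of a Bismark coverage file is ignored and levels are recomputed from
the methylated/unmethylated read counts.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A malformed line in an input file (reported with its line number)."""


class ValidationError(ValueError):
    """A well-formed record violating an invariant (e.g. meth > total)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CpGRecord:
    """Methylated/total read counts for one CpG in one sample.

    ``pos`` is the 0-based position of the C of the CpG on the plus strand.
    """

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos} on {self.chrom}")
        if self.meth_reads < 0 or self.total_reads < 0:
            raise ValidationError(
                f"negative read count at {self.chrom}:{self.pos} "
                f"(meth={self.meth_reads}, total={self.total_reads})"
            )
        if self.meth_reads > self.total_reads:
            raise ValidationError(
                f"meth_reads > total_reads at {self.chrom}:{self.pos} "
                f"({self.meth_reads} > {self.total_reads})"
            )

    @property
    def level(self) -> float:
        """Methylation level meth/total; NaN when the site has no coverage."""
        if self.total_reads == 0:
            return math.nan
        return self.meth_reads / self.total_reads


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with an optional strand and name."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclasses.dataclass(frozen=True)
class PWM:
    """Position weight matrix with a background model for log-odds scanning.

    ``matrix`` has shape (w, 4) over the alphabet A, C, G, T and each row sums
    to one.  A pseudocount is mixed in at construction so every entry is
    strictly positive and log-odds scores stay finite.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float = 1e-4

    ALPHABET = "ACGT"

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValidationError(f"PWM {self.name}: matrix must be (w, 4)")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-2):
            bad = np.argmin(np.isclose(mat.sum(axis=1), 1.0, atol=1e-2))
            raise ValidationError(
                f"PWM {self.name}: row {bad} sums to {mat.sum(axis=1)[bad]:.3f}"
            )
        if not np.isclose(bg.sum(), 1.0, atol=1e-2):
            raise ValidationError(f"PWM {self.name}: background sums to {bg.sum():.3f}")
        # mix in the pseudocount and renormalise so rows sum to 1 +/- 1e-6
        mat = mat + self.pseudocount
        mat /= mat.sum(axis=1, keepdims=True)
        bg = bg + self.pseudocount
        bg /= bg.sum()
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        """PWM matching the reverse complement of this motif."""
        return PWM(
            name=self.name,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=0.0,
        )


# ---------------------------------------------------------------------------
# CpG methylation tables
# ---------------------------------------------------------------------------

def read_cpg_table(path: str | Path, dialect: str = "bismark_cov") -> list[CpGRecord]:
    """Read a per-CpG methylation call table.

    ``bismark_cov`` is the Bismark coverage format (chrom, 1-based start, end,
    percent, count-methylated, count-unmethylated); the percent column is
    ignored and counts are summed into the total.  ``bedgraph_counts`` is a
    0-based five-column variant (chrom, start, end, count-methylated,
    count-total).  Records are returned sorted by (chrom, pos).
    """
    if dialect not in ("bismark_cov", "bedgraph_counts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[CpGRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bismark_cov":
                    if len(fields) < 6:
                        raise ParseError("expected >= 6 tab-separated fields")
                    chrom, start = fields[0], int(fields[1])
                    meth, unmeth = int(fields[4]), int(fields[5])
                    if unmeth < 0:
                        raise ValidationError(f"negative unmethylated count {unmeth}")
                    rec = CpGRecord(chrom, start - 1, meth, meth + unmeth)
                else:
                    if len(fields) < 5:
                        raise ParseError("expected >= 5 tab-separated fields")
                    chrom, start = fields[0], int(fields[1])
                    meth, total = int(fields[3]), int(fields[4])
                    rec = CpGRecord(chrom, start, meth, total)
            except ValidationError:
                raise
            except (ValueError, ParseError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_cpg_table(
    records: Sequence[CpGRecord], path: str | Path, dialect: str = "bismark_cov"
) -> None:
    """Write CpG records in a dialect ``read_cpg_table`` reads back exactly."""
    with open(path, "w") as fh:
        for r in records:
            if dialect == "bismark_cov":
                pct = 100.0 * r.meth_reads / r.total_reads if r.total_reads else 0.0
                fh.write(
                    f"{r.chrom}\t{r.pos + 1}\t{r.pos + 1}\t{pct:.6f}"
                    f"\t{r.meth_reads}\t{r.total_reads - r.meth_reads}\n"
                )
            elif dialect == "bedgraph_counts":
                fh.write(
                    f"{r.chrom}\t{r.pos}\t{r.pos + 2}\t{r.meth_reads}\t{r.total_reads}\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Repeat annotation
# ---------------------------------------------------------------------------

_RM_FAMILY_MAP = (
    ("SVA", "SVA"),
    ("L1", "L1"),
    ("Alu", "Alu"),
    ("LTR", "LTR"),
    ("ERV", "LTR"),
)


def _normalise_family(class_family: str, subtype: str) -> str:
    for key, fam in _RM_FAMILY_MAP:
        if key in class_family or subtype.startswith(key):
            return fam
    return class_family.split("/")[0] if class_family else ""


def read_repeat_annotation(path: str | Path, dialect: str = "repeatmasker_out"):
    """Read repeat copies from RepeatMasker ``.out`` or BED6.

    RepeatMasker 1-based inclusive query coordinates are converted to 0-based
    half-open, and its strand symbol ``C`` (complement) is mapped to ``-``.
    Returns a list of :class:`~retromethylmap.copy_catalog.RepeatCopy`.
    """
    from .copy_catalog import RepeatCopy  # deferred to avoid an import cycle

    if dialect not in ("repeatmasker_out", "bed6"):
        raise ValueError(f"unknown dialect {dialect!r}")
    copies: list[RepeatCopy] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if dialect == "repeatmasker_out":
                fields = line.split()
                # RepeatMasker header lines start with "SW"/"score" or are blank
                if fields[0] in ("SW", "score") or fields[0].startswith("="):
                    continue
                if len(fields) < 11:
                    raise ParseError(f"{path}, line {lineno}: expected >= 11 fields")
                chrom = fields[4]
                start, end = int(fields[5]) - 1, int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                subtype, class_family = fields[9], fields[10]
            else:
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ParseError(f"{path}, line {lineno}: expected BED6")
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                subtype = fields[3]
                strand = fields[5] if fields[5] in ("+", "-") else "."
                class_family = ""
            if end <= start:
                raise ParseError(
                    f"{path}, line {lineno}: end <= start after conversion"
                )
            family = _normalise_family(class_family, subtype)
            is_solo = dialect == "repeatmasker_out" and family == "LTR" and (
                "int" not in subtype
            )
            copies.append(
                RepeatCopy(
                    interval=GenomicInterval(chrom, start, end, strand, subtype),
                    subtype=subtype,
                    family=family,
                    is_solo_ltr=is_solo,
                )
            )
    return copies


# ---------------------------------------------------------------------------
# BED intervals (peaks, genes)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6/BED12 intervals.

    Only the chrom/start/end span, name and strand are used; BED12 block
    structure is ignored so a gene record yields its full transcript span.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}, line {lineno}: expected >= 3 fields")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand, name)
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Motifs (MEME minimal format)
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path, pseudocount: float = 1e-4) -> list[PWM]:
    """Read motifs from a MEME minimal-format file, one PWM per MOTIF block.

    The background model is taken from the ``Background letter frequencies``
    line when present, otherwise uniform 0.25 per base.
    """
    motifs: list[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            vals: dict[str, float] = {}
            while i < len(lines):
                tok = lines[i].split()
                if len(tok) >= 2 and tok[0] in "ACGT":
                    vals.update(dict(zip(tok[::2], map(float, tok[1::2]))))
                    i += 1
                else:
                    break
            if len(vals) == 4:
                background = np.array([vals[b] for b in "ACGT"])
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else f"motif_{len(motifs)}"
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                l2 = lines[i].strip()
                if l2.startswith("letter-probability"):
                    i += 1
                    continue
                toks = l2.split()
                if len(toks) == 4 and all(_is_float(t) for t in toks):
                    rows.append([float(t) for t in toks])
                    i += 1
                elif not l2:
                    i += 1
                    if rows:
                        break
                else:
                    break
            if not rows:
                raise ParseError(f"{path}: MOTIF {name} has no probability matrix")
            motifs.append(
                PWM(name=name, matrix=np.array(rows), background=background.copy(),
                    pseudocount=pseudocount)
            )
            continue
        i += 1
    return motifs


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_pwm(motifs: Sequence[PWM], path: str | Path) -> None:
    """Write motifs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip("ACGT", bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width}\n")
            for row in m.matrix:
                fh.write("  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into an uppercase chrom -> sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Generic tabular output
# ---------------------------------------------------------------------------

def write_table(records, path: str | Path) -> None:
    """Write any tabular result (DataFrame, dataclasses or dicts) as TSV.

    Floats are fixed at 6 decimals and rows keep their input order, so two
    runs on the same input produce byte-identical files.
    """
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if rows and dataclasses.is_dataclass(rows[0]):
            rows = [dataclasses.asdict(r) for r in rows]
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
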