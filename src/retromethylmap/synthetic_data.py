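"""Seeded generator of a small genome with known ground truth.

The generator emulates, at desk scale, the statistical structure the
analysis assumes: a background genome with embedded retroelement copies of
known subtype, VNTR unit count and divergence; two-donor per-CpG
methylation drawn binomially around latent copy classes; binding peaks
whose placement probability is logistic in the implanted motif count; genes
placed so copies have a chosen genic/antisense context; and per-cell
expression coupled to the methylation acquisition class of antisense
copies.  Every artifact is a pure function of (config, seed); the four
stages (genome, methylomes, peaks, expression) consume independent
documented substreams so one stage can be redrawn without disturbing the
others.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .copy_catalog import RepeatCopy
from .io_formats import CpGRecord, GenomicInterval, PWM

CONC_CLASSES = ("common_high", "common_low", "high_and_low", "other")

# latent per-donor mean-level windows per concordance class
_LEVEL_WINDOWS = {
    "high": (0.75, 0.95),
    "low": (0.02, 0.12),
    "medium": (0.30, 0.50),
}
_CLASS_LEVELS = {
    "common_high": ("high", "high"),
    "common_low": ("low", "low"),
    "high_and_low": ("high", "low"),
    "other": ("medium", "medium"),
}
# VNTR unit-count windows coupled to the donor-1 class
_VNTR_RANGES = {"low": (3, 5), "medium": (5, 8), "high": (8, 12)}
# genomic-context probabilities (antisense, sense, non-genic) per class
_CONTEXT_PROBS = {
    "common_high": (0.60, 0.10, 0.30),
    "common_low": (0.10, 0.10, 0.80),
    "high_and_low": (0.25, 0.10, 0.65),
    "other": (0.30, 0.15, 0.55),
}
# multiplicative log-expression effect of the hosted antisense copy's class
_EXPR_EFFECT = {"common_high": 1.0, "high_and_low": 0.5, "other": 0.25, "common_low": 0.0}


@dataclasses.dataclass
class GeneratorConfig:
    """All knobs of the generator; defaults are the study conditions.

    ``read_depth`` is the mean per-CpG coverage (Poisson), ``class_mixture``
    the probabilities of the two-donor concordance classes, and
    ``peak_logistic`` the (intercept, slope) of the peak-placement logistic
    on the implanted motif count.
    """

    seed: int = 0
    genome_length: int = 400_000
    chrom: str = "chr1"
    n_copies: dict = dataclasses.field(
        default_factory=lambda: {"SVA_A": 60, "SVA_D": 60, "L1PA4": 40, "LTR12C": 40}
    )
    class_mixture: dict = dataclasses.field(
        default_factory=lambda: {
            "common_high": 0.35,
            "common_low": 0.25,
            "high_and_low": 0.20,
            "other": 0.20,
        }
    )
    divergence: float = 0.05
    truncated_fraction: float = 0.10
    read_depth: float = 20.0
    background_meth: float = 0.75
    # SVA-like structure: head + VNTR units + tail; consensus carries
    # ``consensus_vntr_units`` units
    head_length: int = 150
    tail_length: int = 150
    vntr_unit_length: int = 36
    consensus_vntr_units: int = 4
    motif_length: int = 8
    couple_vntr_to_class: bool = True
    peak_logistic: tuple = (-4.0, 0.9)
    min_copy_gap: int = 800
    gene_flank: int = 300
    # implanted differential islands in the background
    n_dmrs: int = 5
    dmr_n_cpgs: int = 30
    dmr_levels: tuple = (0.9, 0.1)
    # expression
    expression_coupling: float = 1.0
    base_expression: float = 50.0
    nb_dispersion: float = 0.3
    n_cells: dict = dataclasses.field(default_factory=lambda: {"SSC2": 40})
    n_background_genes: int = 50

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError("class_mixture probabilities must sum to 1")
        if any(v <= 0 for v in self.n_cells.values()):
            raise ValueError("n_cells entries must be positive")


@dataclasses.dataclass
class TruthTable:
    """Ground truth for every generated entity.

    ``copies`` has one row per copy (including truncated ones) with its
    latent classes, true levels, VNTR/motif counts and context;
    ``dmr_regions`` lists implanted differential islands with their
    per-donor levels.
    """

    copies: pd.DataFrame
    dmr_regions: list  # (GenomicInterval, level_d1, level_d2)
    consensus_lengths: dict
    ltr_consensus_lengths: dict
    vntr_unit: str
    motif: str
    genes: list  # GenomicInterval


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # documented substreams: 0 genome/truth, 1 methylomes, 2 peaks, 3 expression
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    if hit.any():
        alphabet = np.array(list("ACGT"))
        repl = alphabet[rng.integers(0, 4, int(hit.sum()))]
        chars[hit] = repl
    return "".join(chars)


def motif_pwm(motif: str, name: str = "synthetic_znf") -> PWM:
    """Near-deterministic PWM for the implanted motif consensus."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(motif), 4), 0.03)
    for i, base in enumerate(motif):
        mat[i, idx[base]] = 0.91
    return PWM(name=name, matrix=mat, background=np.full(4, 0.25))


def generate_genome(config: GeneratorConfig):
    """Build the genome, repeat annotation and truth table.

    Returns ``(genome, copies, truth)`` where ``genome`` is a chrom ->
    sequence mapping and ``copies`` is the repeat annotation as the
    analysis would receive it (truncated copies included, so the
    full-length filter has something to reject).
    """
    rng = _rng(config, 0)
    # consensus building blocks
    motif = _random_seq(rng, config.motif_length)
    unit = motif + _random_seq(rng, config.vntr_unit_length - config.motif_length)
    heads = {}
    tails = {}
    bodies = {}
    consensus_lengths: dict[str, int] = {}
    for subtype in config.n_copies:
        if subtype.startswith("SVA"):
            heads[subtype] = _random_seq(rng, config.head_length)
            tails[subtype] = _random_seq(rng, config.tail_length)
            consensus_lengths[subtype] = (
                config.head_length
                + config.consensus_vntr_units * config.vntr_unit_length
                + config.tail_length
            )
        else:
            length = config.head_length + config.tail_length + (
                config.consensus_vntr_units * config.vntr_unit_length
            )
            bodies[subtype] = _random_seq(rng, length)
            consensus_lengths[subtype] = length

    # draw per-copy truth
    class_names = list(config.class_mixture)
    class_probs = np.array([config.class_mixture[c] for c in class_names])
    specs = []
    for subtype, n in config.n_copies.items():
        for _ in range(int(n)):
            conc = class_names[rng.choice(len(class_names), p=class_probs)]
            w1, w2 = _CLASS_LEVELS[conc]
            lvl1 = float(rng.uniform(*_LEVEL_WINDOWS[w1]))
            lvl2 = float(rng.uniform(*_LEVEL_WINDOWS[w2]))
            d1_class = w1
            if subtype.startswith("SVA"):
                lo, hi = (
                    _VNTR_RANGES[d1_class]
                    if config.couple_vntr_to_class
                    else (3, 12)
                )
                units = int(rng.integers(lo, hi + 1))
            else:
                units = 0
            truncated = bool(rng.random() < config.truncated_fraction)
            strand = "+" if rng.random() < 0.5 else "-"
            a_ctx, s_ctx, n_ctx = _CONTEXT_PROBS[conc]
            context = ("genic_antisense", "genic_sense", "non_genic")[
                rng.choice(3, p=[a_ctx, s_ctx, n_ctx])
            ]
            specs.append(
                dict(
                    subtype=subtype,
                    conc_class=conc,
                    level_d1=lvl1,
                    level_d2=lvl2,
                    vntr_units=units,
                    truncated=truncated,
                    strand=strand,
                    context=context,
                )
            )
    rng.shuffle(specs)

    # realise sequences
    for spec in specs:
        subtype = spec["subtype"]
        if subtype.startswith("SVA"):
            vntr = unit * spec["vntr_units"]
            raw = heads[subtype] + vntr + tails[subtype]
            vntr_span = (config.head_length, config.head_length + len(vntr))
        else:
            raw = bodies[subtype]
            vntr_span = (0, min(100, len(raw)))
        seq = _mutate(rng, raw, config.divergence)
        if spec["truncated"]:
            frac = rng.uniform(0.70, 0.88)
            keep = int(frac * consensus_lengths[subtype])
            seq = seq[:keep]
            vntr_span = (min(vntr_span[0], keep - 1), min(vntr_span[1], keep))
        # motifs surviving divergence, one per intact unit
        n_motifs = 0
        if subtype.startswith("SVA") and not spec["truncated"]:
            for k in range(spec["vntr_units"]):
                off = config.head_length + k * config.vntr_unit_length
                if seq[off : off + len(motif)] == motif:
                    n_motifs += 1
        spec["seq"] = seq
        spec["motif_count"] = n_motifs
        spec["vntr_span"] = vntr_span

    # DMR islands: CpG-dense blocks in the background
    island_unit = "CGAATTGA"
    island_seq = island_unit * config.dmr_n_cpgs
    islands = [island_seq] * config.n_dmrs

    # place copies and islands with at least min_copy_gap of background
    blocks = [s["seq"] for s in specs] + islands
    fixed = sum(len(b) for b in blocks)
    n_gaps = len(blocks) + 1
    slack = config.genome_length - fixed - n_gaps * config.min_copy_gap
    if slack < 0:
        raise ValueError("copies requested exceed genome capacity")
    extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
    gaps = extra + config.min_copy_gap

    parts: list[str] = []
    cursor = 0
    placements: list[tuple[int, int]] = []
    order = list(range(len(blocks)))
    rng.shuffle(order)
    for gi, bi in enumerate(order):
        bg = _random_seq(rng, int(gaps[gi]))
        parts.append(bg)
        cursor += len(bg)
        parts.append(blocks[bi])
        placements.append((bi, cursor))
        cursor += len(blocks[bi])
    parts.append(_random_seq(rng, int(gaps[-1])))
    genome = {config.chrom: "".join(parts)}

    # assemble truth and annotation
    copies: list[RepeatCopy] = []
    rows = []
    dmr_regions = []
    genes: list[GenomicInterval] = []
    gene_n = 0
    for bi, start in sorted(placements, key=lambda t: t[1]):
        if bi >= len(specs):  # an island
            iv = GenomicInterval(config.chrom, start, start + len(island_seq))
            dmr_regions.append((iv, config.dmr_levels[0], config.dmr_levels[1]))
            continue
        spec = specs[bi]
        end = start + len(spec["seq"])
        iv = GenomicInterval(config.chrom, start, end, spec["strand"], spec["subtype"])
        copy = RepeatCopy(
            interval=iv,
            subtype=spec["subtype"],
            family="SVA" if spec["subtype"].startswith("SVA") else (
                "L1" if spec["subtype"].startswith("L1") else "LTR"
            ),
        )
        copies.append(copy)
        host = None
        if spec["context"] != "non_genic":
            gene_strand = (
                spec["strand"]
                if spec["context"] == "genic_sense"
                else ("-" if spec["strand"] == "+" else "+")
            )
            host = f"gene_{gene_n}"
            gene_n += 1
            genes.append(
                GenomicInterval(
                    config.chrom,
                    max(0, start - config.gene_flank),
                    min(len(genome[config.chrom]), end + config.gene_flank),
                    gene_strand,
                    host,
                )
            )
        rows.append(
            dict(
                copy_id=copy.copy_id,
                subtype=spec["subtype"],
                chrom=config.chrom,
                start=start,
                end=end,
                strand=spec["strand"],
                truncated=spec["truncated"],
                conc_class=spec["conc_class"],
                class_d1=_CLASS_LEVELS[spec["conc_class"]][0],
                class_d2=_CLASS_LEVELS[spec["conc_class"]][1],
                level_d1=spec["level_d1"],
                level_d2=spec["level_d2"],
                vntr_units=spec["vntr_units"],
                motif_count=spec["motif_count"],
                context=spec["context"],
                host_gene=host,
                vntr_start=start + spec["vntr_span"][0],
                vntr_end=start + spec["vntr_span"][1],
            )
        )
    columns = [
        "copy_id", "subtype", "chrom", "start", "end", "strand", "truncated",
        "conc_class", "class_d1", "class_d2", "level_d1", "level_d2",
        "vntr_units", "motif_count", "context", "host_gene",
        "vntr_start", "vntr_end",
    ]
    truth = TruthTable(
        copies=pd.DataFrame(rows, columns=columns),
        dmr_regions=dmr_regions,
        consensus_lengths=consensus_lengths,
        ltr_consensus_lengths=dict(consensus_lengths),
        vntr_unit=unit,
        motif=motif,
        genes=genes,
    )
    return genome, copies, truth


def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.nonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]


def generate_methylomes(
    truth: TruthTable,
    config: GeneratorConfig,
    genome: Mapping[str, str],
) -> tuple[list[CpGRecord], list[CpGRecord]]:
    """Two-donor per-CpG counts: depth ~ Poisson, meth ~ Binomial(site mean).

    Site means are the copy's latent donor level inside full-length copy
    spans, the implanted island levels inside differential islands, and the
    flat background level elsewhere.  Only covered sites are emitted, as a
    coverage-format caller would.
    """
    rng = _rng(config, 1)
    out: tuple[list[CpGRecord], list[CpGRecord]] = ([], [])
    for chrom, seq in genome.items():
        pos = _cpg_positions(seq)
        mean1 = np.full(pos.size, config.background_meth)
        mean2 = np.full(pos.size, config.background_meth)
        rows = truth.copies[truth.copies.chrom == chrom]
        for _, row in rows.iterrows():
            sel = (pos >= row.start) & (pos < row.end)
            mean1[sel] = row.level_d1
            mean2[sel] = row.level_d2
        for iv, l1, l2 in truth.dmr_regions:
            if iv.chrom != chrom:
                continue
            sel = (pos >= iv.start) & (pos < iv.end)
            mean1[sel] = l1
            mean2[sel] = l2
        for donor, means in ((0, mean1), (1, mean2)):
            depth = rng.poisson(config.read_depth, pos.size)
            meth = rng.binomial(depth, means)
            recs = out[donor]
            for p, d, m in zip(pos, depth, meth):
                if d > 0:
                    recs.append(CpGRecord(chrom, int(p), int(m), int(d)))
    return out


def generate_peaks(
    truth: TruthTable, config: GeneratorConfig, seed: int | None = None
) -> list[GenomicInterval]:
    """Binding peaks coupled to motif content.

    Each copy receives a peak with probability
    ``logistic(intercept + slope * motif_count)``; the peak spans the
    copy's motif cluster (its VNTR in genome coordinates).  ``seed``
    overrides the config stream so peak placement can be redrawn on a
    fixed truth.
    """
    rng = (
        np.random.default_rng([int(seed) % (2**31), 2])
        if seed is not None
        else _rng(config, 2)
    )
    intercept, slope = config.peak_logistic
    peaks = []
    for _, row in truth.copies.iterrows():
        eta = intercept + slope * row.motif_count
        p = 1.0 / (1.0 + np.exp(-eta))
        if rng.random() < p:
            a, b = int(row.vntr_start), int(row.vntr_end)
            if b <= a:
                a, b = int(row.start), int(row.start) + 1
            peaks.append(GenomicInterval(row.chrom, a, b, ".", f"peak_{row.copy_id}"))
    return peaks


def generate_expression(
    truth: TruthTable, config: GeneratorConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-cell gene counts with class-coupled host-gene expression.

    Genes hosting an antisense copy are expressed at
    ``base * exp(coupling * effect(class))`` where the effect rises from
    common-low (0) through high-and-low to common-high (1); counts are
    negative binomial.  Background genes carry the base level.
    """
    rng = _rng(config, 3)
    hosts = truth.copies[
        (truth.copies.context == "genic_antisense")
        & truth.copies.host_gene.notna()
    ]
    gene_mu: dict[str, float] = {}
    for _, row in hosts.iterrows():
        effect = _EXPR_EFFECT[row.conc_class]
        gene_mu[row.host_gene] = config.base_expression * float(
            np.exp(config.expression_coupling * effect)
        )
    for g in range(config.n_background_genes):
        gene_mu[f"bg_gene_{g}"] = config.base_expression
    genes = sorted(gene_mu)
    cells = []
    cell_types: dict[str, str] = {}
    for ctype, n in config.n_cells.items():
        for i in range(int(n)):
            cell = f"{ctype}_{i}"
            cells.append(cell)
            cell_types[cell] = ctype
    r = 1.0 / config.nb_dispersion  # NB size parameter
    data = np.empty((len(genes), len(cells)), dtype=np.int64)
    for gi, gene in enumerate(genes):
        mu = gene_mu[gene]
        p = r / (r + mu)
        data[gi] = rng.negative_binomial(r, p, size=len(cells))
    counts = pd.DataFrame(data, index=genes, columns=cells)
    # a dead cell would break RPM normalisation downstream; resample lazily
    totals = counts.sum(axis=0)
    for cell in totals[totals == 0].index:
        counts.loc[genes[0], cell] = 1
    return counts, cell_types


def write_fixture(
    outdir: str | Path, config: GeneratorConfig
) -> dict[str, Path]:
    """Generate everything and write the on-disk fixture set.

    Emits FASTA, BED6 repeat annotation, two Bismark coverage files, peak
    BED, gene BED, expression counts TSV, cell-type TSV, consensus-length
    TSV, the motif in MEME format, and the truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, copies, truth = generate_genome(config)
    meth1, meth2 = generate_methylomes(truth, config, genome)
    peaks = generate_peaks(truth, config)
    counts, cell_types = generate_expression(truth, config)

    paths = {
        "genome": outdir / "genome.fa",
        "repeats": outdir / "repeats.bed",
        "cov_d1": outdir / "donor1.cov",
        "cov_d2": outdir / "donor2.cov",
        "peaks": outdir / "peaks.bed",
        "genes": outdir / "genes.bed",
        "counts": outdir / "expression_counts.tsv",
        "cell_types": outdir / "cell_types.tsv",
        "consensus": outdir / "consensus_lengths.tsv",
        "motifs": outdir / "motifs.meme",
        "truth": outdir / "truth.tsv",
    }
    io_formats.write_fasta(genome, paths["genome"])
    io_formats.write_bed([c.interval for c in copies], paths["repeats"])
    io_formats.write_cpg_table(meth1, paths["cov_d1"])
    io_formats.write_cpg_table(meth2, paths["cov_d2"])
    io_formats.write_bed(peaks, paths["peaks"])
    io_formats.write_bed(truth.genes, paths["genes"])
    counts.to_csv(paths["counts"], sep="\t")
    pd.Series(cell_types, name="cell_type").rename_axis("cell").to_csv(
        paths["cell_types"], sep="\t"
    )
    pd.Series(truth.consensus_lengths, name="consensus_length").rename_axis(
        "subtype"
    ).to_csv(paths["consensus"], sep="\t")
    io_formats.write_pwm([motif_pwm(truth.motif)], paths["motifs"])
    io_formats.write_table(truth.copies, paths["truth"])
    return paths
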