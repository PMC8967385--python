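"""Orchestration of the two composite analyses.

``run_resistance_analysis`` reproduces the single-sample workflow: select
full-length copies, quantify and classify per-copy methylation, then relate
the classes to binding-peak overlap, motif content, VNTR unit number and
read mappability.  ``run_sperm_analysis`` reproduces the two-donor
workflow: concordance classes, genomic-context fractions, host-gene
expression comparison, and the DMR census with repeat-family overlap.

Both runs are pure functions of their inputs; each writes its tables to the
output directory together with a manifest of content hashes, and logs
record counts at stage boundaries so the filter survival of every stage is
auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import association, copy_catalog, dmr, io_formats, mappability, methylome
from .copy_catalog import RepeatCopy
from .io_formats import GenomicInterval
from .methylome import Thresholds

logger = logging.getLogger("retromethylmap")


@dataclasses.dataclass
class RunConfig:
    """Paths and parameters for a pipeline run (loadable from YAML)."""

    repeats: str
    consensus_lengths: str
    outdir: str
    coverage: list = dataclasses.field(default_factory=list)  # donor order
    genome: str | None = None
    genes: str | None = None
    peaks: str | None = None
    motifs: str | None = None
    expression_counts: str | None = None
    cell_types: str | None = None
    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)
    motif_p_threshold: float = 1e-4
    read_length: int = 100
    dmr_window_cpgs: int = 10
    dmr_seed_diff: float = 0.25
    dmr_min_successive: int = 10
    dmr_min_diff: float = 0.40
    dmr_family: str = "SVA"
    repeat_dialect: str = "bed6"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        cfg = cls(**raw)
        for field in ("repeats", "consensus_lengths"):
            p = getattr(cfg, field)
            if not Path(p).exists():
                raise FileNotFoundError(f"{field}: {p}")
        return cfg


def load_consensus_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(int)))


def copies_to_table(copies: Sequence[RepeatCopy]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "copy_id": c.copy_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "strand": c.interval.strand,
            "subtype": c.subtype,
            "family": c.family,
            "consensus_length": c.consensus_length,
            "is_solo_ltr": c.is_solo_ltr,
        }
        for c in copies
    )


def copies_from_table(df: pd.DataFrame) -> list[RepeatCopy]:
    return [
        RepeatCopy(
            interval=GenomicInterval(
                r.chrom, int(r.start), int(r.end), r.strand, r.subtype
            ),
            subtype=r.subtype,
            family=r.family,
            consensus_length=int(r.consensus_length),
            is_solo_ltr=bool(r.is_solo_ltr),
        )
        for r in df.itertuples()
    ]


def _copy_sequence(copy: RepeatCopy, genome: dict[str, str]) -> str:
    seq = genome[copy.interval.chrom][copy.interval.start : copy.interval.end]
    if copy.interval.strand == "-":
        seq = association.reverse_complement(seq)
    return seq


def _write_outputs(tables: dict[str, pd.DataFrame], outdir: Path) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, table in tables.items():
        path = outdir / f"{name}.tsv"
        io_formats.write_table(table, path)
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _select_copies(config: RunConfig) -> list[RepeatCopy]:
    copies = io_formats.read_repeat_annotation(config.repeats, config.repeat_dialect)
    logger.info("repeat annotation: %d copies", len(copies))
    consensus = load_consensus_lengths(config.consensus_lengths)
    full = copy_catalog.select_full_length(
        copies, consensus, config.thresholds.full_length_fraction
    )
    logger.info("full-length filter: %d of %d copies kept", len(full), len(copies))
    return full


def _classified_copies(
    config: RunConfig, cov_path: str
) -> tuple[list[RepeatCopy], dict[str, float], dict[str, str]]:
    full = _select_copies(config)
    records = io_formats.read_cpg_table(cov_path)
    logger.info("%s: %d CpG records", cov_path, len(records))
    index = methylome.CpGIndex(records)
    levels: dict[str, float] = {}
    for copy in full:
        cm = methylome.copy_methylation(copy, index, config.thresholds)
        if cm.analyzable:
            levels[copy.copy_id] = cm.mean_level
    labels = {
        cid: methylome.classify_methylation(lvl, config.thresholds)
        for cid, lvl in levels.items()
    }
    logger.info("analyzable copies: %d of %d", len(levels), len(full))
    return full, levels, labels


def run_resistance_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Single-sample demethylation-resistance workflow (PGC-style)."""
    if len(config.coverage) < 1:
        raise ValueError("resistance analysis needs one coverage file")
    full, levels, labels = _classified_copies(config, config.coverage[0])
    analyzable = [c for c in full if c.copy_id in levels]
    subtype_of = {c.copy_id: c.subtype for c in full}

    tables: dict[str, pd.DataFrame] = {}
    copy_meths = [
        methylome.CopyMethylation(cid, lvl, config.thresholds.min_cpgs)
        for cid, lvl in levels.items()
    ]
    tables["family_summary"] = methylome.family_summary(
        copy_meths, subtype_of, config.thresholds
    )
    tables["copy_methylation"] = pd.DataFrame(
        {
            "copy_id": cid,
            "subtype": subtype_of[cid],
            "mean_level": lvl,
            "class": labels[cid],
        }
        for cid, lvl in levels.items()
    )

    by_class = {"low": [], "medium": [], "high": []}
    for copy in analyzable:
        by_class[labels[copy.copy_id]].append(copy)

    if config.peaks:
        peaks = io_formats.read_bed(config.peaks)
        logger.info("peaks: %d intervals", len(peaks))
        overlap = association.overlap_fraction(by_class, peaks)
        tables["class_overlap"] = overlap
        counts = overlap[["n_overlapping"]].copy()
        counts["n_non_overlapping"] = overlap.n_copies - overlap.n_overlapping
        nonempty = counts[overlap.n_copies > 0]
        if len(nonempty) >= 2:
            test = association.class_association_test(nonempty.to_numpy())
            tables["class_overlap_test"] = pd.DataFrame([dataclasses.asdict(test)])

    if config.motifs and config.genome:
        genome = io_formats.read_fasta(config.genome)
        pwms = io_formats.read_pwm(config.motifs)
        rows = []
        for pwm in pwms:
            for copy in analyzable:
                seq = _copy_sequence(copy, genome)
                rows.append(
                    {
                        "motif": pwm.name,
                        "copy_id": copy.copy_id,
                        "class": labels[copy.copy_id],
                        "motif_count": association.motif_count_per_copy(
                            seq, pwm, config.motif_p_threshold
                        ),
                    }
                )
        motif_table = pd.DataFrame(rows)
        tables["motif_counts"] = motif_table
        cmp_rows = []
        for motif_name, grp in motif_table.groupby("motif"):
            groups = {
                label: sub.motif_count.to_list()
                for label, sub in grp.groupby("class")
                if len(sub) >= 2
            }
            if len(groups) >= 2:
                cmp = association.group_comparison(groups, style="all_pairs")
                cmp.insert(0, "motif", motif_name)
                cmp_rows.append(cmp)
        if cmp_rows:
            tables["motif_count_comparison"] = pd.concat(cmp_rows, ignore_index=True)

    if config.genome:
        genome = io_formats.read_fasta(config.genome)
        index = mappability.GenomeIndex(genome, config.read_length)
        rows = []
        for copy in analyzable:
            if copy.copy_length < config.read_length:
                continue
            res = mappability.copy_mappability(
                copy, genome, config.read_length, index=index
            )
            rows.append(
                {
                    "copy_id": copy.copy_id,
                    "n_reads": res.n_reads,
                    "n_unique": res.n_unique,
                    "mappability": res.mappability,
                }
            )
        tables["mappability"] = pd.DataFrame(rows)

    _write_outputs(tables, Path(config.outdir))
    return tables


def run_sperm_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Two-donor concordance, context, expression and DMR workflow."""
    if len(config.coverage) != 2:
        raise ValueError("sperm analysis needs exactly two coverage files (donor order)")
    full = _select_copies(config)
    cov1 = io_formats.read_cpg_table(config.coverage[0])
    cov2 = io_formats.read_cpg_table(config.coverage[1])
    logger.info("coverage: %d / %d CpG records", len(cov1), len(cov2))
    idx1, idx2 = methylome.CpGIndex(cov1), methylome.CpGIndex(cov2)

    conc: dict[str, str] = {}
    rows = []
    for copy in full:
        cm1 = methylome.copy_methylation(copy, idx1, config.thresholds)
        cm2 = methylome.copy_methylation(copy, idx2, config.thresholds)
        if not (cm1.analyzable and cm2.analyzable):
            continue
        label = methylome.concordance_class(
            cm1.mean_level, cm2.mean_level, config.thresholds
        )
        conc[copy.copy_id] = label
        rows.append(
            {
                "copy_id": copy.copy_id,
                "subtype": copy.subtype,
                "level_d1": cm1.mean_level,
                "level_d2": cm2.mean_level,
                "concordance_class": label,
            }
        )
    tables: dict[str, pd.DataFrame] = {"concordance": pd.DataFrame(rows)}
    logger.info("copies analyzable in both donors: %d of %d", len(conc), len(full))

    if config.genes:
        genes = io_formats.read_bed(config.genes)
        with_context = []
        host_of: dict[str, str | None] = {}
        for copy in full:
            if copy.copy_id not in conc:
                continue
            ctx = copy_catalog.classify_genomic_context(copy, genes)
            with_context.append((copy, ctx))
            host_of[copy.copy_id] = ctx.host_gene if ctx.category == "genic_antisense" else None
        tables["context_fractions"] = copy_catalog.context_fraction_by_class(
            with_context, conc
        )

        if config.expression_counts and config.cell_types:
            counts = pd.read_csv(config.expression_counts, sep="\t", index_col=0)
            ct = pd.read_csv(config.cell_types, sep="\t", index_col=0)
            cell_types = dict(zip(ct.index, ct.iloc[:, 0]))
            rpm = association.expression_rpm(counts, cell_types)
            first_type = rpm.columns[0]
            groups: dict[str, list[float]] = {}
            for cid, host in host_of.items():
                if host is None or host not in rpm.index:
                    continue
                groups.setdefault(conc[cid], []).append(float(rpm.loc[host, first_type]))
            expr_rows = [
                {"class": k, "n_genes": len(v), "mean_rpm": sum(v) / len(v)}
                for k, v in sorted(groups.items())
            ]
            tables["host_gene_expression"] = pd.DataFrame(expr_rows)
            testable = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(testable) >= 2:
                tables["host_gene_expression_test"] = association.group_comparison(
                    testable, style="all_pairs"
                )

    candidates = dmr.candidate_dmrs(
        cov1,
        cov2,
        window_cpgs=config.dmr_window_cpgs,
        seed_diff=config.dmr_seed_diff,
        min_depth=config.thresholds.min_depth,
    )
    logger.info("DMR candidates: %d", len(candidates))
    refined = dmr.refine_dmrs(
        candidates,
        cov1,
        cov2,
        min_depth=config.thresholds.min_depth,
        min_successive=config.dmr_min_successive,
        min_diff=config.dmr_min_diff,
    )
    logger.info("refined DMRs: %d", len(refined))
    flagged, census = dmr.annotate_dmrs(refined, full, family=config.dmr_family)
    tables["dmrs"] = pd.DataFrame(
        {
            "chrom": d.interval.chrom,
            "start": d.interval.start,
            "end": d.interval.end,
            "mean_d1": d.mean_d1,
            "mean_d2": d.mean_d2,
            "n_cpgs_both": d.n_cpgs_both,
            "direction": d.direction,
            "overlaps_family": d.overlaps_sva,
        }
        for d in flagged
    )
    tables["dmr_census"] = census

    _write_outputs(tables, Path(config.outdir))
    return tables
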