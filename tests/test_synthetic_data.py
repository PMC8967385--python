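import numpy as np
import pandas as pd
import pytest

from retromethylmap.association import estimate_vntr_units, expression_rpm, motif_count_per_copy
from retromethylmap.copy_catalog import select_full_length
from retromethylmap.dmr import candidate_dmrs, refine_dmrs
from retromethylmap.methylome import CpGIndex, Thresholds, copy_methylation
from retromethylmap.synthetic_data import (
    GeneratorConfig,
    generate_expression,
    generate_genome,
    generate_methylomes,
    generate_peaks,
    motif_pwm,
)

SMALL = dict(
    genome_length=120_000,
    n_copies={"SVA_A": 20, "SVA_D": 15, "L1PA4": 10},
    n_dmrs=2,
)


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        out = []
        for _ in range(2):
            cfg = GeneratorConfig(seed=11, **SMALL)
            genome, copies, truth = generate_genome(cfg)
            m1, m2 = generate_methylomes(truth, cfg, genome)
            peaks = generate_peaks(truth, cfg)
            counts, ct = generate_expression(truth, cfg)
            out.append((genome, [c.copy_id for c in copies], truth.copies, m1, m2,
                        [(p.start, p.end) for p in peaks], counts, ct))
        a, b = out
        assert a[0] == b[0]
        assert a[1] == b[1]
        pd.testing.assert_frame_equal(a[2], b[2])
        assert a[3] == b[3] and a[4] == b[4]
        assert a[5] == b[5]
        pd.testing.assert_frame_equal(a[6], b[6])
        assert a[7] == b[7]

    def test_different_seeds_differ(self):
        g1, _, _ = generate_genome(GeneratorConfig(seed=1, **SMALL))
        g2, _, _ = generate_genome(GeneratorConfig(seed=2, **SMALL))
        assert g1 != g2


class TestGenomeTruthClosure:
    def test_vntr_truth_recovered_at_zero_divergence(self):
        cfg = GeneratorConfig(seed=3, divergence=0.0, truncated_fraction=0.0, **SMALL)
        genome, copies, truth = generate_genome(cfg)
        seq_of = {c.copy_id: genome[c.interval.chrom][c.interval.start:c.interval.end]
                  for c in copies}
        sva = truth.copies[truth.copies.subtype.str.startswith("SVA")]
        for _, row in sva.iterrows():
            est = estimate_vntr_units(seq_of[row.copy_id], truth.vntr_unit)
            assert est == row.vntr_units
            # with no divergence every unit keeps its motif
            assert row.motif_count == row.vntr_units

    def test_motif_scan_closure_at_zero_divergence(self):
        cfg = GeneratorConfig(seed=5, divergence=0.0, truncated_fraction=0.0, **SMALL)
        genome, copies, truth = generate_genome(cfg)
        pwm = motif_pwm(truth.motif)
        sva = truth.copies[truth.copies.subtype.str.startswith("SVA")].head(10)
        for _, row in sva.iterrows():
            seq = genome[row.chrom][row.start : row.end]
            assert motif_count_per_copy(seq, pwm, 1e-4) == row.vntr_units

    def test_truncated_copies_fail_full_length_filter(self):
        cfg = GeneratorConfig(seed=4, truncated_fraction=0.5, **SMALL)
        _, copies, truth = generate_genome(cfg)
        kept = select_full_length(
            copies, truth.consensus_lengths, 0.9, truth.ltr_consensus_lengths
        )
        kept_ids = {c.copy_id for c in kept}
        for _, row in truth.copies.iterrows():
            assert (row.copy_id in kept_ids) == (not row.truncated)

    def test_capacity_error(self):
        cfg = GeneratorConfig(seed=0, genome_length=10_000,
                              n_copies={"SVA_A": 50}, n_dmrs=0)
        with pytest.raises(ValueError, match="capacity"):
            generate_genome(cfg)


class TestMethylomes:
    def test_degenerate_level_one_gives_site_level_one(self):
        cfg = GeneratorConfig(
            seed=6, background_meth=1.0, n_dmrs=0,
            class_mixture={"common_high": 1.0},
            genome_length=60_000, n_copies={"SVA_A": 5},
        )
        genome, _, truth = generate_genome(cfg)
        truth.copies["level_d1"] = 1.0
        truth.copies["level_d2"] = 1.0
        m1, _ = generate_methylomes(truth, cfg, genome)
        assert all(r.meth_reads == r.total_reads for r in m1)

    def test_flat_background_produces_no_refined_dmrs(self):
        cfg = GeneratorConfig(seed=8, genome_length=60_000, n_copies={}, n_dmrs=0)
        genome, _, truth = generate_genome(cfg)
        m1, m2 = generate_methylomes(truth, cfg, genome)
        cands = candidate_dmrs(m1, m2)
        assert refine_dmrs(cands, m1, m2) == []

    def test_high_and_low_truth_recovered_at_depth_50(self):
        """Copies with true levels (0.9, 0.05) land in high_and_low."""
        from retromethylmap.methylome import concordance_class

        cfg = GeneratorConfig(seed=9, read_depth=50, n_dmrs=0,
                              class_mixture={"high_and_low": 1.0},
                              genome_length=80_000, n_copies={"SVA_D": 25})
        genome, copies, truth = generate_genome(cfg)
        truth.copies["level_d1"] = 0.9
        truth.copies["level_d2"] = 0.05
        m1, m2 = generate_methylomes(truth, cfg, genome)
        idx1, idx2 = CpGIndex(m1), CpGIndex(m2)
        thr = Thresholds()
        hits = total = 0
        for copy in copies:
            c1 = copy_methylation(copy, idx1, thr)
            c2 = copy_methylation(copy, idx2, thr)
            if not (c1.analyzable and c2.analyzable):
                continue
            total += 1
            hits += concordance_class(c1.mean_level, c2.mean_level, thr) == "high_and_low"
        assert total >= 20
        assert hits / total >= 0.95


class TestPeaks:
    def test_zero_copies_give_empty_bed(self):
        cfg = GeneratorConfig(seed=0, genome_length=30_000, n_copies={}, n_dmrs=0)
        _, _, truth = generate_genome(cfg)
        assert generate_peaks(truth, cfg) == []

    def test_positive_coupling_enriches_high_class(self):
        cfg = GeneratorConfig(seed=10, **SMALL)
        _, _, truth = generate_genome(cfg)
        peaks = generate_peaks(truth, cfg)
        spans = [(p.start, p.end) for p in peaks]

        def frac(rows):
            n = 0
            for _, r in rows.iterrows():
                n += any(s < r.end and e > r.start for s, e in spans)
            return n / max(len(rows), 1)

        sva = truth.copies[truth.copies.subtype.str.startswith("SVA")]
        f_high = frac(sva[sva.class_d1 == "high"])
        f_low = frac(sva[sva.class_d1 == "low"])
        assert f_high > f_low

    def test_redraw_with_explicit_seed_changes_only_peaks(self):
        cfg = GeneratorConfig(seed=12, **SMALL)
        _, _, truth = generate_genome(cfg)
        p1 = generate_peaks(truth, cfg, seed=100)
        p2 = generate_peaks(truth, cfg, seed=101)
        p1b = generate_peaks(truth, cfg, seed=100)
        assert [(p.start, p.end) for p in p1] == [(p.start, p.end) for p in p1b]
        assert [(p.start, p.end) for p in p1] != [(p.start, p.end) for p in p2]


class TestExpression:
    def test_coupling_raises_common_high_host_expression(self):
        cfg = GeneratorConfig(seed=13, **SMALL)
        _, _, truth = generate_genome(cfg)
        counts, cell_types = generate_expression(truth, cfg)
        rpm = expression_rpm(counts, cell_types)
        hosts = truth.copies[truth.copies.context == "genic_antisense"]
        mean_of = lambda cls: rpm.loc[
            hosts[hosts.conc_class == cls].host_gene, rpm.columns[0]
        ].mean()
        assert mean_of("common_high") > mean_of("common_low")

    def test_zero_coupling_rarely_significant(self):
        """Null check: without coupling the host-class comparison is flat."""
        from retromethylmap.association import group_comparison

        sig = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = GeneratorConfig(seed=seed, expression_coupling=0.0, **SMALL)
            _, _, truth = generate_genome(cfg)
            counts, cell_types = generate_expression(truth, cfg)
            rpm = expression_rpm(counts, cell_types)
            hosts = truth.copies[truth.copies.context == "genic_antisense"]
            groups = {}
            for cls, sub in hosts.groupby("conc_class"):
                vals = rpm.loc[sub.host_gene, rpm.columns[0]].tolist()
                if len(vals) >= 2:
                    groups[cls] = vals
            if len(groups) < 2:
                continue
            res = group_comparison(groups, style="all_pairs")
            sig += (res.p_adj < 0.05).any()
        assert sig <= n_seeds // 2  # at alpha=0.05 significance should be rare

    def test_all_requested_types_present(self):
        cfg = GeneratorConfig(seed=14, n_cells={"SSC2": 5, "soma": 4}, **SMALL)
        _, _, truth = generate_genome(cfg)
        counts, cell_types = generate_expression(truth, cfg)
        assert set(cell_types.values()) == {"SSC2", "soma"}
        rpm = expression_rpm(counts, cell_types)
        assert set(rpm.columns) == {"SSC2", "soma"}
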