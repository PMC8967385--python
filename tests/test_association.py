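import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_copy
from retromethylmap.association import (
    _int_score_matrix,
    class_association_test,
    estimate_vntr_units,
    expression_rpm,
    group_comparison,
    metaprofile,
    motif_count_per_copy,
    overlap_fraction,
    scan_motifs,
)
from retromethylmap.io_formats import PWM, GenomicInterval


def forcing_pwm(pattern: str, name: str = "force") -> PWM:
    """PWM putting nearly all mass on one word."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(pattern), 4), 0.01)
    for i, b in enumerate(pattern):
        mat[i, idx[b]] = 0.97
    return PWM(name, mat, np.full(4, 0.25))


def brute_force_hits(seq: str, pwm: PWM, thr: float):
    """Independent oracle: enumerate every window on both strands, with the
    exact p-value obtained by full enumeration of all words of the motif
    width under the scan's background."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    w = pwm.width
    words = list(itertools.product(range(4), repeat=w))
    hits = []
    for strand in "+-":
        eff = pwm if strand == "+" else pwm.reverse_complement()
        mat = _int_score_matrix(eff)[:, :4]
        bg = eff.background
        word_scores = np.array(
            [sum(mat[i, b] for i, b in enumerate(word)) for word in words]
        )
        word_probs = np.array(
            [np.prod([bg[b] for b in word]) for word in words]
        )
        for off in range(len(seq) - w + 1):
            score = sum(
                mat[i, idx[c]]
                for i, c in enumerate(seq[off : off + w])
                if idx[c] != 4
            )
            p = word_probs[word_scores >= score].sum()
            if p <= thr:
                hits.append((off, strand))
    return sorted(hits)


class TestScanMotifs:
    def test_forced_ac_on_forward_strand(self):
        hits = scan_motifs("ACGT", forcing_pwm("AC"), p_threshold=0.1)
        # offset 0 forward; the GT window at offset 2 is AC on the minus strand
        assert [(h.offset, h.strand) for h in hits] == [(0, "+"), (2, "-")]
        # the forced word has probability 1/16 under a uniform background
        assert hits[0].p_value == pytest.approx(1 / 16, rel=1e-3)

    def test_reverse_complement_hit(self):
        hits = scan_motifs("GT", forcing_pwm("AC"), p_threshold=0.1)
        assert [(h.offset, h.strand) for h in hits] == [(0, "-")]

    def test_empty_and_short_sequences(self):
        assert scan_motifs("", forcing_pwm("AC"), 0.5) == []
        assert scan_motifs("A", forcing_pwm("AC"), 0.5) == []

    def test_agrees_exactly_with_enumeration_oracle(self, rng):
        """100 random (PWM, sequence, threshold) cases, motif width <= 8."""
        for case in range(100):
            w = int(rng.integers(2, 9))
            pwm = PWM(
                f"m{case}",
                rng.dirichlet(np.full(4, 0.6), size=w),
                rng.dirichlet(np.full(4, 3.0)),
            )
            n = int(rng.integers(w, 201))
            seq = "".join(
                np.array(list("ACGTN"))[rng.choice(5, n, p=[0.24, 0.24, 0.24, 0.24, 0.04])]
            )
            thr = 10 ** rng.uniform(-4, -0.5)
            mine = sorted((h.offset, h.strand) for h in scan_motifs(seq, pwm, thr))
            assert mine == brute_force_hits(seq, pwm, thr), f"case {case}"

    def test_hits_sorted_by_offset(self, rng):
        seq = "ACAC" * 20
        hits = scan_motifs(seq, forcing_pwm("ACAC"), 0.01)
        offsets = [h.offset for h in hits]
        assert offsets == sorted(offsets)


class TestMotifCount:
    def test_three_disjoint_implants(self):
        pwm = forcing_pwm("ACGTAC")
        seq = "ACGTAC" + "T" * 20 + "ACGTAC" + "G" * 20 + "ACGTAC"
        assert motif_count_per_copy(seq, pwm, 1e-3) == 3

    def test_overlapping_candidates_counted_once(self):
        # AAAA-forcing motif: the run AAAAA holds two overlapping windows
        pwm = forcing_pwm("AAAA")
        seq = "CCCAAAAACCC"
        hits = scan_motifs(seq, pwm, 1e-2)
        assert len(hits) >= 2
        assert motif_count_per_copy(seq, pwm, 1e-2) == 1

    def test_random_sequence_has_no_hits_at_stringent_threshold(self, rng):
        pwm = forcing_pwm("ACGTACGT")
        misses = sum(
            motif_count_per_copy(
                "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)]), pwm, 1e-6
            )
            == 0
            for _ in range(20)
        )
        assert misses == 20


class TestVNTRUnits:
    UNIT = "ACGTTGCAAGGTTACG"

    def test_exact_tandem_repeat(self):
        assert estimate_vntr_units(self.UNIT * 5, self.UNIT) == 5

    def test_units_with_ten_percent_divergence(self, rng):
        seq = ""
        for _ in range(3):
            unit = list(self.UNIT)
            for i in rng.choice(len(unit), size=max(1, len(unit) // 10), replace=False):
                unit[i] = "ACGT"[(("ACGT".index(unit[i])) + 1) % 4]
            seq += "".join(unit)
        assert estimate_vntr_units(seq, self.UNIT, min_identity=0.8) == 3

    def test_unit_free_sequence(self):
        assert estimate_vntr_units("T" * 100, self.UNIT) == 0

    def test_short_unit_rejected(self):
        with pytest.raises(ValueError):
            estimate_vntr_units("ACGT", "ACGT")


class TestOverlapFraction:
    def _copies(self, n, start=0, cls="high"):
        return [
            make_copy(start=start + i * 2000, end=start + i * 2000 + 1000)
            for i in range(n)
        ]

    def test_printed_fraction_arithmetic(self):
        """30 of 47 overlapping gives 63.8%; 0 of 8 gives 0."""
        high = self._copies(47)
        low = self._copies(8, start=200_000)
        peaks = [
            GenomicInterval("chr1", c.interval.start + 10, c.interval.start + 60)
            for c in high[:30]
        ]
        table = overlap_fraction({"high": high, "low": low}, peaks).set_index("class")
        assert table.loc["high", "fraction"] == pytest.approx(0.638, abs=5e-4)
        assert table.loc["high", "n_overlapping"] == 30
        assert table.loc["low", "fraction"] == 0.0

    def test_no_peaks_all_zero(self):
        table = overlap_fraction({"a": self._copies(5)}, [])
        assert (table.fraction == 0).all()

    def test_invariant_to_peak_order_and_splitting(self, rng):
        copies = self._copies(20)
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 300)
            for s in rng.integers(0, 40_000, 15)
        ]
        ref = overlap_fraction({"x": copies}, peaks)
        shuffled = list(peaks)[::-1]
        split = []
        for p in peaks:
            mid = (p.start + p.end) // 2
            split += [
                GenomicInterval(p.chrom, p.start, mid),
                GenomicInterval(p.chrom, mid, p.end),
            ]
        assert overlap_fraction({"x": copies}, shuffled).equals(ref)
        assert overlap_fraction({"x": copies}, split).equals(ref)

    def test_empty_class_reported_missing(self):
        table = overlap_fraction({"void": []}, []).set_index("class")
        assert np.isnan(table.loc["void", "fraction"])


class TestAssociationTest:
    def test_two_by_two_z_statistic_squares_to_hand_chi2(self):
        """Expected counts (7,3)/(7,3) give chi-square 3.8095."""
        res = class_association_test([[5, 5], [9, 1]])
        assert res.method == "two_proportion_z"
        assert res.statistic**2 == pytest.approx(3.8095, abs=2e-3)
        assert res.df == 1

    def test_identical_proportions_give_p_one(self):
        res = class_association_test([[10, 10], [20, 20]])
        assert res.p_value == pytest.approx(1.0)

    def test_three_class_table_uses_chi_square_df_two(self):
        res = class_association_test([[5, 5], [9, 1], [2, 8]])
        assert res.method == "chi_square"
        assert res.df == 2

    def test_low_expected_cells_flagged(self):
        assert class_association_test([[1, 0], [0, 1], [1, 1]]).low_expected
        assert not class_association_test([[20, 20], [30, 10], [5, 35]]).low_expected


class TestMetaprofile:
    def test_uniform_coverage_gives_flat_profile(self):
        copies = [make_copy(start=0, end=1000), make_copy(start=2000, end=2800)]
        cov = {"chr1": np.ones(5000)}
        prof = metaprofile(copies, cov, n_bins=10)
        assert prof == pytest.approx(np.ones(10))

    def test_leading_signal_concentrates_in_leading_bins(self):
        copies = [make_copy(start=i * 2000, end=i * 2000 + 1000) for i in range(4)]
        peaks = [
            GenomicInterval("chr1", c.interval.start, c.interval.start + 100)
            for c in copies
        ]
        prof = metaprofile(copies, peaks, n_bins=10)
        assert prof[0] == pytest.approx(1.0)
        assert prof[2:] == pytest.approx(np.zeros(8))

    def test_minus_strand_copy_is_reversed(self):
        copy = make_copy(start=0, end=1000, strand="-")
        # signal at the genomic *end*, which is the element 5' end on minus
        peaks = [GenomicInterval("chr1", 900, 1000)]
        prof = metaprofile([copy], peaks, n_bins=10)
        assert prof[0] == pytest.approx(1.0)
        assert prof[1:] == pytest.approx(np.zeros(9))

    def test_short_copy_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            prof = metaprofile(
                [make_copy(start=0, end=5)], {"chr1": np.ones(100)}, n_bins=10
            )
        assert np.isnan(prof).all()


class TestExpressionRPM:
    def test_rpm_definition(self):
        counts = pd.DataFrame({"cell1": [10, 90]}, index=["g1", "g2"])
        rpm = expression_rpm(counts, {"cell1": "T"})
        assert rpm.loc["g1", "T"] == pytest.approx(1e5)
        assert rpm.loc["g2", "T"] == pytest.approx(9e5)

    def test_type_mean_is_unweighted(self):
        counts = pd.DataFrame(
            {"c1": [100, 900], "c2": [300, 700]}, index=["g1", "g2"]
        )
        rpm = expression_rpm(counts, {"c1": "T", "c2": "T"})
        assert rpm.loc["g1", "T"] == pytest.approx(2e5)

    def test_per_cell_rpm_sums_to_one_million(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"c{i}" for i in range(6)],
        )
        types = {f"c{i}": f"t{i}" for i in range(6)}  # one cell per type
        rpm = expression_rpm(counts, types)
        assert rpm.sum(axis=0).to_numpy() == pytest.approx(np.full(6, 1e6))

    def test_zero_total_cell_named_in_error(self):
        counts = pd.DataFrame({"dead": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="dead"):
            expression_rpm(counts, {"dead": "T"})


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        vals = list(np.linspace(0, 1, 20))
        res = group_comparison({"a": vals, "b": vals}, style="all_pairs")
        assert res.p_adj.iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_large_shift_detected(self, rng):
        res = group_comparison(
            {"a": rng.normal(0, 1, 50), "b": rng.normal(5, 1, 50)},
            style="all_pairs",
        )
        assert res.p_adj.iloc[0] < 1e-6

    def test_adjusted_p_not_below_pairwise_t(self, rng):
        from scipy import stats

        groups = {k: rng.normal(0, 1, 25) for k in "abcd"}
        res = group_comparison(groups, style="all_pairs")
        for _, row in res.iterrows():
            t_p = stats.ttest_ind(groups[row.group1], groups[row.group2]).pvalue
            assert row.p_adj >= t_p - 1e-9

    def test_dunnett_against_control(self, rng):
        res = group_comparison(
            {
                "control": rng.normal(0, 1, 40),
                "same": rng.normal(0, 1, 40),
                "shifted": rng.normal(3, 1, 40),
            },
            style="vs_control",
        )
        res = res.set_index("group1")
        assert (res.method == "dunnett").all()
        assert res.loc["shifted", "p_adj"] < 1e-4
        assert res.loc["same", "p_adj"] > 0.05

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_comparison({"a": [1.0], "b": [1.0, 2.0]})
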