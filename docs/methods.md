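# Methods

This note records the models, filter constants, numerical choices and
limitations behind `retromethylmap`, in the order the pipeline runs.

## Coordinates and input handling

All modules use 0-based half-open intervals. Readers convert at the
boundary: Bismark coverage rows (1-based) and RepeatMasker `.out` rows
(1-based inclusive, strand `C` for the minus strand) are normalised on
input. Methylation counts are authoritative — the percent column of a
coverage file is ignored and levels are recomputed as
`meth_reads / total_reads`, which avoids rounding drift. CpGs are keyed by
the position of the C on the plus strand; the readers accept either
strand-merged or unmerged input but never merge strands themselves.

## Copy catalog

A repeat instance is *full length* when its genomic span covers at least
`min_fraction` (default 0.9) of its subtype's consensus length; the
boundary is inclusive, and solo LTRs are judged against the LTR consensus.
One inclusive rule (≥) is used for both regular copies and solo LTRs: the
alternative strict reading differs only for copies exactly on the
boundary, and a single rule keeps the filter monotone and easy to reason
about.

*Gene body* means the full transcript span, introns included (BED12
records are read as chromStart–chromEnd), because intronic antisense
insertions are the main case of interest. Any overlap of ≥ 1 bp makes a
copy genic; with several overlapping genes the largest overlap wins and
ties go to the gene with the smaller start, making the result independent
of gene order. Orientation relative to the host gene gives genic-antisense
versus genic-sense; an unstranded copy overlapping a gene is an error
rather than a silent guess.

## Per-copy methylation

Filter constants (the `Thresholds` dataclass):

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 5 reads | per-CpG depth floor |
| `min_cpgs` | 10 sites | passing CpGs needed for a copy to be analyzable |
| `low_max` | 0.20 | class boundary, `level < low_max` is low |
| `high_min` | 0.60 | class boundary, `level >= high_min` is high |
| `full_length_fraction` | 0.9 | consensus-coverage floor |

The per-copy level is the *unweighted* mean of per-site levels — sites
count equally regardless of depth. Classification is a partition:
0.20 maps to medium and 0.60 to high, exactly as the boundaries are
written. Two-donor concordance uses the same boundaries (≥ 0.60 high,
< 0.20 low) in both donors; `high_and_low` is directional (donor 1 high,
donor 2 low), with donor 1 defined by the order of the coverage files in
the run configuration and a `mirrored` switch to also name the opposite
configuration. Per-subtype summaries flag subtypes with fewer than 30
analyzable copies (the reporting floor) instead of dropping them.

VNTR-internal CpGs are included in SVA copy means by default; the
`region` argument of `copy_methylation` restricts the mean to a
sub-interval (e.g. the VNTR span) when wanted.

## Motif scanning

Occurrences of a PWM are scored as log2 odds against a 0-order background,
with a pseudocount (default 1e-4) mixed into both so scores stay finite.
Scores are scaled by 1000 and rounded to integers; the null distribution
of the window score is then computed exactly by dynamic programming on the
integer grid, one motif position at a time, and a window is a hit when its
survival probability is at or below the p threshold. The minus strand is
scanned with the reverse-complement PWM against the complemented
background, whose null distribution equals the forward one — the standard
exact-scan construction. `N` bases contribute zero log-odds. The suite
checks exact agreement with full window-and-word enumeration for widths up
to 8.

Hit thresholds are exact p-values, not q-values: q-values depend on the
universe of scanned windows, while a p threshold keeps hit sets a pure
function of (sequence, PWM, threshold). `bh_qvalues` converts a scan's
p-values by Benjamini–Hochberg when a q-scale cutoff is preferred.
Per-copy motif *counts* resolve overlapping hits greedily left to right
(best score wins at equal offsets) so tandem motifs count once per unit.

VNTR unit number is estimated by greedy consensus tiling: a window equal
to the unit length matching the unit consensus at identity ≥ 0.8 counts as
one unit and advances a full unit, otherwise the cursor moves 1 bp. This
is a deliberate, deterministic definition — unit counting has no canonical
algorithm — and both the identity floor and the unit consensus are
arguments.

## Peak overlap and tests

A copy overlaps a peak set when the peaks intersect it by at least
`min_overlap_bp` (default 1) in total, making the fraction invariant to
splitting a peak into abutting pieces. Class-versus-overlap tables are
tested by a two-proportion z-test for two classes and Pearson chi-square
without continuity correction otherwise (a 2×2 continuity correction is
available but off by default); results carry a `low_expected` flag when
any expected cell is below 1, and a table with a zero margin returns
p = 1 with the flag set rather than failing. Group comparisons use Tukey's
HSD (studentized range) for all pairs and Dunnett's test against the
first-listed group as control; the method used is recorded in the output.

## Mappability

From each start position along a copy a read of `read_length` (default
100 bp) fully contained in the copy is taken; a read is properly mapped
when its exact occurrence count over both strands of the whole genome is
one (a palindromic read counts once per locus, and reads containing `N`
never match). Mappability is unique reads over total reads. Exact search
is stricter than a mismatch-tolerant aligner; a Hamming-distance mode
(`max_mismatches`) exists for sensitivity checks. The k-mer index used in
production is observationally equivalent to comparing each read against
every genome window, and the suite enforces that equivalence against a
double-loop census.

## DMR calling

The candidate stage is plumbing by design and accepts any candidate BED in
its place. Its own caller slides windows of 10 CpGs analyzable (depth ≥ 5)
in both samples, keeps windows with an absolute mean difference ≥ 0.25,
merges overlapping windows, and trims each merged span to the outermost
CpG whose own difference reaches the seed threshold — without trimming,
windows straddling a boundary drag flat flanking sites into the span and
systematically widen candidates.

The normative refinement filter then keeps a candidate iff (a) the union
of CpG positions observed in either sample contains a run of ≥ 10
*successive* sites analyzable in both samples — a site analyzable in only
one sample breaks the run (strictest reading; `successive=False` relaxes
to a total count) — and (b) the means over analyzable CpGs differ by
≥ 0.40, applied at candidate level, not per site. Direction follows the
sign of the difference. Refinement is anti-monotone in both thresholds.
Repeat-family annotation requires ≥ 1 bp intersection; abutting half-open
intervals do not overlap.

## Synthetic data generator

The generator emulates the structure the analysis assumes, at desk scale,
with every artifact a pure function of (config, seed). Independent
substreams (genome/truth, methylomes, peaks, expression) let one stage be
redrawn on a fixed truth — used for the null calibration of the peak test.

Defaults and what they emulate:

- **Genome**: 400 kb of uniform random sequence with 200 embedded copies
  (60 SVA_A, 60 SVA_D, 40 L1PA4, 40 LTR12C), at least 800 bp apart.
  SVA-like copies are head (150 bp) + VNTR (36-bp unit × drawn count) +
  tail (150 bp); other subtypes are plain consensus. Copies carry 5%
  per-base substitution divergence; 10% are truncated to 70–88% of the
  consensus so the full-length filter has something to reject. Random
  sequence yields roughly one CpG per 16 bp, so a typical copy holds
  ~25–40 CpGs — comfortably above the 10-CpG analyzability floor.
- **Latent classes**: each copy draws a two-donor concordance class
  (common-high 0.35, common-low 0.25, high-and-low 0.20, other 0.20) and
  per-donor mean levels from the class windows high U(0.75, 0.95), low
  U(0.02, 0.12), medium U(0.30, 0.50). The donor-1 class doubles as the
  single-sample class for the resistance workflow.
- **Methylomes**: per CpG, depth ~ Poisson(20) and
  meth ~ Binomial(depth, site mean); site mean is the copy's donor level
  inside copies, the island levels (0.9/0.1) inside implanted
  differential islands (five islands of 30 CpGs at 8-bp spacing), and a
  flat 0.75 background elsewhere. There is no within-copy autocorrelation
  beyond these blocks: none of the implemented statistics uses it.
- **Motif/VNTR coupling**: each VNTR unit starts with a fixed 8-bp motif;
  unit counts are drawn per donor-1 class (low 3–5, medium 5–8, high
  8–12), and the truth table records how many motifs survive divergence.
- **Peaks**: one peak per copy with probability
  logistic(−4.0 + 0.9 × motif count), spanning the copy's VNTR. At these
  defaults the expected overlap fraction rises from ≈ 0.15 (low) through
  ≈ 0.45 (medium) to ≈ 0.85 (high), a separation large enough that class
  monotonicity is not a coin flip at n = 200. Null calibration sets the
  logistic to (0, 0), i.e. probability ½ independent of class, keeping
  per-class counts large enough for the chi-square p to be effectively
  continuous.
- **Genes and expression**: context is drawn per concordance class
  (antisense probability 0.60 for common-high down to 0.10 for
  common-low); genic copies get a host gene spanning the copy ± 300 bp on
  the appropriate strand. Host-gene expression is negative binomial
  (dispersion 0.3) around base mean 50 scaled by
  exp(coupling × effect), effect 1.0 / 0.5 / 0.25 / 0 for common-high /
  high-and-low / other / common-low, over 40 cells of one type plus 50
  background genes.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: indel divergence and nested/fragmented repeat
structure, bisulfite conversion error, strand-specific coverage,
CpG-island background structure, linkage between neighbouring copies, and
realistic KRAB-ZFP peak shapes. The generator validates the machinery and
the filter logic, not biological effect sizes.

## Problem sizes and determinism

The default test and acceptance runs use the sizes above (400 kb genome,
200 copies, depth 20; 80 kb genomes for the focused recovery suites;
20–100 random cases per brute-force oracle; 200 redraws for the null
calibration), chosen so the whole suite validates every oracle and
recovery property in well under a minute each while leaving the latent
effects many standard errors away from the decision boundaries. Recovery
checks score a detected DMR as matching an implanted island at reciprocal
overlap ≥ 0.5, and count as false positives only detections touching no
island — a wide detection of a real island is a localisation miss, not a
background call. Property tests are derandomised or fixed-seed;
byte-level determinism is asserted within this implementation only (the
generator's draw order is documented, but exact draws are not portable
across RNG implementations).

## Known limitations

- The exact-match mappability is stricter than a mismatch-tolerant
  aligner; reported mappabilities are lower bounds in that sense.
- The candidate DMR caller is intentionally simple (no HMM, no smoothing);
  its role is to feed the refinement filter, and any external candidate
  set can replace it.
- Dunnett's test takes the first-listed group as control; the caller is
  responsible for group order.
- `estimate_vntr_units` tiles left to right and does not recover units
  interrupted by large indels.
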