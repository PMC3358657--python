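# Methods

## Coordinate and alignment contract

All in-memory coordinates are 0-based half-open. SAM's 1-based POS is
converted on read; BED6 passes through natively. Alignments are reduced
to ungapped blocks of length equal to the query length: profiles are
built on single-exon genes from short reads, so spliced or gapped CIGARs
(anything outside M/=/X) carry no usable signal here and are rejected
with a counter rather than interpreted. A read is a multi-mapper — and
is excluded together with all records sharing its name — when its NH tag
reports more than one hit or when its name occurs at more than one
mapped locus; this enforces the unique-mapper convention on SAM files
from any aligner. Read strand is recorded but coverage counts both
strands equally.

## Coverage profiles and the presence filter

Coverage at gene position *i* is the number of read intervals containing
*i*; minus-strand genes are reversed at construction so index 0 is
always the transcript 5' end, making every downstream 5'–3' statement
orientation-safe. Counts stay raw integers — no per-experiment depth
scaling — because all downstream comparison is through Pearson
correlation, which is invariant to positive scaling.

"Covered by reads" is read in its weakest form: at least one overlapping
read (any nonzero position). A gene is retained when it is covered in at
least `presence_fraction` (default 0.90) of experiments. A stricter
minimum-mean-coverage variant is available (`min_mean_coverage`, default
off) since the original predicate's depth requirement is ambiguous; the
default is the permissive reading so the filter never silently hides
data.

## Similarity, clustering, laboratory contrast

Per gene, the product-moment correlation is computed for every
experiment pair; a constant profile makes the correlation undefined and
the gene is skipped for that pair (never imputed as 0, which would bias
low-complexity pairs toward dissimilarity). Positions carrying NaN
(mappability-masked) are excluded pairwise. The pair's similarity is the
arithmetic mean over genes with defined correlation; an entry with no
defined gene is NaN and must be resolved before clustering.

Distances are `d = 1 − r` by default (`(1−r)/2` available); the
transform is a package choice, exposed in configuration. UPGMA merges
the pair of clusters with minimal average inter-cluster distance, at
ultrametric height = half that distance, with the size-weighted linkage
update; ties break toward the lowest pair of cluster indices in creation
order, making output deterministic. Tests check the implementation
against both a recompute-all-cross-pairs oracle and SciPy's average
linkage.

The within- vs between-laboratory contrast uses the Wilcoxon rank-sum
test with midrank ties. When `|within| · |between| ≤ 10 000` the p-value
is exact: a subset-sum dynamic program over doubled midranks counts the
same C(n+m, n) equally likely label assignments as literal enumeration
(verified against literal enumeration in tests) without materialising
them. Above the threshold, the normal approximation with tie and
continuity correction (SciPy) is used. The default alternative is
one-sided ("greater"), matching the directional question of whether
same-laboratory profiles are more similar.

## 5'–3' linear bias

An experiment's relative profile scales each gene's profile to mean 1
(equal gene weights regardless of expression), maps positions to
`(i + 0.5)/length`, and averages within `n_bins` (default 100) half-open
bins, last bin closed; empty bins are flagged and excluded from fitting.
Positions within one read length of a gene's ends are covered by fewer
than L read placements, so their expected coverage is attenuated by
interval geometry, not by sampling bias; the aggregation therefore trims
`read_length − 1` positions from each end by default (capped so at least
two positions survive per gene). Without this trim the edge taper leaks
into the fitted slope and leaves a systematic residual after correction.

The bias model is the OLS line through the non-empty bins. Correction
divides each profile value by `max(a + b·x_i, 0.01·a)` — division, not
subtraction, because coverage is multiplicative in sampling rate, and
the 1%-of-intercept floor prevents sign flips when the line crosses zero
inside the gene. A non-positive intercept is rejected as a degenerate
fit. Normalized sets are new objects; originals are never overwritten.

## Mappability

For read length L and mismatch allowance k (1 for L < 26, 2 for
26 ≤ L ≤ 50, 3 for L > 50, overridable), the L-mer at each genomic start
is aligned against both strands of the whole genome; it is unique iff it
has exactly one alignment location (its own origin). Uniqueness counts
strand-specific placements, so a reverse-palindromic L-mer is its own
second hit. L-mers containing N are never unique and windows containing
N never match — the conservative choice.

The k-mismatch search is exact: pigeonhole seed partitioning (k+1
contiguous slices; any ≤ k-mismatch match must match one slice exactly)
generates candidates from exact-match hash lookups, verified by Hamming
distance, with an early exit at two hits. k = 0 uses plain L-mer hash
counting. This is intended for desk-scale genomes (up to ~10⁶ nt); no
external aligner is involved, so "the same parameters as the reads" is
reproducible by construction.

Per-position mappability `m_i` is the fraction of the valid read starts
covering *i* that are unique — coverage at a position aggregates up to L
placements, so the placement fraction, not the start indicator, is what
coverage loses when placements go ambiguous. Normalization divides by
`m_i` and masks (NaN, excluded downstream) positions with `m_i = 0`;
zero-filling would fabricate anti-correlation.

## Synthetic studies

The generator emulates a multi-laboratory study with known ground truth.
A laboratory's signature is a read-start density over relative gene
position `x ∈ [0, 1]`:

    b(x) = max(1e-3, 1 + slope·(x − 0.5) + Σ amp·exp(−(x − c)² / 2w²))

renormalized to sum 1 over the valid starts of each gene; the floor
keeps every position reachable so no gene can drop to zero coverage and
trip the presence filter nondeterministically. Start positions are
evaluated at gene-relative coordinates `(j + 0.5)/length`, which keeps a
linear density slope exactly recoverable from interior coverage (the
read window only shifts the coordinate by a constant). Bias acts on the
read 5' end in transcript orientation, so minus-strand genes exercise
the profile-reversal path.

Genomes are i.i.d. uniform A/C/G/T, one chromosome, genes non-overlapping
with intergenic gaps of at least one read length and alternating
strands; an optional duplicated intergenic segment creates a known
mappability-zero region. Expression vectors are log-normal (σ = 1 by
default), redrawn per experiment ("different tissues") or optionally
shared within a lab. Reads are error-free genome copies written as
mapped SAM with NH:i:1; sequencing error, PCR duplicates, paired ends
and quality strings are deliberately out of scope — the object of study
is positional bias. Consequently, passing tests demonstrate recovery of
*positional* laboratory signatures under clean mapping; they do not
speak to GC, primer-hexamer or degradation biases of real libraries.

Every random draw flows from named integer seeds (master seed +
experiment seed through NumPy's SeedSequence); identical configurations
give byte-identical files. `simulate_experiment` (SAM) and
`simulate_profiles` (direct coverage via convolution of start counts
with a length-L window) consume the same RNG stream and are asserted
equal in tests; the direct path exists because large simulation studies
would otherwise spend their time writing and re-parsing SAM.

Default study conditions for the recovery analyses: 3 laboratories × 3
experiments, 20 genes of 500–1000 nt, 100 000 reads of 50 nt per
experiment, linear trends {+0.8, 0, −0.8}, lab-specific bumps of
amplitude 0.5 and width 0.05 centered at 0.25/0.50/0.75. These sizes
make every per-gene profile deep enough (mean coverage ≈ 300×) that
profile similarity reflects the injected densities rather than Poisson
noise, while keeping any analysis run in seconds. The acceptance script
uses a smaller SAM-backed study (8 genes, 5000 reads) for the
end-to-end determinism check, where file I/O rather than statistics is
under test.

## Pipeline orchestration

Stages run in the order coverage → filter → [bias] → [mappability] →
correlate → cluster/compare; the normalization passes are optional and
re-enter before correlation. Each stage persists its product
(`profiles.tsv`, `genes_retained.txt`, `similarity.tsv`, …) so stages
can be run across invocations; requesting a stage whose prerequisite
artifact is absent fails naming the stage to run first. Every output
carries the configuration hash in a header comment, outputs contain no
timestamps, and reruns with unchanged inputs are byte-identical.
`--threads` is accepted as a scheduling hint and never affects results.

## Known limitations

- The k-mismatch mappability search is exact but quadratic-ish in
  genome size through its candidate verification; it is not meant for
  mammalian-scale genomes.
- The exact rank-sum DP is conditional on observed midranks, as exact
  tie-handling requires; with heavy ties its null distribution is
  discrete and p-values are conservative at the attainable levels.
- Whether 5'–3' and mappability normalization remove laboratory
  clustering depends entirely on the injected non-linear signatures; the
  package treats the normalized re-clustering as a scenario to run, not
  a property to assert.
- Paired-end fragment modelling, spliced alignment, color-space reads
  and real-data batch inference are out of scope.
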