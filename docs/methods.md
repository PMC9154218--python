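# Methods

## Score scale and classification

All importers normalize to the natural-log probability ratio
`score = ln(p / (1 − p))`, the common axis used by nanopore modification
callers.  Probabilities are clamped to `[1e-6, 1 − 1e-6]` before the log so
stored scores are always finite (raw scores of ±13.8 therefore bound the
scale).  SAM ML bytes decode to the midpoint of the interval they encode,
`p = (b + 0.5)/256`, so byte 255 maps to +6.24 rather than +∞.  Megalodon
rows carry log-probabilities for the modified and canonical states; their
difference is the score directly.  Guppy-style and custom tables may carry
either probabilities or ready-made log ratios, selected per column spec.

Classification is a total function of the score: `score ≥ hi → MOD`,
`score ≤ lo → UNMOD`, strictly between → AMBIG.  The defaults (−2, +2)
follow the widely used nanopolish convention of requiring roughly 7.4:1
odds before calling either way; both are adjustable per sample, and
adjusting cutoffs rewrites the stored classification in place so that
MOD + UNMOD + AMBIG always equals the stored call count.  AMBIG calls are
excluded from every methylation fraction (numerator and denominator) but
reported alongside; they are drawn as small grey dots in the locus raw
panel so discarded evidence stays visible.

## Storage

Calls live in a single SQLite table keyed by (sample, read, chrom,
position, modification code) with an index on (sample, chrom, position)
for region queries.  Re-importing the same call replaces the previous row
(last import wins).  The store can be in-memory or a file; file-backed
stores are what the CLI's `--db` option passes around.

## BAM import

MM/ML skip-count decoding is delegated to pysam's `modified_bases`
accessor (positions verified to be reported in stored-SEQ orientation);
lifting the resulting read positions to reference coordinates goes through
`get_aligned_pairs`, so calls landing in insertions or soft clips are
dropped — an unaligned base has no reference coordinate, and inventing one
would misplace the call.  Reads whose MM/ML tags are malformed or
length-mismatched are skipped with a warning and counted in the import
report.  `?`-flagged and unflagged MM sub-tags are treated identically:
skipped canonical bases produce no call rather than an implicit
unmodified call, which would fabricate scores the caller never emitted.
The independent check of all of this is a brute-force per-base decoder in
the test suite and acceptance script that re-derives reference positions
by walking read and CIGAR by hand.

### Strand collapsing

CpG is symmetric: the cytosines of the two strands form one biological
site.  Minus-strand CpG calls are therefore assigned to the plus-strand C
(position − 1) so both strands aggregate together.  Asymmetric contexts
(e.g. the two adenines of GATC in 6mA footprinting) are distinct bases and
keep their strands separate; collapsing is enabled only when the motif is
CG and the modified base is C.

### Nanopolish groups

Nanopolish emits one row per group of nearby CpGs with a single
log-likelihood ratio.  A row covering k motifs is expanded to k calls
sharing the row's score (matching nanopolish's own split-groups
convention).  Group member positions are recovered by scanning the row's
sequence context for the motif window whose span matches the row's
start/end, which stays correct when the context flanks contain extra
motif occurrences that are not group members.  Nanopolish coordinates are
treated as 0-based, the convention its methylation TSVs actually use;
everything internal is 0-based half-open, with 1-based coordinates only
in the DSS output where that format requires them.

## Aggregation

Fractions are per-call, not per-read averages, matching bedMethyl
semantics; a call belongs to a segment iff `start ≤ pos < end`.  Segments
on chromosomes absent from the store yield zero rows with a warning
rather than an error, so one malformed BED line cannot kill a long run.
There is no default minimum-coverage filter; `min_coverage` (CLI
`--mincov`) masks fractions below a chosen classified-call count.

Binned profiles tile a chromosome or region with fixed-size bins (last
partial bin kept and flagged), count motif occurrences per bin from the
reference, and mask bins with zero motif sites — a bin with no CpG can
have no CpG methylation level, and plotting it as 0 would read as
unmethylated.  Both a per-call fraction and the motif-site count are
reported, so callers can normalize either way; plots show the fraction.

bedMethyl output is BED9+2 (name = modification code, score = coverage
capped at 1000, percent = integer-rounded 100·fraction); sites with zero
classified calls are omitted.  DSS output is the per-sample
`chr pos N X` table with 1-based positions.

## Locus and region profiles

Locus data lives in motif space: ranks 0..n−1 over the ordered motif
occurrences in the window, removing CpG-density variation from the x
axis.  Per-read call states distinguish NOCALL (the read covers the site
but the caller emitted nothing) from AMBIG (a call was made and discarded
by the cutoff band).  Smoothing pools classified calls in a centered
boxcar window over motif ranks — default 21 sites, odd widths only so the
window is symmetric — truncated at the edges; windows containing no
classified call yield no point.  Pooling calls (rather than averaging
per-site fractions) weights each site by its coverage, which is more
stable at low depth; the per-site alternative is one line of user code on
the returned counts.  Smoothing over ranks was chosen over
genomic-distance kernels because the plots are drawn in motif space.

Windows above ~1 Mb trigger a warning pointing at the binned region path,
which delegates to the whole-genome binner restricted to the region and
smooths over unmasked bins.  Read stacking in the read panel is greedy
first-fit by start coordinate (purely aesthetic).  Read extents shown are
the span of each read's stored calls, since the call store does not
retain full alignment intervals.

Phase splitting consumes HP/PS tags as written by WhatsHap or similar;
reads without HP form an explicit "unphased" group so the groups always
partition the reads.  methkit never computes phasing itself.

## Repeat composites

Each element instance is globally aligned to the family consensus with
affine gaps: match +2, mismatch −3, a gap of length L costs 5 + 2L.  End
gaps on the element side are free, so 5′/3′-truncated copies align to the
corresponding consensus stretch without penalty, while the consensus
itself is treated globally.  The alignment is Biopython's
`PairwiseAligner`; an independent Gotoh dynamic program in the tests
verifies both the optimal score and that the reported column mapping
attains it (co-optimal alignments make mapping-identity between two
implementations ill-posed, so the mapping is validated by re-scoring).
Elements under 60% alignment identity are excluded as likely misassigned
family members.

Calls are lifted through the match/mismatch columns only; a copy whose
alignment deletes a consensus position contributes nothing there.  Minus
strand elements are reverse-complemented before alignment, which also
reflects their coordinates into consensus orientation; for CpG the lifted
position of a minus-strand collapsed call lands on the consensus G and is
snapped to the consensus C so both orientations pool at one site.  Calls
whose consensus column is not a motif site on the consensus (mutated
copies can gain or shift CpGs) are still pooled but flagged `on_motif =
False` and excluded from the plotted profile.  Individual tracks retain
the `max_elements` copies with the most classified calls, ties broken by
coordinate.  When one read spans two tandem copies its calls are assigned
by element interval, so each call is counted once for the element it falls
in.

## Score distributions

The score KDE uses a Scott's-rule Gaussian kernel on a 512-point grid
spanning the data range extended by four bandwidths; four (not the more
common three) keeps the trapezoidal integral within 1e-3 of 1 even when
the data collapse to a near-degenerate spike at the range edge.

## The simulator

The generator emulates the inputs of a small nanopore methylation
experiment: a uniform-random reference at configurable GC content,
optional planted repeat copies (substituted at 2% by default, optionally
5′-truncated and/or minus-strand), per-site true modification
probabilities defined by intervals with optional per-haplotype overrides,
and reads whose states are independent Bernoulli draws from the true
probability.  Scores are drawn from `N(+4, 1.5)` for modified and
`N(−4, 1.5)` for unmodified states — means and spread chosen to reproduce
the strongly bimodal per-read score distributions real callers produce,
with ~9% of draws falling in the ±2 ambiguous band — and encoded to ML
bytes through the logistic, so decoding recovers each score to within
byte quantization.  Default sequencing parameters (read length
1,000 ± 200 bp, depth 15×, half the reads on the reverse strand) are
ordinary long-read values at pilot scale.

Reads are written pre-aligned with perfect-match CIGARs by default; an
indel mode inserts/deletes bases on forward reads to exercise CIGAR
lifting.  Records are coordinate-sorted in memory before writing, so the
BAM contains no run-specific program lines and is byte-identical under a
fixed seed.

What the simulator does *not* model bounds what green tests mean for real
data: there are no basecalling errors or mismatches, no reference bias,
no correlated methylation along a molecule or between neighbouring CpGs,
no coverage biases, and the score model is exactly the two-Gaussian
mixture the classifier assumes.  Passing tests therefore demonstrate that
the bookkeeping — decoding, lifting, classification, aggregation,
phasing, alignment — is exact, and that estimates are statistically
consistent when the caller's error model holds; they say nothing about
caller accuracy on real signal.

## Verification problem sizes

The acceptance script runs the MM-decoding oracle on 1,000 random reads
(≤50 bp, ≤8 modified sites, random M/I/D/S CIGARs, both orientations),
parameter recovery on 200 replicates of a 3,600 bp genome at 8× with
three truth levels (0.2 / 0.5 / 0.8), a 6,000 bp phased dataset at 14×
(hap1 0.9 / hap2 0.1), and the alignment oracle on 500 random pairs of
5–30 bp sequences — sizes at which every binomial bound in the suite is
already tight while the whole script completes in well under a minute per
section.

## Known limitations

- The store keeps one call per (sample, read, chrom, position,
  modification); duplex or multi-strand callers that emit two calls per
  molecule position collapse to the last imported.
- Motif scanning is reference-based; calls at sites absent from the
  reference (e.g. sample-specific CpGs) never enter motif space, though
  they still count in segment and bin aggregates.
- The guppy tabular dialect is a fixed default column mapping
  (read_id, chrom, strand, pos, prob_mod with a header); real guppy
  deployments vary, so the mapping is overridable via the same column
  spec as the custom dialect.
- Composite pooling assumes the consensus is a reasonable average of the
  family; highly diverged subfamilies should be split before pooling.
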