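# Methods

## The biological problem

Large low-copy plasmids of cyanobacteria replicate through dedicated Rep
proteins; when the initiator is deleted, the plasmid can survive by
recombining into another replicon through homologous sequences (transposase
or integrase genes duplicated across replicons), forming a cointegrate that
carries the entire plasmid. Long-insert mate-pair sequencing detects this:
after mapping, read pairs that straddle the junction have one mate on the
plasmid and one on the acceptor replicon. Separately, the copy number of
the plasmid is controlled by an overlapping mRNA/antisense-RNA pair cleaved
by RNase E, analogous to ColE1's RNA I/RNA II; mapping those cleavage sites
requires exact strand-aware coordinate arithmetic. This package implements
both computational strands and a synthetic-data generator that makes them
testable end to end.

## Synthetic genomes and mate-pair libraries (`replikit.synth`)

A genome is a set of named circular replicons (exactly one chromosome) with
per-replicon copy numbers, plus repeat families whose placements carry
byte-identical sequence (reverse-complemented for `-` placements). Default
simulation conditions mirror the study system scaled down: a 100 kb
chromosome, a 30 kb anchor plasmid and a 15 kb second plasmid at copy
number 2, sharing one 1.5 kb repeat family (the size class of the
transposase genes through which real cointegrates formed). The generator is
uniform in base composition; it does not model GC skew, coverage bias or
real gene content, so passing tests demonstrate the correctness of the
*procedures*, not robustness to every real-library artifact.

Cointegrate formation is a single crossover: the acceptor is opened inside
its repeat copy at a chosen offset, the donor is rotated so its repeat copy
aligns and inserted whole, and the donor disappears as a free replicon.
Total base content is conserved and the two junctions are each flanked by a
full repeat copy; the crossover position within the repeat is
unidentifiable in principle, which is why downstream calls report
intervals. Double-crossover replacement (which would not retain the whole
donor) is deliberately not modelled.

Libraries follow the mate-pair protocol: fragment replicon chosen with
probability proportional to copy number x length, insert uniform on
[2,000, 10,000] nt, fragments may span the circular origin, one 150 nt read
per fragment end (mate 1 reads the fragment 5'->3', mate 2 the opposite
end), and a configurable fraction of reads (default 0.1) runs through the
circularisation point: a genuine prefix, then the junction adapter (a fixed
19-mer, configurable), then sequence from the opposite fragment end.
Substitution errors are applied at a default rate of 0.5% (a realistic
short-read figure and the rate used in the acceptance simulations); indels,
PCR duplicates and chimeric inter-fragment artifacts are out of scope. The
quality model is two-state — Q38 bases with a geometric low-quality (Q12)
3' tail of mean 3 nt — just enough structure to exercise the quality
trimmer. Truth tables record each mate's source replicon, 1-based leftmost
forward-strand coordinate, strand and adapter status.

## Read processing (`replikit.qc`)

Order of operations: adapter split -> quality trim -> terminal clip ->
length filter. Adapter chimeras must be removed before coordinate-based
clipping, hence adapter first; the retained segment is the longest
adapter-free piece (ties -> leftmost). Quality trimming is Mott trimming:
with cutoff Q=30 the error-probability limit is 1e-3 and the retained
interval maximises the summed (limit - p_err); ties prefer the longer, then
the more 5' interval. "Phred > 30" is interpreted as this error-probability
criterion, not hard truncation at the first base below Q30. The fixed
5 nt terminal clip runs exactly once per read set (a processed flag on the
batch prevents double clipping), after which trimming is idempotent. Reads
shorter than 20 nt are flagged discarded, never silently dropped; if one
mate dies the pair leaves the pairing analysis but the survivor still
counts for depth. Subsampling (default 4,000,000 *reads*, configurable) is
uniform without replacement and seeded.

## Mapping (`replikit.mapping`)

Seed-and-extend: exact 15-mers at stride 7 over both read orientations
against a forward-strand index of the concatenated reference (circular
replicons indexed across the origin; placements reported modulo length,
1-based, leftmost aligned base). Candidate diagonals receive a banded
(±12) local Smith–Waterman extension scored +1/−2/−3 (linear gaps). A
placement must satisfy length fraction (aligned read bases / read length)
≥ 0.8 and similarity fraction (matches / aligned columns, gaps counted)
≥ 0.9; all placements tying the best score are returned, because junction
evidence lives inside repeats and the ambiguity must stay visible — the
random multiread placement that commercial mappers default to is
intentionally not reproduced. Identity is defined as matches over aligned
columns and length fraction over the (trimmed) read length; other mappers
using these thresholds may define them slightly differently, so they are
documented approximations. Tests hold
the mapper to an exhaustive local-alignment oracle: whenever it places a
read its best score equals the Smith–Waterman optimum, and seed misses at
1% substitution error stay below 1%.

## Fusion detection (`replikit.fusion`)

The literal reciprocal procedure: A = pairs with a mate on the anchor; B =
subset with the other mate on another replicon; B' = the same with
references switched; C = B ∩ B' keyed on pair identity. A mate "maps to" a
replicon only if its *unique* best placement is there (default): with
shared repeats, tied placements would fabricate cross-replicon pairs in a
wild type. The permissive any-placement mode is retained for comparison.
Calls come from single-linkage clustering of (anchor position, target
position) with linkage distance equal to the maximum insert on both axes;
clusters below 5 supporting pairs are dropped (long-insert libraries give
dense junction coverage, so singletons are library artifacts). Intervals
span the innermost evidence plus one read length and are widened to any
overlapping annotated repeat (flagged `within_repeat`). Mate orientation
is not used as evidence; the procedure is purely replicon-identity based.

## Copy number and blot quantification (`replikit.depth`)

Depth = summed per-read weight / replicon length; ratio to the chromosome
estimates copies per chromosome copy. Reads (not pairs) are counted;
multireads default to fractional weight (1/n placements) because shared
repeats would otherwise inflate plasmid depth; `unique` weighting is
available. Strain comparison is the ratio of ratios. Blot quantification
divides mean plasmid-probe signal by mean chromosome-probe signal per
group and applies a classical pooled-variance unpaired two-tailed t-test on
per-replicate ratios (Welch behind a flag); with <2 replicates the ratio is
reported and the test refused, and zero-variance degenerate inputs yield
p=0 or p=1 with a warning.

## Locus arithmetic (`replikit.locus`)

A substrate is a strand, a templated genomic span (5'-most and 3'-most
coordinates) and a count of non-templated 5' residues. Length =
span + extra5. A cleavage site's coordinate is the 5' nucleotide of the
downstream product; extra5 counts toward the 5'-most fragment; fragment
lengths always sum to the substrate length, and reverse-strand problems
mirror coordinate-flipped forward-strand ones (both are property-tested).
PSS classification uses only the sign of the (log) fold change and the
adjusted p at alpha = 0.05 (the printed table's "0.00" entries are stored
as printed; comparisons use <= alpha, so printing precision cannot flip a
call). In the enzyme-variant comparison (native vs 5'-sensing-deficient
RNase E) significance in *either* direction marks a site whose processing
depends on 5' sensing — sites enriched with the native enzyme are its
direct cleavages, sites enriched in the deficient strain accumulate because
their downstream processing required 5' sensing; both are reported under
one category with the direction recoverable from the fold-change sign.
The digest operation cuts at every exact recognition-site occurrence
(HindIII semantics by default, cut offset 1), supports circular molecules,
and is cross-checked against an independent restriction library in tests;
amplicon location is exact primer matching with T7-leader stripping.

## Pipeline (`replikit.pipeline`)

One config (dict/YAML/JSON) with per-stage blocks; per-stage seeds derive
from the master seed via `numpy.random.SeedSequence(seed).spawn` in a fixed
order (genome, library), so identical config + seed gives byte-identical
summaries. Reads are always mapped to the *wild-type* reference (that is
the point of the assay: the mutant's reads betray the rearrangement against
the unrearranged reference). Any stage failure aborts with the stage name.

## Problem sizes and numerical choices

The simulation-based tests run at 50,000 pairs per library (twenty seeded
cointegrate libraries and twenty matched wild-type libraries) and 100,000
pairs for copy-number recovery — sizes chosen so the binomial sampling
error on depth ratios sits well inside the ±15% acceptance band and
junction coverage is dense (about 1,900 straddling pairs per junction).
Floating-point ties in Mott trimming use a 1e-12 tolerance. Alignment
scores are integers; identity and length fractions are exact rational
comparisons in floating point at read-length denominators, far from any
representable-precision hazard.

## Known limitations

* The mapper is exact-seed based; reads whose every sampled 15-mer is hit
  by an error go unmapped (measured < 1% at 1% substitution error). Indel
  handling is banded at ±12.
* The simulator omits GC bias, indels, duplicates and real mate-pair
  chemistry quirks; sensitivity numbers on real libraries will differ.
* Junction calls are intervals, not breakpoints — a crossover inside an
  identical repeat is unidentifiable within it, and the reported interval
  deliberately covers the repeat.
* The sense-transcript in vitro substrate of the original locus cannot be
  reconstructed from printed coordinates alone (its stated length is not
  derivable from the stated TSS and boundary positions), so no operation
  asserts it; the antisense substrate arithmetic is exact.
* Orphan-read handling assumes index-aligned mate files; name-based pairing
  of arbitrary FASTQs warns on and excludes orphans.
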