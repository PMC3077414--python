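# Methods

This note documents the models, defaults and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Sequence handling and coordinates

Genomes and fragments are plain `{A,C,G,T,N}` sequences; IUPAC
ambiguity codes are legal only in pattern files, so scanning semantics
stay unambiguous. All internal coordinates are 0-based half-open (BED
convention); GFF3 is converted on read, and human-readable reports
print 1-based positions and rounded kb distances.

## Consensus expansion and genome scanning

A degenerate pattern over the 15 standard IUPAC codes is expanded by
Cartesian product of each code's base set; several same-length patterns
union into one set of K distinct L-mers. The scan reports **every**
occurrence of every member: overlapping occurrences all count, a
position matching several variants counts once per (position, strand),
and windows containing N never match. Forward-only scanning is the
default; `strands="both"` additionally reports positions whose reverse
complement is a member, once each with strand `-`. Which convention a
published genome-wide count used is generally ambiguous, so both modes
are exposed.

The implementation packs each window into a 2-bit rolling integer code
and tests membership against the sorted pattern-code array; the
contract, enforced by property tests, is exact equivalence with a naive
sliding-window search. The 4,096-member binding-site set referenced in
the spacing arithmetic is user-supplied input — its derivation from
SELEX data is not re-derived here.

Expected spacing `4^L / K` assumes uniform i.i.d. bases. Observed
spacing is `G/n` with G the total scanned length; it is undefined (an
error, not infinity) for n = 0. Overrepresentation is
expected/observed spacing.

## AT composition and the rank-sum comparison

AT-content is `100·(A+T)/(A+C+G+T)` with N excluded from numerator and
denominator. The genome background tiles each record left-to-right into
non-overlapping windows (default 500 bp — large enough to smooth local
fluctuation, small enough to resolve isochore-scale variation);
trailing remainders are discarded so all windows are identically sized,
and windows with less than 50% unambiguous bases are excluded and
counted. The exclusion threshold is this package's choice; assembly
N-gap handling has no universal convention.

The two-sample comparison uses the Wilcoxon rank-sum / Mann–Whitney
test: W is the Mann–Whitney statistic of sample 1 (pairs with x > y,
ties ½), with the classic rank sum `W + n1(n1+1)/2` carried alongside.
The exact distribution is used when both samples have at most 25
observations and the pooled sample is tie-free; otherwise the normal
approximation with midranks, tie variance correction and a 0.5
continuity correction (delegated to `scipy.stats.mannwhitneyu`; an
independent enumeration oracle backs the tests). The headline
fragment-vs-genome test is one-sided "greater" because the scientific
hypothesis is AT enrichment; the two-sided p is always emitted
alongside. Shared 2-percentage-point histogram bins support plotting
the two distributions on a common axis.

## Short matching and segment collection

The cross-fragment aligner is an ungapped seed-and-extend search in the
style of blastn tuned for short sequences: exact shared 7-mers seed
extensions scored +1/−3, each direction stopping when the running score
falls 10 below its running maximum (X-drop) and trimming back to the
maximum. Every extended seed is reported — the permissive limit of an
essentially unfiltered search (very high E-value cutoff, complexity
filter off); Karlin–Altschul E-value statistics are deliberately not
implemented, as downstream use is exhaustive segment collection, not
significance ranking. Distinct seeds trimming to identical coordinates
merge; self-pairs are excluded; both subject strands are searched, with
reverse-strand coordinates convertible back to plus-strand positions.

Segment collection keeps alignments whose length equals the requested
size exactly (11 or 12 bp), extracts the query-side string (always plus
orientation), and removes exact duplicates — the operational stand-in
for manual redundancy curation; near-duplicate collapsing is not
attempted. Order is lexicographic for determinism.

## Sequence logo

Column information content is `ic = 2 + Σ_b f_b log₂ f_b` bits
(0·log 0 = 0), letter heights `f_b · ic`, uniform background. The
small-sample correction `e(n) = 3/(2·ln2·n)` can be subtracted
(floored at 0) but defaults off: identical segment sets then always
yield identical logos regardless of n, and no pseudocounts are ever
added. Plotting is a small stacked-bar matplotlib renderer; the TSV
matrix is the primary output.

## qPCR enrichment

Fold enrichment is `2^(Ct_NoAb − Ct_IP)` per sample, assuming perfect
doubling per cycle (no efficiency correction). The mean is taken over
fold values, not ΔCt values — the convention that reproduces the
published 246-fold average of the bundled Ct table. Reports round folds
to two decimals.

## Locus classification

A locus is **intragenic** if it overlaps any gene span; the reported
feature is the exon or intron with the largest overlap, ties broken
toward the exon (a unique feature per fragment, and exonic evidence is
the rarer call). Exon/intron numbering is strand-aware: intron 1 is the
first intron in transcript orientation. Overlapping multiple genes, the
largest overlap wins, then the lexicographically smaller gene id.
Otherwise the locus is **intergenic**, annotated with the nearest gene
on its chromosome by edge-to-edge distance and a strand-aware
upstream/downstream relation; distances are stored exactly and rounded
only in human-readable reports. A locus on a contig carrying no gene
models (or explicitly flagged) is **unplaced**. These three categories
partition any input.

## Synthetic data

The generator emulates the modelled experiment's scale: ~49 fragments
of 105–1848 bp over a background whose 500-bp-window AT fractions come
from a two-component Gaussian mixture (0.7 weight at mean 0.56, sd
0.05; 0.3 at 0.64, sd 0.07, clamped to [0.05, 0.95]). A mixture is used
because genomic AT distributions are right-shifted and skewed rather
than normal; these component values are package defaults chosen to give
a marginal mean near the 59% genomic average, not measured quantities.
Within a window bases are i.i.d. at the drawn composition.

Fragment starts are sampled with weight `exp(β · fragment AT)`, with β
calibrated per fragment length from the realized variance of candidate
fragment AT so the expected selected-fragment AT sits the configured
shift (default +0.06 AT fraction) above the genome mean — an
exponential tilt, the smooth monotone weighting that realizes an
additive shift directly. Motif planting draws Poisson(density × Mbp)
non-overlapping positions and overwrites each with a uniformly chosen
variant, returning ground truth; overlap-free planting keeps recovery
unambiguous. Gene models are placed non-overlapping by allocating the
free space between randomly structured genes. qPCR ΔCt values are
Normal(7.64, 1.13) over a fixed IP baseline of 30 cycles — the moments
of the bundled Ct table.

All generators draw from independent streams keyed on (seed, stream
id) and are bit-reproducible. What the generator does **not** emulate:
chromatin structure, nucleosome positioning, mappability, repeat
content, sequencing or cloning error, and correlated composition along
chromosomes (windows are independent draws). Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
composition model, not performance on real genomes.

## Problem sizes and verification

Property tests run the scan-vs-naive-oracle equivalence over 100 seeded
random genomes of 2–20 kb with random 4–8-mer pattern sets on both
strand modes; rank-sum null calibration uses 1000 simulated pairs
(n₁ = 20, n₂ = 50) against a 99% binomial envelope at α = 0.05; exact
vs normal rank-sum agreement is checked within 0.02 absolute for
tie-free samples of 8–25; the aligner is compared to an exhaustive
diagonal-segment oracle on 60-bp fragment pairs; planted-motif recovery
and the spurious-match rate run on a 5-Mbp genome — composition-neutral
(AT 0.5) for the spurious-rate check, since the `4^L/K` expectation
assumes uniform bases. AT-shift detection power is measured over 100
replicates of 49 fragments against a 100-kb background at the default
+0.06 shift. The acceptance script uses 20 such replicates and a 1-Mbp
planted genome.

## Known limitations

* Genome-build-dependent published quantities (exact genome-wide match
  counts, the genome-scale rank-sum W and p, the curated 134-segment
  logo) require the original assembly and annotation and are out of
  scope; the bundled printed tables carry the desk-reproducible values.
* Exact-set matching only — no position-weight-matrix scoring or
  mismatch-tolerant matching.
* The aligner is ungapped by design; gapped similarity between
  fragments is invisible to it.
* `expected_spacing` is a uniform-composition null; on AT-biased
  genomes AT-rich pattern sets will exceed it for compositional reasons
  alone, which is part of why observed overrepresentation ratios need
  cautious interpretation.
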