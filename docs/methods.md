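# Methods

## The detection model

A targeted fusion hypothesis is a pair of disjoint gene intervals
(gene A, gene B). Evidence is counted per read pair, each query name at
most once, after three filters: both mates mapped with primary
alignments (secondary and supplementary records are never pair members;
the content of a chimeric read's supplementary alignment reaches the
caller only through the `SA:Z` tag of its primary), neither mate
flagged as a PCR/optical duplicate (duplicate marking is expected
upstream; the caller performs no duplicate detection of its own), and
both mates at MAPQ ≥ 20. Classification is a partition:

- **split**: some read's primary alignment overlaps one gene and
  carries an SA entry whose alignment interval overlaps the other gene,
  and the mate maps to that other gene (*strict* mode) or to either
  gene (*lenient* mode). A pair meeting the split condition is never
  also counted discordant. If both mates qualify, the pair is counted
  once (read 1 preferred) and logged as ambiguous.
- **discordant**: the mates' primaries overlap the two different genes
  and neither read carries a qualifying SA entry.
- **none**: everything else.

"Overlaps" always means an aligned reference base inside the interval;
clipped bases never establish overlap. The total fusion read pair count
is split + discordant, and a sample is *detected* when the total
reaches a threshold (default 1, because fusion-negative controls show
zero counts inside a target region).

Strict mode is the default because the definition of a split read pair
places the mate in the partner gene. Lenient mode exists because a
short insert can leave the mate on the near side of the junction; on
simulated data with 300 bp inserts and 150 bp reads roughly half of the
junction-crossing pairs have near-side mates, so the two modes are
reported separately rather than merged.

SA entries qualify only if they reach the same MAPQ threshold as the
mates (symmetric filtering — the conservative choice) and only if the
primary alignment is actually clipped (a split alignment implies a
clip). When several SA entries reach the partner gene, the one with
highest SA MAPQ wins, ties broken by lower NM, then leftmost position.

## Breakpoint localization

For each of the two alignments of a split read — the primary CIGAR and
the selected SA entry's CIGAR — the junction coordinate is the boundary
aligned base on the clipped side: if the leading clip (soft and hard
clips combined) is ≥ the trailing clip, the boundary is `POS`;
otherwise it is `POS + ref_span − 1`, where ref_span sums the
reference-consuming CIGAR operations (M, D, N, =, X). Because both
CIGARs are already expressed in their own reference orientation, the
rule needs no extra strand handling: for an opposite-orientation fusion
the minus-strand segment's CIGAR is reversed accordingly and the rule
still lands on the junction base. Clip-side ties default to the leading
side. Unique (pos A, pos B) pairs are deduplicated at exact coordinates
(a window option was considered and left out: the oracle tests require
zero-base error, and real WGBS data in this design concentrates support
on exact coordinates); the modal breakpoint is the pair with the most
supporting reads.

## The synthetic data generator

The generator emulates the dilution-series validation design: two
random contigs (default 50 kb, GC 0.45) with one gene interval each
(the central 60 % of the contig), a fusion allele joining gene A at a
chosen coordinate to gene B (same-strand concatenation, or
reverse-complement joining for opposite orientation), and paired-end
fragments drawn from the fusion allele with probability `fraction` and
from the wildtype genome otherwise.

Default conditions (all configurable):

| parameter | default | rationale |
|---|---|---|
| depth | 63× | sequencing depth used for the dilution series |
| fraction | 1.0 | a pure fusion-positive sample; dilutions set 0–1 |
| read_length | 150 bp | paired-end short-read platform standard |
| fragment_mean / sd | 300 / 60 bp | bisulfite treatment fragments DNA; short inserts |
| conversion_rate | 0.995 | typical unmethylated-C→T conversion of current kits |
| meth_cpg / chg / chh | 0.75 / 0.01 / 0.01 | mammalian-like methylation landscape |
| seq_error | 0.001 | flat substitution error |
| mapq | 60 | oracle MAPQ for unique placements |
| min_clip | 20 bp | below typical aligner seed length a split is not reported |
| base quality | Q37 | constant; quality modeling is out of scope |

Conversion follows the directional (OT/OB) protocol: each fragment is
assigned an original strand uniformly; every cytosine on that strand is
first declared methylated with its context probability (context read
from the reference trinucleotide of the source sequence — wildtype
contig or fused allele — so junction-adjacent contexts are correct),
then, if unmethylated, rendered as thymine with `conversion_rate`.
Read 1 is sequenced off the converted strand (C→T pattern), read 2 off
its complement (G→A in reference orientation). Fragment lengths are
Normal(mean, sd) truncated below at the read length; fragment counts
are set so expected coverage over the genome matches `depth`.

Placement is by construction, not alignment: wildtype-origin reads get
one full-match primary record at their true locus; junction-crossing
reads get a soft-clipped primary for the longer segment plus a
hard-clipped supplementary for the shorter one, with reciprocal SA:Z
tags, correct paired-end flags and mate fields, and NM:i:0 (the oracle
defines truth; it does not re-estimate mismatches against the wildtype
reference, which bisulfite conversion would inflate meaninglessly). A
junction-side segment shorter than `min_clip` (default 20 bp) is
absorbed into the clip with no supplementary record — mirroring that an
aligner cannot seed a split below its seed length. Optional knobs
inject low-MAPQ pairs (to exercise the MAPQ filter), duplicate-flagged
copies (standing in for upstream duplicate marking; duplicates get
fresh query names and no truth rows, since truth describes molecules),
and random off-target inter-contig pairs (chimeric background noise).

What the generator does *not* emulate: realistic base-quality and error
profiles, indels, copy-number structure, non-directional (PBAT)
libraries, mappability variation, and genuine alignment failure modes
of bisulfite-converted sequence. Passing oracle tests therefore
demonstrates that the classification and localization logic is exact on
well-formed split alignments — not that any particular aligner will
produce such alignments from real WGBS reads.

## Coverage, downsampling, background

Coverage profiles count aligned bases only (CIGAR M/=/X) of primary,
non-duplicate records, averaged in bins (deletions advance the cursor
without depth). This is deliberately the quantity under which a true
junction produces a local drop: bases beyond the breakpoint belong to
the partner locus or are clipped.

Downsampling keeps each query name with probability f via a seeded
keyed hash (blake2b) of the name, so mates and supplementaries travel
together and subsets are nested across fractions for a fixed seed —
analogous to subsampling one library to increasing depths.

The genome-wide background scan operationalizes a "fusion-like" pair as
inter-contig, or intra-contig with mate separation > 1 Mb (default,
configurable), or carrying an SA entry across such a distance; the
target intervals in this package are always far apart or on different
contigs, so every true fusion pair is fusion-like. Pairs with both
mates inside the target intervals count as target-region signal,
everything else as genome-wide background; the partition is exact.

## Conversion-rate QC

For every reference cytosine covered by an aligned base, the read base
is counted as converted (T on the cytosine strand; A for bottom-strand
cytosines viewed in reference orientation) or retained (C/G), with the
context (CpG/CHG/CHH) from the reference trinucleotide on the
cytosine's strand. Which strand a record reports follows the
directional protocol: read 1 forward / read 2 reverse → top strand,
otherwise bottom. Restricting the assessment to a named contig
reproduces spike-in-style checks (all-context conversion on an
unmethylated contig; CpG retention = 1 − CpG conversion for a
CpG-methylated control); run genome-wide, the CHH rate is the
whole-genome conversion estimate.

## Limit of detection

Detection outcomes (detected_i of n_i at fraction x_i, in percent) are
fit by maximum-likelihood binomial regression with probit link,
P = Φ(a + bx). The LoD at confidence c is (Φ⁻¹(c) − a)/b, default
c = 0.95. The fit is deterministic. Four configurations are exposed
because the fraction scale and the handling of zero-fraction negative
controls are genuinely open choices: linear or log₁₀ fraction axis,
controls included or excluded. A log-scale fit cannot represent x = 0,
so the log-with-controls cell necessarily drops the zero rows and
coincides with log-without — it is reported anyway, flagged, for
completeness. On the reference dilution table (0 %: 0/3; 2 %: 1/3;
5 %: 2/3; 10–100 %: 3/3) the four cells give 7.36, 8.08, 9.32 and
9.32 %; the linear-scale exclude-zero fit is the documented worked
example.

Complete separation (outcomes split perfectly by a threshold fraction)
is detected combinatorially and flagged rather than raised; the MLE
then diverges and the result is marked non-converged/non-identifiable.
All-identical outcomes raise a fit error. A Firth-type bias-reduced fit
(penalized likelihood maximized numerically, seeded from the MLE when
finite) is available but off by default: with only a handful of
observations it shrinks the slope strongly and is intended as a
diagnostic under quasi-separation, not the reporting configuration.
Negative slopes make the LoD non-identifiable and are flagged.

## Problem sizes used in validation

The test suite runs entirely on generated data: 20 kb toy contigs at
depths 3–20× for unit tests; 1 000 pure-fusion fragments for exact
breakpoint recovery; depths 5/10/20× with 30 injected chimeric pairs
for the fusion-negative null; a 150× library downsampled to 10–100 %
for the linearity check; ten 2 kb-contig targets at depths graded
200–2000× for replicate concordance (the grading spans a ~10× dynamic
range of expected counts so that Poisson noise is small relative to
the graded spread, the regime in which a Pearson r ≥ 0.99 between
replicates is the expected outcome); and 200 simulated dilution
experiments (7 fractions × 3 replicates) for probit recovery. These
sizes were chosen as the smallest designs in which each property is
statistically decisive.

## Known limitations

- The caller trusts the aligner's SA tags; it does not realign clipped
  sequence, so breakpoint accuracy is bounded by the aligner's.
- Exact-coordinate breakpoint deduplication will split support across
  neighboring coordinates if an aligner places clip boundaries
  inconsistently around homology at the junction.
- Genome-wide "fusion-like" background depends on the 1 Mb separation
  convention; intra-contig fusions closer than that are invisible to
  the background scan (though not to the targeted caller, as long as
  the two gene intervals are disjoint).
- The probit LoD is a property of the whole design (depth, detection
  threshold, replicate count); estimates from triplicate designs carry
  wide sampling variability, which the recovery test quantifies.
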