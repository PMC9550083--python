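# Methods

This note documents the models, conventions and numerical choices behind
`indelmark`, in the order the pipeline runs them.

## Variant representation and normalization

An InDel is stored in VCF anchor-base convention: 1-based position, REF and
ALT alleles sharing their first base, signed length `len(ALT) − len(REF)`
(positive = insertion). Identity is the exact tuple
(chromosome, position, REF, ALT) — *allele-exact* matching, because a PCR
band reflects the exact length change, not merely the locus.

Calls from different accessions can describe the same event at different
anchors, so every call is normalized before any set operation: shared
trailing bases are trimmed (extending left with reference sequence whenever
an allele would empty), then shared leading bases are trimmed while both
alleles keep one base. This is the standard left-alignment/parsimony loop;
it is idempotent and is checked in the tests against an independent
string-diff oracle (longest common suffix first, then prefix).

Equal-length (SNP/MNP) alleles are rejected at the reader; multi-ALT records
are split into one candidate per carried allele. A site absent from a
sample's single-sample VCF is interpreted as reference genotype — the
semantics of per-sample (non-gVCF) caller output. This is a documented
limitation: a missing call caused by low coverage is indistinguishable from
true reference, and a real study would add a depth mask.

## Group-common catalogs and specific InDels

A group's catalog intersects the normalized allele sets of all members: an
allele is group-common when every member carries it. "Carries" defaults to
genotype-contains-ALT (heterozygous counts), with a `require_homozygous`
strict mode; the permissive default suits near-homozygous inbred rice lines
and matters only for heterozygous inputs.

A target-group-common allele is *subspecies-specific* when (i) no accession
of the other group carries the identical allele — a different-length ALT at
the same locus still qualifies, since it just predicts a third band — and
(ii) |length| is strictly greater than the 10 bp gel threshold
(`--min-indel-len`, default 10, applied as `> 10`). Each selected variant
carries a rule trace naming the conditions that admitted it.

Density bookkeeping uses half-open 100-kb windows on 0-based positions
(last window truncated at the chromosome end); per-chromosome density is
count per Mb of chromosome length, rounded to 2 decimals only in reports.
Both invariants — window counts summing to totals, density = count/Mb — are
asserted on every pipeline run.

## Primer design

Templates are 200 nt of reference flank on each side of the REF-allele site
(configurable); a template whose flank is truncated below 150 nt by a
chromosome end is flagged undesignable. Forward candidates are all
substrings of the left flank and reverse candidates all reverse-complemented
substrings of the right flank with length 18–25 nt. Filters, in order of
cost: GC in [0.40, 0.60]; nearest-neighbor Tm in [55, 63] °C; exactly one
exact full-length occurrence over both genome strands (via an 18-mer
positional index with extension check, equivalent to a naive scan). Pair
constraints: REF-allele product within [150, 300] bp (the alternate allele
may fall outside by up to the InDel length — when the product-range sources
disagree the stricter 150–300 bound is used), pair Tm difference ≤ 3 °C
(a standard default; not dictated by any protocol), and a minimal cross-dimer
filter rejecting pairs whose 3′-terminal 4-mers are mutually complementary.
No other hairpin/dimer thermodynamics are modelled.

The returned pair minimizes
`1.0·(|Tm_F−58| + |Tm_R−58|) + 0.5·(|len_F−21| + |len_R−21|)
+ 0.02·|product−225|` (weights configurable; units °C⁻¹, bp⁻¹, bp⁻¹), with
deterministic tie-breaking by leftmost forward start, smallest product, then
shortest primers. The search is exhaustive over the candidate space, so the
tests can require exact penalty agreement with an independent brute-force
enumerator.

Melting temperature: unified nearest-neighbor thermodynamics (SantaLucia
1998 parameter set), terminal A·T/G·C initiation terms, entropy salt
correction 0.368·(N−1)·ln[Na⁺], 50 mM monovalent salt, 50 nM of each strand
(duplex CT/4 model). The implementation is in-package and is cross-checked
in the tests against Biopython's `Tm_NN` under identical settings; a
Wallace-rule mode (2·(A+T) + 4·(G+C)) exists for closed-form checks.
The wet-lab annealing temperature corresponding to these constraints is
58 °C.

## In-silico PCR, gel model and classification

In-silico PCR is exact-match only (consistent with the exact-uniqueness
specificity filter): every forward match upstream of every
reverse-complement match, product capped at 2 kb. A marker fails when either
allele yields zero or multiple products. The virtual gel declares two bands
distinguishable when they differ by ≥ 10 bp (6 % polyacrylamide) or ≥ 20 bp
(4 % agarose) and both are within the gel's usable size range; these
thresholds are stated defaults, not measured mobilities, and are
configurable. Because the design filter already requires |ΔL| > 10 bp, every
designed marker is PAGE-resolvable by construction.

Classification operates on per-accession band *sets* so heterozygotes (two
bands) and third alleles are handled uniformly; the discriminating classes
require the two groups to share no band set. IJ names are assigned in
(reference-FASTA chromosome order, position) order, zero-padded to the
panel's ordinal width, after restricting to discriminating markers (default,
`--keep-all-classes` to disable). Gene annotation, when a GFF3 is supplied,
lists genes within 50 kb of the marker — an explicit stand-in for "tightly
linked", configurable.

## Marker application

Band matrices are varieties × markers over {0, 1, missing}. Genetic distance
is simple matching over pairwise-complete markers (Jaccard available);
missing-data handling is pairwise deletion, and a pair with zero comparable
markers yields a missing distance (error in strict mode). Clustering is
UPGMA — chosen over neighbor-joining because its ultrametric output matches
the use of such panels for subspecies grouping and admits a closed-form
two-taxon test — with ties broken by lexicographic cluster-name order so the
newick output is reproducible. The tests verify cophenetic agreement with
SciPy average linkage.

## Synthetic cohort

The generator emulates a resequencing panel of 10 + 10 inbred accessions
from two subspecies groups against a shared reference. Defaults: 2
chromosomes × 500 kb of i.i.d. sequence at GC 0.44 (rice-like); 200
group-specific InDels of 11–60 bp, 100 InDels shared by all 20 accessions,
50 private InDels (one carrier each) and 30 sub-threshold (≤ 10 bp)
group-specific-like InDels; homozygous 1/1 genotypes (a heterozygous
fraction exists only to exercise the zygosity policy). The genome scale is
deliberately far below a real rice genome so a full pipeline run takes
seconds; marker counts therefore exercise the method's logic, not its
genome-scale yield. Planted sites sit on a jittered 700-bp grid (minimum
spacing 500 bp, 1 kb end margins) so flank templates never overlap a
neighbouring variant or a chromosome end, and variants are emitted already
left-aligned, as a GATK-style caller would.

What the generator does *not* model: sequencing error and missing calls
(dropout exists only at the band-matrix stage), alignment artifacts,
repetitive or low-complexity reference sequence, linkage structure, and
population-level allele-frequency variation within a group. Passing the
closure tests therefore shows the selection/design/validation logic is
correct under clean input, not that real resequencing data will yield
markers at the same rate — on a real genome, repeats and near-duplications
are exactly what the genome-uniqueness and multi-product filters exist to
remove.

## Problem sizes and determinism

The test suite uses a small cohort (2 × 60 kb chromosomes, 3 + 3 samples,
25 planted variants) for unit tests and the full default cohort for the
closure tests; the acceptance script runs the full default cohort plus a
doubled small-cohort pipeline for the byte-identity check. All randomness
flows from a single integer seed through NumPy seed sequences; outputs
contain no timestamps, so identical configurations reproduce byte-identical
files.
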