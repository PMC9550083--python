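# indelmark

Development and application of subspecies-discriminating InDel PCR markers
from multi-accession variant calls.

## The problem

Rice breeders working with *Oryza sativa* ssp. *javanica* (tropical
japonica) germplasm need cheap, gel-readable codominant markers that
separate javanica from indica material — for hybrid identification, genetic
distance estimation and marker-assisted selection with nothing more than a
thermocycler and a polyacrylamide gel. Given resequencing-derived InDel call
sets for a panel of accessions split into two subspecies groups, `indelmark`
automates the whole marker-development workflow:

1. **Catalog** — normalize (left-align) every InDel call and build, per
   group, the set of *group-common* InDels: alleles carried by every
   accession of the group.
2. **Select** — keep *subspecies-specific* InDels: group-common in the
   target group, absent (as the identical allele) from every accession of
   the other group — irrespective of which group matches the reference —
   and with |length| > 10 bp so alleles resolve on a gel.
3. **Design** — extract 200 nt of reference flank on each side of the
   variant and search for a primer pair with length 18–25 nt (optimum 21),
   Tm 55–63 °C (optimum 58, nearest-neighbor thermodynamics), GC 40–60 %,
   exactly one exact match in the whole genome per primer, and a
   reference-allele product of 150–300 bp spanning the InDel. Among valid
   pairs the minimum-penalty pair is chosen:
   `w_tm·Σ|Tm−58| + w_len·Σ|len−21| + w_prod·|product−225|`.
4. **Validate in silico** — per-accession exact-match PCR on each allele,
   a virtual-gel resolvability check, and classification of every marker as
   failed / monomorphic / polymorphic-nondiscriminating /
   discriminating (biallelic or multiallelic). Discriminating markers are
   renamed IJ1…IJn along the genome and exported as a physical map.
5. **Apply** — score panels as binary band matrices (0/1/missing), report
   per-marker discrimination, compute simple-matching genetic distances
   d(i,j) = mismatches / pairwise-comparable markers, and cluster with
   UPGMA (newick output).

A seedable synthetic-cohort generator (`indelmark.synthetic_data`) plants
known variant classes — group-specific, shared, private, sub-threshold —
into a random reference so the entire pipeline can be exercised and checked
against planted truth without any external data.

## Worked example

```
indelmark simulate --outdir demo/cohort --seed 1
indelmark run-all \
    --reference demo/cohort/reference.fa \
    --vcf-dir demo/cohort/vcf \
    --groups demo/cohort/groups.tsv \
    --outdir demo/run --seed 1
```

prints

```
report written to demo/run/report.json
n_input_indel_calls: 4350
n_group_common_target: 330
n_specific_gt_minlen: 200
n_pairs_designed: 200
n_named_markers: 200
```

Reading the accounting chain: the 20 synthetic accessions contribute 4,350
InDel calls; 330 alleles are common to all ten javanica-like accessions
(200 planted group-specific + 100 shared + 30 sub-threshold); the >10 bp
cross-group specificity filter keeps exactly the 200 planted group-specific
InDels; a constraint-satisfying, genome-unique primer pair is found for all
200; and all 200 classify as discriminating_biallelic, so all are named
IJ001–IJ200. `demo/run/` also holds the marker table (primer sequences, Tm,
predicted REF/ALT product sizes), density tables (per-chromosome counts and
100-kb windows), the simulated band matrix, the genetic-distance matrix
(within-group 0, between-group 1 on this noiseless cohort) and the UPGMA
tree.

The same stages are available as library functions
(`group_common`, `specific_indels`, `design_pair`, `insilico_pcr`,
`classify_marker`, `genetic_distance`, `upgma_tree`, …) for use on real
per-sample VCFs against a real reference FASTA.

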