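"""InDel normalization, group-common catalogs, subspecies-specific selection
and genome-wide density statistics.

The central objects are :class:`IndelVariant` (one normalized
insertion/deletion in VCF anchor-base representation) and
:class:`GroupCatalog` (the InDel alleles shared by *every* accession of one
subspecies group). A *subspecies-specific* InDel is a group-common allele of
the target group that no accession of the other group carries — regardless of
which group matches the reference genome — and whose length exceeds the gel
threshold (default: strictly more than 10 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DesignError, ReferenceMismatchError
from .genome_io import ReferenceGenome, SampleCallSet

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True, order=True)
class IndelVariant:
    """A normalized InDel in VCF convention (1-based anchor base shared).

    ``length`` is signed: positive for insertions (ALT longer than REF),
    negative for deletions.
    """

    chromosome: str
    pos: int
    ref: str
    alt: str

    @property
    def length(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> VariantKey:
        return (self.chromosome, self.pos, self.ref, self.alt)

    def __post_init__(self) -> None:
        if len(self.alt) == len(self.ref):
            raise DesignError(
                f"{self.chromosome}:{self.pos} {self.ref}>{self.alt}: "
                "equal-length alleles are not an InDel"
            )


def normalize(
    chromosome: str, pos: int, ref: str, alt: str, reference: ReferenceGenome
) -> IndelVariant:
    """Left-align and parsimony-trim an InDel against the reference.

    Uses the standard variant-normalization loop: shared trailing bases are
    trimmed (extending left with reference sequence when an allele would
    empty), then shared leading bases are trimmed while both alleles keep at
    least one base. Idempotent; raises :class:`ReferenceMismatchError` when
    REF disagrees with the reference sequence.
    """
    if len(ref) == len(alt):
        raise DesignError(
            f"{chromosome}:{pos} {ref}>{alt}: equal-length alleles are not an InDel"
        )
    seq = reference.sequences.get(chromosome)
    if seq is None:
        raise ReferenceMismatchError(f"chromosome {chromosome!r} not in reference")
    if seq[pos - 1:pos - 1 + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"{chromosome}:{pos}: REF {ref!r} does not match reference "
            f"{seq[pos - 1:pos - 1 + len(ref)]!r}"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:  # cannot extend left past the chromosome start
                    base = ""
                else:
                    pos -= 1
                    base = seq[pos - 1]
                ref, alt = base + ref, base + alt
            continue
        if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            continue
        break
    return IndelVariant(chromosome, pos, ref, alt)


@dataclass
class GroupCatalog:
    """Per-group InDel catalog with a variant × sample presence map.

    ``presence`` covers every allele seen in *any* member (needed for
    cross-group absence checks); ``common`` holds only the alleles present in
    all members under the chosen zygosity policy.
    """

    group: str
    members: list[str]
    presence: dict[VariantKey, set[str]]
    variants: dict[VariantKey, IndelVariant]
    common: set[IndelVariant]

    @property
    def common_keys(self) -> set[VariantKey]:
        return {v.key for v in self.common}


def group_common(
    call_sets: list[SampleCallSet],
    reference: ReferenceGenome,
    require_homozygous: bool = False,
) -> GroupCatalog:
    """Build the group-common InDel catalog for one subspecies group.

    A sample "carries" an allele when its genotype contains at least one copy
    (``require_homozygous=True`` demands 1/1). An allele is group-common when
    every member carries the identical normalized allele.
    """
    if not call_sets:
        raise DesignError("group_common: empty group")
    groups = {cs.group for cs in call_sets}
    if len(groups) != 1:
        raise DesignError(f"group_common: mixed group labels {sorted(groups)}")
    members = [cs.sample_id for cs in call_sets]
    if len(set(members)) != len(members):
        raise DesignError("group_common: duplicated sample ids")

    presence: dict[VariantKey, set[str]] = {}
    variants: dict[VariantKey, IndelVariant] = {}
    for cs in call_sets:
        for call in cs.variants:
            if require_homozygous and not call.is_hom:
                continue
            v = normalize(call.chrom, call.pos, call.ref, call.alt, reference)
            variants.setdefault(v.key, v)
            presence.setdefault(v.key, set()).add(cs.sample_id)

    n = len(members)
    common = {variants[k] for k, samples in presence.items() if len(samples) == n}
    return GroupCatalog(
        group=groups.pop(),
        members=members,
        presence=presence,
        variants=variants,
        common=common,
    )


@dataclass
class SpecificIndelSet:
    """Subspecies-specific InDels of a target group, with a per-variant trace
    of the rule that admitted each one."""

    target_group: str
    other_group: str
    min_len: int
    variants: list[IndelVariant]
    rule_trace: dict[VariantKey, str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chromosome": v.chromosome,
                "position_1based": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "indel_length": v.length,
                "rule": self.rule_trace[v.key],
            }
            for v in self.variants
        ]
        return pd.DataFrame(
            rows,
            columns=["chromosome", "position_1based", "ref", "alt",
                     "indel_length", "rule"],
        )


def specific_indels(
    catalog_target: GroupCatalog,
    catalog_other: GroupCatalog,
    min_len: int = 10,
) -> SpecificIndelSet:
    """Select target-group-common InDels absent (as the identical allele) from
    every sample of the other group, with |length| strictly above ``min_len``.

    "Absent" is allele-exact: an other-group sample carrying a different ALT
    at the same locus still leaves the locus specific (it simply predicts a
    third band size on the gel). A sample whose VCF lacks the site is taken
    as reference genotype there.
    """
    selected: list[IndelVariant] = []
    trace: dict[VariantKey, str] = {}
    for v in sorted(catalog_target.common):
        if abs(v.length) <= min_len:
            continue
        carriers = catalog_other.presence.get(v.key, set())
        if carriers:
            continue
        n_other = len(catalog_other.members)
        trace[v.key] = (
            f"common_in_{catalog_target.group}({len(catalog_target.members)}/"
            f"{len(catalog_target.members)});|len|={abs(v.length)}>{min_len};"
            f"identical_allele_in_{catalog_other.group}:0/{n_other}"
        )
        selected.append(v)
    return SpecificIndelSet(
        target_group=catalog_target.group,
        other_group=catalog_other.group,
        min_len=min_len,
        variants=selected,
        rule_trace=trace,
    )


@dataclass
class DensityTable:
    """Per-chromosome InDel totals/densities and 100-kb window counts."""

    per_chromosome: pd.DataFrame  # chromosome, count, length_mb, density_per_mb
    windows: pd.DataFrame         # chromosome, window_index, start_1based, end_1based, count
    window_size: int

    def check(self) -> None:
        """Assert the bookkeeping invariants (window sums and density)."""
        sums = self.windows.groupby("chromosome")["count"].sum()
        for _, row in self.per_chromosome.iterrows():
            total = int(sums.get(row["chromosome"], 0))
            if total != int(row["count"]):
                raise AssertionError(
                    f"{row['chromosome']}: window sum {total} != total {row['count']}"
                )
            expect = row["count"] / row["length_mb"] if row["length_mb"] else 0.0
            if abs(expect - row["density_per_mb"]) > 1e-9:
                raise AssertionError(f"{row['chromosome']}: density mismatch")


def density_table(
    variants: list[IndelVariant] | set[IndelVariant],
    chrom_lengths: dict[str, int],
    window: int = 100_000,
) -> DensityTable:
    """Count InDels per chromosome and per half-open ``window``-bp bin.

    Windows are [k·w, (k+1)·w) on 0-based positions, the last window truncated
    at the chromosome end; densities are per Mb of chromosome length.
    """
    counts: dict[str, int] = {c: 0 for c in chrom_lengths}
    win_counts: dict[tuple[str, int], int] = {}
    for v in variants:
        if v.chromosome not in chrom_lengths:
            raise DesignError(f"variant on unknown chromosome {v.chromosome!r}")
        if v.pos > chrom_lengths[v.chromosome]:
            raise DesignError(
                f"{v.chromosome}:{v.pos} beyond chromosome length "
                f"{chrom_lengths[v.chromosome]}"
            )
        counts[v.chromosome] += 1
        k = (v.pos - 1) // window
        win_counts[(v.chromosome, k)] = win_counts.get((v.chromosome, k), 0) + 1

    chrom_rows = []
    win_rows = []
    for chrom, length in chrom_lengths.items():
        mb = length / 1e6
        chrom_rows.append(
            {
                "chromosome": chrom,
                "count": counts[chrom],
                "length_mb": mb,
                "density_per_mb": counts[chrom] / mb if mb else 0.0,
            }
        )
        n_windows = (length + window - 1) // window
        for k in range(n_windows):
            win_rows.append(
                {
                    "chromosome": chrom,
                    "window_index": k,
                    "start_1based": k * window + 1,
                    "end_1based": min((k + 1) * window, length),
                    "count": win_counts.get((chrom, k), 0),
                }
            )
    return DensityTable(
        per_chromosome=pd.DataFrame(
            chrom_rows, columns=["chromosome", "count", "length_mb", "density_per_mb"]
        ),
        windows=pd.DataFrame(
            win_rows,
            columns=["chromosome", "window_index", "start_1based", "end_1based", "count"],
        ),
        window_size=window,
    )


def between_group_diff(
    catalog_a: GroupCatalog, catalog_b: GroupCatalog, chromosomes: list[str]
) -> pd.DataFrame:
    """Per-chromosome count of loci where the two groups' common genotypes
    differ (symmetric difference of the common allele sets), plus the mean.

    Returns a frame with one row per chromosome and a trailing ``mean`` row.
    """
    diff = catalog_a.common_keys ^ catalog_b.common_keys
    counts = {c: 0 for c in chromosomes}
    for key in diff:
        counts[key[0]] += 1
    rows = [{"chromosome": c, "n_differing": counts[c]} for c in chromosomes]
    mean = sum(counts.values()) / len(chromosomes) if chromosomes else 0.0
    rows.append({"chromosome": "mean", "n_differing": mean})
    return pd.DataFrame(rows, columns=["chromosome", "n_differing"])
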