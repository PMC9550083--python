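"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Everything user-facing (VCF, marker TSVs, truth tables) is 1-based inclusive,
as in VCF; all in-memory sequence arithmetic is 0-based half-open. Functions
that take or return positions say which convention they use in their name or
docstring.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .errors import FormatError

_DNA = set("ACGTN")


@dataclass
class ReferenceGenome:
    """A reference assembly held fully in memory as uppercase strings.

    ``sequences`` maps chromosome name to sequence; chromosome order follows
    the order of appearance in the source FASTA, which is also the natural
    chromosome order used for marker naming downstream.
    """

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Sequence on [start0, end0), clipped to the chromosome."""
        seq = self.sequences[chrom]
        return seq[max(0, start0):min(len(seq), end0)]


@dataclass(frozen=True)
class VariantCall:
    """One raw InDel call from a single-sample VCF (pre-normalization).

    ``pos`` is the 1-based VCF anchor position. ``is_hom`` is true when the
    genotype is homozygous for this ALT allele; ``multiallelic`` marks calls
    split out of a multi-ALT record.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    is_hom: bool = True
    multiallelic: bool = False


@dataclass
class SampleCallSet:
    """All InDel calls of one accession, tagged with its subspecies group."""

    sample_id: str
    group: str
    variants: list[VariantCall] = field(default_factory=list)
    n_snps_dropped: int = 0


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    """Read a (multi-)FASTA into a :class:`ReferenceGenome`.

    Sequences are uppercased. Malformed headers, non-DNA characters and
    duplicated chromosome names raise :class:`FormatError` naming the line.
    """
    sequences: dict[str, list[str]] = {}
    name: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: line {lineno}: empty FASTA header")
                if name in sequences:
                    raise FormatError(
                        f"{path}: line {lineno}: duplicated chromosome name {name!r}"
                    )
                sequences[name] = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: line {lineno}: sequence before any FASTA header"
                    )
                chunk = line.upper()
                if not set(chunk) <= _DNA:
                    bad = sorted(set(chunk) - _DNA)
                    raise FormatError(
                        f"{path}: line {lineno}: non-DNA characters {bad}"
                    )
                sequences[name].append(chunk)
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome({n: "".join(parts) for n, parts in sequences.items()})


def write_fasta(genome: ReferenceGenome, path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _indel_calls_from_record(rec) -> tuple[list[VariantCall], int]:
    """Split a pysam record into per-ALT InDel calls carried by the genotype.

    Returns (calls, snps_dropped) where snps_dropped is 1 if the record held
    only equal-length (SNP/MNP) alleles.
    """
    sample = rec.samples[0]
    if "GT" not in sample or sample["GT"] is None or all(a is None for a in sample["GT"]):
        raise FormatError(
            f"{rec.chrom}:{rec.pos}: record has no GT genotype for the sample"
        )
    gt = tuple(a for a in sample["GT"] if a is not None)
    alts = rec.alts or ()
    multi = len(alts) > 1
    calls: list[VariantCall] = []
    any_indel = False
    for i, alt in enumerate(alts, start=1):
        if alt is None or alt.startswith("<"):
            continue
        if len(alt) == len(rec.ref):
            continue  # SNP/MNP allele
        any_indel = True
        if i not in gt:
            continue  # allele not carried by this sample
        calls.append(
            VariantCall(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref.upper(),
                alt=alt.upper(),
                is_hom=all(a == i for a in gt),
                multiallelic=multi,
            )
        )
    return calls, 0 if any_indel else 1


def read_sample_vcf(
    path: str | os.PathLike,
    sample_id: str,
    group: str,
    min_qual: float | None = None,
) -> SampleCallSet:
    """Read one single-sample VCF, keeping only InDel alleles the sample carries.

    Records whose every ALT allele has the same length as REF (SNPs/MNPs) are
    dropped and counted in ``n_snps_dropped``. Multi-ALT records contribute one
    :class:`VariantCall` per carried InDel allele, flagged multiallelic.
    ``min_qual`` optionally drops records below a QUAL threshold (no filtering
    by default).
    """
    callset = SampleCallSet(sample_id=sample_id, group=group)
    with pysam.VariantFile(os.fspath(path)) as vcf:
        if len(vcf.header.samples) != 1:
            raise FormatError(
                f"{path}: expected a single-sample VCF, found "
                f"{len(vcf.header.samples)} samples; split per sample first"
            )
        if "GT" not in vcf.header.formats:
            raise FormatError(f"{path}: VCF has no GT FORMAT field")
        for rec in vcf:
            if min_qual is not None and (rec.qual is None or rec.qual < min_qual):
                continue
            calls, dropped = _indel_calls_from_record(rec)
            callset.n_snps_dropped += dropped
            callset.variants.extend(calls)
    return callset


def write_sample_vcf(
    callset: SampleCallSet,
    path: str | os.PathLike,
    chrom_lengths: dict[str, int],
) -> None:
    """Write a minimal VCF 4.2 with one sample column and GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{callset.sample_id}\n"
        )
        order = {c: i for i, c in enumerate(chrom_lengths)}
        for v in sorted(callset.variants, key=lambda v: (order[v.chrom], v.pos)):
            gt = "1/1" if v.is_hom else "0/1"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t100\t.\t.\tGT\t{gt}\n"
            )


def split_multisample_vcf(
    path: str | os.PathLike, groups: dict[str, str]
) -> list[SampleCallSet]:
    """Convenience splitter for a merged multi-sample VCF (secondary path).

    ``groups`` maps sample name to group label; samples absent from the map
    are skipped. Per-sample single-VCF input remains the canonical route.
    """
    callsets: dict[str, SampleCallSet] = {}
    with pysam.VariantFile(os.fspath(path)) as vcf:
        names = [s for s in vcf.header.samples if s in groups]
        for s in names:
            callsets[s] = SampleCallSet(sample_id=s, group=groups[s])
        for rec in vcf:
            alts = rec.alts or ()
            multi = len(alts) > 1
            for s in names:
                gt = rec.samples[s].get("GT")
                if gt is None:
                    continue
                gt = tuple(a for a in gt if a is not None)
                for i, alt in enumerate(alts, start=1):
                    if alt is None or alt.startswith("<") or len(alt) == len(rec.ref):
                        continue
                    if i in gt:
                        callsets[s].variants.append(
                            VariantCall(
                                chrom=rec.chrom,
                                pos=rec.pos,
                                ref=rec.ref.upper(),
                                alt=alt.upper(),
                                is_hom=all(a == i for a in gt),
                                multiallelic=multi,
                            )
                        )
    return list(callsets.values())


MARKER_TABLE_COLUMNS = [
    "marker_name",
    "chromosome",
    "position_1based",
    "indel_length",
    "forward_primer",
    "reverse_primer",
    "product_size_ref",
    "product_size_alt",
    "tm_f",
    "tm_r",
    "classification",
]


def write_marker_table(markers: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a marker table TSV with the canonical column set."""
    if markers.empty:
        raise ValueError("refusing to write an empty marker table")
    missing = [c for c in MARKER_TABLE_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker table lacks columns: {missing}")
    out = markers[MARKER_TABLE_COLUMNS].copy()
    out["tm_f"] = out["tm_f"].round(2)
    out["tm_r"] = out["tm_r"].round(2)
    out.to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker_name": str, "chromosome": str})
    missing = [c for c in MARKER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: marker table lacks columns {missing}")
    return df


def read_gff3_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Extract gene features from a GFF3 as (chrom, start, end, strand, gene_id).

    Coordinates stay 1-based inclusive as in GFF3. The attribute column is
    only mined for ``ID=``; anything else is ignored.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "gene_id": attrs.get("ID", f"gene_line{lineno}"),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])
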