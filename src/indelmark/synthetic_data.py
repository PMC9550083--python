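"""Synthetic two-group cohort generator.

Emulates the variant structure of a resequencing panel of two rice subspecies
groups (default 10 + 10 inbred accessions) mapped against a common reference:

* ``group_specific`` — InDels carried by every accession of the target
  ("javanica-like") group and by none of the other group; the class the whole
  marker pipeline exists to recover. Lengths default to 11–60 bp, i.e. above
  the >10 bp gel threshold.
* ``group_common_shared`` — InDels carried by all accessions of both groups
  (divergence from the reference, useless as subspecies markers).
* ``private`` — InDels carried by exactly one accession.
* ``sub_threshold`` — group-specific-like InDels of length ≤ 10 bp that must
  be rejected by the length filter.

All randomness flows from ``CohortDesign.seed`` through ``numpy`` seed
sequences; every operation is deterministic for a fixed design. Planted sites
are spaced ≥ 500 bp apart so 200-nt flank templates never overlap a
neighbouring variant, and variants are emitted in left-aligned normalized
form (as a GATK-style caller would).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError
from .genome_io import (
    ReferenceGenome,
    SampleCallSet,
    VariantCall,
    write_fasta,
    write_sample_vcf,
)
from .indel_catalog import IndelVariant, normalize

GROUP_A = "indica-like"
GROUP_B = "javanica-like"

# planted-site geometry: margin from chromosome ends, grid pitch and jitter
# chosen so any two sites are >= 500 bp apart and flanks never truncate
_MARGIN = 1_000
_PITCH = 700
_JITTER = 200


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort; seed-determined throughout."""

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_per_group: int = 10
    n_group_specific: int = 200
    n_group_common_shared: int = 100
    n_private: int = 50           # total across all samples, one carrier each
    n_sub_threshold: int = 30
    indel_length_range: tuple[int, int] = (11, 60)
    sub_threshold_length_range: tuple[int, int] = (1, 10)
    gc_content: float = 0.44      # rice genome-wide GC is ~0.44
    heterozygous_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_group_specific", "n_group_common_shared", "n_private",
                     "n_sub_threshold"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.indel_length_range[0] <= 0:
            raise DesignError("indel_length_range lower bound must be > 0")
        if self.n_per_group < 1:
            raise DesignError("n_per_group must be >= 1")

    @property
    def n_planted(self) -> int:
        return (self.n_group_specific + self.n_group_common_shared
                + self.n_private + self.n_sub_threshold)

    @property
    def sample_ids(self) -> list[str]:
        a = [f"IND{i:02d}" for i in range(1, self.n_per_group + 1)]
        b = [f"JAV{i:02d}" for i in range(1, self.n_per_group + 1)]
        return a + b

    @property
    def groups(self) -> dict[str, str]:
        return {
            s: (GROUP_A if s.startswith("IND") else GROUP_B)
            for s in self.sample_ids
        }


def _rng(design: CohortDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng([design.seed, stream])


def generate_reference(design: CohortDesign) -> ReferenceGenome:
    """Generate an i.i.d. reference genome at the design GC content."""
    _check_capacity(design)
    rng = _rng(design, 0)
    gc = design.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    sequences = {}
    for i in range(design.n_chromosomes):
        draw = rng.choice(bases, size=design.chrom_length, p=p)
        sequences[f"chr{i + 1}"] = "".join(draw)
    return ReferenceGenome(sequences)


def _check_capacity(design: CohortDesign) -> None:
    per_chrom = max(0, (design.chrom_length - 2 * _MARGIN) // _PITCH)
    if per_chrom * design.n_chromosomes < design.n_planted:
        raise DesignError(
            f"chrom_length {design.chrom_length} too short for "
            f"{design.n_planted} planted variants at >=500 bp spacing"
        )


def _site_grid(design: CohortDesign, rng: np.random.Generator) -> list[tuple[str, int]]:
    """All candidate (chromosome, 1-based pos) sites, shuffled; grid pitch and
    jitter keep any two sites >= _PITCH - _JITTER = 500 bp apart."""
    sites: list[tuple[str, int]] = []
    for i in range(design.n_chromosomes):
        chrom = f"chr{i + 1}"
        grid = np.arange(_MARGIN, design.chrom_length - _MARGIN, _PITCH)
        jitter = rng.integers(0, _JITTER, size=grid.size)
        for pos0 in grid + jitter:
            sites.append((chrom, int(pos0) + 1))
    order = rng.permutation(len(sites))
    return [sites[i] for i in order]


def _make_variant(
    reference: ReferenceGenome,
    chrom: str,
    pos: int,
    length: int,
    insertion: bool,
    rng: np.random.Generator,
    gc: float,
) -> IndelVariant:
    seq = reference.sequences[chrom]
    anchor = seq[pos - 1]
    if insertion:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        ins = "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))
        ref, alt = anchor, anchor + ins
    else:
        ref, alt = anchor + seq[pos:pos + length], anchor
    return normalize(chrom, pos, ref, alt, reference)


def plant_cohort(
    reference: ReferenceGenome, design: CohortDesign
) -> tuple[list[SampleCallSet], pd.DataFrame]:
    """Plant the four variant classes and emit per-sample call sets plus the
    truth table (one row per planted variant; private variants count once).

    ``eligible`` flags the variants the full marker pipeline should recover:
    group-specific, length > 10 bp, full non-truncated flanks (guaranteed by
    the planting margins, so here simply class == group_specific with
    |length| > 10).
    """
    _check_capacity(design)
    rng = _rng(design, 1)
    sites = _site_grid(design, rng)
    if len(sites) < design.n_planted:
        raise DesignError("not enough candidate sites for the requested counts")

    classes = (
        ["group_specific"] * design.n_group_specific
        + ["group_common_shared"] * design.n_group_common_shared
        + ["private"] * design.n_private
        + ["sub_threshold"] * design.n_sub_threshold
    )
    samples = design.sample_ids
    groups = design.groups
    group_b_samples = [s for s in samples if groups[s] == GROUP_B]

    lo, hi = design.indel_length_range
    slo, shi = design.sub_threshold_length_range
    rows = []
    per_sample: dict[str, list[VariantCall]] = {s: [] for s in samples}
    used_keys: set = set()
    for cls, (chrom, pos) in zip(classes, sites):
        if cls == "sub_threshold":
            length = int(rng.integers(slo, shi + 1))
        else:
            length = int(rng.integers(lo, hi + 1))
        insertion = bool(rng.random() < 0.5)
        v = _make_variant(reference, chrom, pos, length, insertion, rng,
                          design.gc_content)
        if v.key in used_keys:  # left-shift collisions are geometrically excluded
            continue
        used_keys.add(v.key)

        if cls == "private":
            carriers = [samples[int(rng.integers(0, len(samples)))]]
        elif cls == "group_common_shared":
            carriers = samples
        else:  # group_specific and sub_threshold: all of group B, none of A
            carriers = group_b_samples

        is_hom = not (design.heterozygous_fraction > 0
                      and rng.random() < design.heterozygous_fraction)
        for s in carriers:
            per_sample[s].append(
                VariantCall(chrom=v.chromosome, pos=v.pos, ref=v.ref,
                            alt=v.alt, is_hom=is_hom)
            )
        rows.append(
            {
                "chromosome": v.chromosome,
                "position_1based": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "indel_length": v.length,
                "class": cls,
                "carriers": ",".join(carriers) if cls == "private" else cls,
                "eligible": cls == "group_specific" and abs(v.length) > 10,
            }
        )

    truth = pd.DataFrame(
        rows,
        columns=["chromosome", "position_1based", "ref", "alt", "indel_length",
                 "class", "carriers", "eligible"],
    ).sort_values(["chromosome", "position_1based"], kind="mergesort")
    truth = truth.reset_index(drop=True)

    call_sets = [
        SampleCallSet(sample_id=s, group=groups[s], variants=per_sample[s])
        for s in samples
    ]
    return call_sets, truth


def simulate_band_matrix(
    marker_variants: list[IndelVariant],
    call_sets: list[SampleCallSet],
    marker_names: list[str] | None = None,
    dropout_rate: float = 0.0,
    seed: int = 0,
):
    """Score a cohort against a marker panel as a binary band matrix.

    Entry is 1 when the accession carries the marker's javanica-type (ALT)
    allele, 0 otherwise; a ``dropout_rate`` fraction of entries is set to
    missing uniformly at random (failed lanes).
    """
    from .marker_analysis import BandMatrix  # local import to avoid a cycle

    if marker_names is None:
        marker_names = [
            f"M{i + 1:03d}" for i in range(len(marker_variants))
        ]
    if len(marker_names) != len(marker_variants):
        raise DesignError("marker_names length mismatch")
    carried = {
        cs.sample_id: {(c.chrom, c.pos, c.ref, c.alt) for c in cs.variants}
        for cs in call_sets
    }
    data = pd.DataFrame(
        [
            [1.0 if v.key in carried[cs.sample_id] else 0.0
             for v in marker_variants]
            for cs in call_sets
        ],
        index=[cs.sample_id for cs in call_sets],
        columns=marker_names,
        dtype=float,
    )
    if dropout_rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(data.shape) < dropout_rate
        data = data.mask(mask)
    groups = pd.Series({cs.sample_id: cs.group for cs in call_sets})
    return BandMatrix(data=data, groups=groups[data.index])


def write_cohort(
    outdir: str | os.PathLike,
    reference: ReferenceGenome,
    call_sets: list[SampleCallSet],
    truth: pd.DataFrame,
) -> dict[str, Path]:
    """Write FASTA + per-sample VCFs + truth TSV; returns the paths written."""
    out = Path(outdir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["reference"] = out / "reference.fa"
    write_fasta(reference, paths["reference"])
    lengths = reference.lengths
    for cs in call_sets:
        p = out / "vcf" / f"{cs.sample_id}.vcf"
        write_sample_vcf(cs, p, lengths)
        paths[cs.sample_id] = p
    paths["truth"] = out / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    groups = pd.DataFrame(
        [{"sample_id": cs.sample_id, "group": cs.group} for cs in call_sets]
    )
    paths["groups"] = out / "groups.tsv"
    groups.to_csv(paths["groups"], sep="\t", index=False)
    return paths
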