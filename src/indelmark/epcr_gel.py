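"""In-silico PCR, virtual-gel resolvability, marker classification, IJ naming
and physical-map export.

A marker's in-silico behaviour is evaluated per accession: the accession's
allele is substituted into the flank template, both primers are matched
exactly (forward on the plus strand, reverse as its reverse complement
downstream), and the resulting band sizes are collected. Markers are then
classified the way a gel would be read across the two subspecies panels:

* ``failed`` — some accession yields no product (or an ambiguous multi-product
  amplification);
* ``monomorphic`` — every accession shows the identical band set;
* ``discriminating_biallelic`` — exactly two distinct band sets, and no band
  set is shared between the two groups;
* ``discriminating_multiallelic`` — more than two distinct band sets, still
  perfectly separating the groups;
* ``polymorphic_nondiscriminating`` — polymorphic, but some band set occurs
  in both groups.

Discriminating markers are renamed IJ1…IJn by position along the genome
(chromosome order = order of appearance in the reference FASTA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DesignError
from .indel_catalog import IndelVariant
from .primer_engine import FlankTemplate, PrimerPair, revcomp

FAILED = "failed"
MONOMORPHIC = "monomorphic"
NONDISCRIMINATING = "polymorphic_nondiscriminating"
DISCRIMINATING_BI = "discriminating_biallelic"
DISCRIMINATING_MULTI = "discriminating_multiallelic"
DISCRIMINATING = {DISCRIMINATING_BI, DISCRIMINATING_MULTI}


@dataclass(frozen=True)
class Amplicon:
    """One predicted PCR product on a queried sequence (0-based half-open)."""

    start: int
    end: int
    allele: str = "ref"

    @property
    def size(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise DesignError("amplicon with non-positive size")


@dataclass
class GelModel:
    """Virtual gel: minimum resolvable size difference and largest usable band."""

    name: str = "page6"
    min_diff: int = 10     # 6 % polyacrylamide
    max_size: int = 1000


AGAROSE_4 = GelModel(name="agarose4", min_diff=20, max_size=2000)


def _find_all(pattern: str, seq: str) -> list[int]:
    hits = []
    start = seq.find(pattern)
    while start != -1:
        hits.append(start)
        start = seq.find(pattern, start + 1)
    return hits


def insilico_pcr(
    forward: str,
    reverse: str,
    sequence: str,
    max_product: int = 2000,
    allele: str = "ref",
) -> list[Amplicon]:
    """All exact-match amplicons of a primer pair on ``sequence``.

    The forward primer must match the plus strand; the reverse primer's
    reverse complement must match downstream without overlapping the forward
    site; products longer than ``max_product`` are not reported.
    """
    rc = revcomp(reverse)
    f_starts = _find_all(forward, sequence)
    r_starts = _find_all(rc, sequence)
    out = []
    for fs in f_starts:
        for rs in r_starts:
            end = rs + len(rc)
            if rs >= fs + len(forward) and end - fs <= max_product:
                out.append(Amplicon(start=fs, end=end, allele=allele))
    return out


def predict_allele_sizes(
    pair: PrimerPair,
    template: FlankTemplate,
    max_product: int = 2000,
) -> tuple[int, int] | None:
    """Band sizes on the REF and ALT alleles of the template, or None when
    either allele amplifies zero or several products (marker fails)."""
    ref_amps = insilico_pcr(pair.forward.sequence, pair.reverse.sequence,
                            template.template, max_product, allele="ref")
    alt_amps = insilico_pcr(pair.forward.sequence, pair.reverse.sequence,
                            template.alt_template(), max_product, allele="alt")
    if len(ref_amps) != 1 or len(alt_amps) != 1:
        return None
    return ref_amps[0].size, alt_amps[0].size


def resolvable(size_a: int, size_b: int, gel: GelModel | None = None) -> bool:
    """Whether two band sizes can be told apart on the virtual gel."""
    gel = gel or GelModel()
    if size_a <= 0 or size_b <= 0:
        raise DesignError("band sizes must be positive")
    return (abs(size_a - size_b) >= gel.min_diff
            and size_a <= gel.max_size and size_b <= gel.max_size)


def classify_marker(
    band_sets: dict[str, frozenset[int]],
    groups: dict[str, str],
) -> str:
    """Classify one marker from per-accession band sets (see module docs)."""
    missing = [v for v in band_sets if v not in groups]
    if missing:
        raise DesignError(f"no group label for varieties {missing}")
    if any(not bands for bands in band_sets.values()):
        return FAILED
    distinct = set(band_sets.values())
    if len(distinct) == 1:
        return MONOMORPHIC
    by_group: dict[str, set[frozenset[int]]] = {}
    for variety, bands in band_sets.items():
        by_group.setdefault(groups[variety], set()).add(bands)
    labels = sorted(by_group)
    if len(labels) == 2 and not (by_group[labels[0]] & by_group[labels[1]]):
        return DISCRIMINATING_BI if len(distinct) == 2 else DISCRIMINATING_MULTI
    return NONDISCRIMINATING


@dataclass
class MarkerRecord:
    """A designed marker: variant, primer pair, predicted sizes, outcome."""

    variant: IndelVariant
    pair: PrimerPair | None
    template: FlankTemplate
    size_ref: int | None = None
    size_alt: int | None = None
    classification: str = FAILED
    ij_name: str | None = None
    linked_genes: list[str] = field(default_factory=list)


def evaluate_markers(
    templates_pairs: list[tuple[FlankTemplate, PrimerPair | None]],
    carried: dict[str, set],
    groups: dict[str, str],
    gel: GelModel | None = None,
    max_product: int = 2000,
) -> list[MarkerRecord]:
    """Run per-accession in-silico PCR for every designed pair and classify.

    ``carried`` maps accession id to the set of variant keys it carries; an
    accession without the variant amplifies the REF allele. Band sizes that
    the gel cannot resolve collapse to the same lane signal, so an
    unresolvable REF/ALT difference reads as monomorphic.
    """
    gel = gel or GelModel()
    records: list[MarkerRecord] = []
    for template, pair in templates_pairs:
        rec = MarkerRecord(variant=template.variant, pair=pair, template=template)
        if pair is not None:
            sizes = predict_allele_sizes(pair, template, max_product)
            if sizes is not None:
                rec.size_ref, rec.size_alt = sizes
                same_lane = not resolvable(rec.size_ref, rec.size_alt, gel)
                band_sets = {}
                for variety in carried:
                    has_alt = template.variant.key in carried[variety]
                    size = rec.size_alt if has_alt else rec.size_ref
                    if same_lane:
                        size = rec.size_ref
                    band_sets[variety] = frozenset([size])
                rec.classification = classify_marker(band_sets, groups)
        records.append(rec)
    return records


def assign_ij_names(
    markers: list[MarkerRecord],
    chrom_order: list[str],
) -> list[MarkerRecord]:
    """Name markers IJ1…IJn by (chromosome order, position); idempotent.

    Ordinals are zero-padded to the width of the largest ordinal.
    """
    order = {c: i for i, c in enumerate(chrom_order)}
    unknown = [m for m in markers if m.variant.chromosome not in order]
    if unknown:
        raise DesignError(
            f"marker chromosome {unknown[0].variant.chromosome!r} not in reference"
        )
    keyed = sorted(markers, key=lambda m: (order[m.variant.chromosome],
                                           m.variant.pos))
    seen = set()
    for m in keyed:
        locus = (m.variant.chromosome, m.variant.pos)
        if locus in seen:
            raise DesignError(f"duplicate marker locus {locus}")
        seen.add(locus)
    width = len(str(len(keyed)))
    for i, m in enumerate(keyed, start=1):
        m.ij_name = f"IJ{i:0{width}d}"
    return keyed


def physical_map(
    markers: list[MarkerRecord],
    chrom_lengths: dict[str, int],
) -> tuple[pd.DataFrame, pd.Series]:
    """Marker positions ordered along each chromosome plus per-chromosome
    counts (chromosomes without markers included with count 0)."""
    order = {c: i for i, c in enumerate(chrom_lengths)}
    rows = sorted(
        (
            {
                "chromosome": m.variant.chromosome,
                "position_1based": m.variant.pos,
                "ij_name": m.ij_name or "",
            }
            for m in markers
        ),
        key=lambda r: (order[r["chromosome"]], r["position_1based"]),
    )
    table = pd.DataFrame(rows, columns=["chromosome", "position_1based", "ij_name"])
    counts = pd.Series(
        {c: int((table["chromosome"] == c).sum()) for c in chrom_lengths},
        name="n_markers",
    )
    return table, counts


def plot_physical_map(
    markers: list[MarkerRecord],
    chrom_lengths: dict[str, int],
    path: str,
) -> None:
    """Render the marker physical map (horizontal bars per chromosome)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 0.8 * max(2, len(chrom_lengths))))
    for i, (chrom, length) in enumerate(chrom_lengths.items()):
        y = len(chrom_lengths) - i
        ax.hlines(y, 0, length / 1e6, color="0.6", lw=6)
        for m in markers:
            if m.variant.chromosome == chrom:
                ax.vlines(m.variant.pos / 1e6, y - 0.2, y + 0.2, color="crimson")
        ax.text(-0.02 * max(chrom_lengths.values()) / 1e6, y, chrom,
                ha="right", va="center")
    ax.set_xlabel("position (Mb)")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def annotate_linked_genes(
    markers: list[MarkerRecord],
    genes: pd.DataFrame,
    window: int = 50_000,
) -> list[MarkerRecord]:
    """Attach gene IDs whose span lies within ``window`` bp of each marker."""
    for m in markers:
        sub = genes[genes["chrom"] == m.variant.chromosome]
        near = sub[
            (sub["start"] - window <= m.variant.pos)
            & (sub["end"] + window >= m.variant.pos)
        ]
        m.linked_genes = list(near["gene_id"])
    return markers
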