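"""Flank-template extraction and constraint-driven PCR primer design.

The design contract mirrors classic InDel-marker practice: 200 nt of
reference sequence is taken on each side of the variant; forward primers are
enumerated from the left flank and reverse primers from the
reverse-complemented right flank; candidates must satisfy length 18–25 nt
(optimum 21), melting temperature 55–63 °C (optimum 58), GC 40–60 %, and
exact genome uniqueness; pairs must amplify a 150–300 bp reference-allele
product spanning the InDel with a pair-Tm difference of at most 3 °C. Among
surviving pairs the one minimizing

    penalty = w_tm·(|Tm_F−58| + |Tm_R−58|) + w_len·(|len_F−21| + |len_R−21|)
              + w_product·|product_ref − 225|

is returned, ties broken by leftmost forward start, then smallest product,
then shortest primers — fully deterministic.

Melting temperatures use the unified nearest-neighbor thermodynamics
(SantaLucia 1998 parameter set) with an entropic salt correction of
0.368·(N−1)·ln[Na+]; defaults are 50 mM monovalent salt and 50 nM of each
strand. A Wallace-rule mode (2·(A+T) + 4·(G+C)) exists for quick closed-form
checks on short oligos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import DesignError
from .genome_io import ReferenceGenome
from .indel_catalog import IndelVariant

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Unified NN parameters (kcal/mol, cal/(mol*K)) for Watson-Crick stacks.
_NN_DH_DS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)   # terminal A·T initiation
_INIT_GC = (0.1, -2.8)  # terminal G·C initiation
_R_GAS = 1.987          # cal/(mol*K)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """(#G + #C) / length; N counts as non-GC (callers reject N upstream)."""
    if not seq:
        raise DesignError("gc_content of empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


@lru_cache(maxsize=200_000)
def melting_temperature(
    seq: str,
    mode: str = "nn",
    na_mM: float = 50.0,
    dnac_nM: float = 50.0,
) -> float:
    """Primer melting temperature in °C.

    ``mode="nn"``: nearest-neighbor duplex Tm for a non-self-complementary
    oligo at ``dnac_nM`` of each strand (effective concentration CT/4) with
    the 0.368·(N−1)·ln[Na+] entropy salt correction.
    ``mode="wallace"``: 2·(A+T) + 4·(G+C).
    """
    if not seq or set(seq) - set("ACGT"):
        raise DesignError(f"melting_temperature: non-ACGT sequence {seq!r}")
    if mode == "wallace":
        at = seq.count("A") + seq.count("T")
        return 2.0 * at + 4.0 * (len(seq) - at)
    if mode != "nn":
        raise DesignError(f"unknown Tm mode {mode!r}")
    dh = 0.0
    ds = 0.0
    for a, b in ((seq[0], _INIT_AT if seq[0] in "AT" else _INIT_GC),
                 (seq[-1], _INIT_AT if seq[-1] in "AT" else _INIT_GC)):
        dh += b[0]
        ds += b[1]
    for i in range(len(seq) - 1):
        h, s = _NN_DH_DS[seq[i:i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    # both strands at dnac_nM: CT/4 == dnac/2 in the two-state duplex model
    k = (dnac_nM / 2.0) * 1e-9
    return (dh * 1000.0) / (ds + _R_GAS * math.log(k)) - 273.15


@dataclass
class FlankTemplate:
    """Variant site plus its reference flanks, the raw material for design.

    ``template`` is left_flank + REF-allele site + right_flank, an exact
    substring of the reference starting at ``template_start0`` (0-based).
    Templates with a flank shorter than ``min_flank`` (chromosome-end
    truncation) are flagged undesignable.
    """

    variant: IndelVariant
    left_flank: str
    right_flank: str
    template: str
    template_start0: int
    truncated: bool
    designable: bool

    @property
    def site(self) -> str:
        return self.variant.ref

    @property
    def site_start_in_template(self) -> int:
        return len(self.left_flank)

    def alt_template(self) -> str:
        """The template with the ALT allele substituted at the site."""
        s = self.site_start_in_template
        return (self.template[:s] + self.variant.alt
                + self.template[s + len(self.variant.ref):])


def extract_flanks(
    reference: ReferenceGenome,
    variant: IndelVariant,
    flank: int = 200,
    min_flank: int = 150,
) -> FlankTemplate:
    """Extract ``flank`` nt on each side of the variant's REF-allele site."""
    if variant.chromosome not in reference.sequences:
        raise DesignError(f"chromosome {variant.chromosome!r} not in reference")
    seq = reference.sequences[variant.chromosome]
    site_start = variant.pos - 1
    site_end = site_start + len(variant.ref)
    left = seq[max(0, site_start - flank):site_start]
    right = seq[site_end:site_end + flank]
    truncated = len(left) < flank or len(right) < flank
    return FlankTemplate(
        variant=variant,
        left_flank=left,
        right_flank=right,
        template=left + seq[site_start:site_end] + right,
        template_start0=site_start - len(left),
        truncated=truncated,
        designable=len(left) >= min_flank and len(right) >= min_flank,
    )


@dataclass
class DesignConstraints:
    """All tunable primer-design thresholds with field-standard defaults."""

    primer_len: tuple[int, int] = (18, 25)
    primer_len_opt: int = 21
    tm_range: tuple[float, float] = (55.0, 63.0)
    tm_opt: float = 58.0
    gc_range: tuple[float, float] = (0.40, 0.60)
    product_range: tuple[int, int] = (150, 300)
    product_opt: int = 225
    max_pair_tm_diff: float = 3.0
    max_genome_hits: int = 1
    w_tm: float = 1.0     # penalty per °C from tm_opt
    w_len: float = 0.5    # penalty per bp from primer_len_opt
    w_product: float = 0.02  # penalty per bp from product_opt
    three_prime_clash_len: int = 4  # 3'-end cross-dimer word length (0 = off)

    def __post_init__(self) -> None:
        if not (self.primer_len[0] <= self.primer_len_opt <= self.primer_len[1]):
            raise DesignError("primer_len_opt outside primer_len range")
        if not (self.tm_range[0] <= self.tm_opt <= self.tm_range[1]):
            raise DesignError("tm_opt outside tm_range")
        if not (self.product_range[0] <= self.product_opt <= self.product_range[1]):
            raise DesignError("product_opt outside product_range")


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str
    strand: str              # "forward" | "reverse"
    start: int               # 0-based start of the binding site in the template
    tm: float
    gc: float
    genome_hits: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_size_ref: int
    product_size_alt: int
    penalty: float


class GenomeIndex:
    """Exact-occurrence index over both strands of a reference.

    Stores every k-mer start position of the forward strand; a primer's hit
    count is the number of extensions of its leading k-mer plus the same for
    its reverse complement. ``k`` must not exceed the shortest primer length.
    """

    def __init__(self, reference: ReferenceGenome, k: int = 18):
        self.reference = reference
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in reference.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                self._index.setdefault(kmer, []).append((chrom, i))

    def _count_forward(self, pattern: str, limit: int) -> int:
        hits = 0
        for chrom, i in self._index.get(pattern[:self.k], ()):
            seq = self.reference.sequences[chrom]
            if seq[i:i + len(pattern)] == pattern:
                hits += 1
                if hits >= limit:
                    return hits
        return hits

    def count(self, primer: str, limit: int = 2) -> int:
        """Occurrences of ``primer`` on either strand (early exit at limit)."""
        if len(primer) < self.k:
            raise DesignError(f"primer shorter than index k={self.k}")
        hits = self._count_forward(primer, limit)
        if hits < limit:
            hits += self._count_forward(revcomp(primer), limit - hits)
        return hits


def specificity_hits(
    primer: str,
    reference: ReferenceGenome,
    index: GenomeIndex | None = None,
) -> int:
    """Exact full-length occurrences of ``primer`` on either genome strand."""
    if set(primer) - set("ACGT"):
        raise DesignError(f"specificity_hits: non-ACGT primer {primer!r}")
    if index is not None:
        return index.count(primer, limit=10**9)
    hits = 0
    for pat in (primer, revcomp(primer)):
        for seq in reference.sequences.values():
            start = seq.find(pat)
            while start != -1:
                hits += 1
                start = seq.find(pat, start + 1)
    return hits


def _enumerate_candidates(
    region: str,
    region_offset: int,
    strand: str,
    constraints: DesignConstraints,
    index: GenomeIndex,
) -> list[PrimerCandidate]:
    """All constraint-satisfying primers whose binding site lies in ``region``
    (a flank), with ``region_offset`` the flank's 0-based template start.

    Reverse-strand primer sequences are the reverse complement of the binding
    site; ``start`` always refers to the plus-strand binding site.
    """
    lmin, lmax = constraints.primer_len
    out: list[PrimerCandidate] = []
    for start in range(0, len(region) - lmin + 1):
        for length in range(lmin, min(lmax, len(region) - start) + 1):
            site = region[start:start + length]
            if "N" in site:
                continue
            gc = gc_content(site)
            if not constraints.gc_range[0] <= gc <= constraints.gc_range[1]:
                continue
            seq = site if strand == "forward" else revcomp(site)
            tm = melting_temperature(seq)
            if not constraints.tm_range[0] <= tm <= constraints.tm_range[1]:
                continue
            hits = index.count(seq, limit=constraints.max_genome_hits + 1)
            if hits != constraints.max_genome_hits:
                continue
            out.append(
                PrimerCandidate(
                    sequence=seq,
                    strand=strand,
                    start=region_offset + start,
                    tm=tm,
                    gc=gc,
                    genome_hits=hits,
                )
            )
    return out


def _three_prime_word(seq: str, n: int) -> str:
    return seq[-n:]


def design_pair(
    template: FlankTemplate,
    constraints: DesignConstraints,
    index: GenomeIndex,
) -> PrimerPair | None:
    """Best constraint-satisfying primer pair for one flank template, or None.

    Exhaustive over all candidate substrings of the two flanks; see the module
    docstring for the penalty and the deterministic tie-break order.
    """
    if not template.designable:
        return None
    site_len = len(template.site)
    left_len = len(template.left_flank)
    fwd = _enumerate_candidates(
        template.left_flank, 0, "forward", constraints, index)
    rev = _enumerate_candidates(
        template.right_flank, left_len + site_len, "reverse", constraints, index)
    if not fwd or not rev:
        return None

    f_start = np.array([c.start for c in fwd])
    f_len = np.array([c.length for c in fwd])
    f_tm = np.array([c.tm for c in fwd])
    r_end = np.array([c.start + c.length for c in rev])
    r_len = np.array([c.length for c in rev])
    r_tm = np.array([c.tm for c in rev])

    product = r_end[None, :] - f_start[:, None]
    ok = (product >= constraints.product_range[0]) & (
        product <= constraints.product_range[1])
    ok &= np.abs(f_tm[:, None] - r_tm[None, :]) <= constraints.max_pair_tm_diff
    n = constraints.three_prime_clash_len
    if n > 0:
        # reject pairs whose 3' ends are mutually complementary n-mers
        f_word = np.array([_three_prime_word(c.sequence, n) for c in fwd])
        r_word = np.array([revcomp(_three_prime_word(c.sequence, n)) for c in rev])
        ok &= f_word[:, None] != r_word[None, :]
    if not ok.any():
        return None

    pen = (
        constraints.w_tm * (np.abs(f_tm - constraints.tm_opt)[:, None]
                            + np.abs(r_tm - constraints.tm_opt)[None, :])
        + constraints.w_len * (np.abs(f_len - constraints.primer_len_opt)[:, None]
                               + np.abs(r_len - constraints.primer_len_opt)[None, :])
        + constraints.w_product * np.abs(product - constraints.product_opt)
    )
    pen = np.where(ok, pen, np.inf)
    best = pen.min()
    fi_all, ri_all = np.nonzero(pen <= best + 1e-12)
    # deterministic tie-break: leftmost forward start, smallest product,
    # shortest forward, shortest reverse
    def tie_key(fr):
        fi, ri = fr
        return (int(f_start[fi]), int(product[fi, ri]),
                int(f_len[fi]), int(r_len[ri]))
    fi, ri = min(zip(fi_all, ri_all), key=tie_key)
    size_ref = int(product[fi, ri])
    return PrimerPair(
        forward=fwd[fi],
        reverse=rev[ri],
        product_size_ref=size_ref,
        product_size_alt=size_ref + template.variant.length,
        penalty=float(pen[fi, ri]),
    )


def design_panel(
    reference: ReferenceGenome,
    variants: list[IndelVariant],
    constraints: DesignConstraints | None = None,
    flank: int = 200,
    index: GenomeIndex | None = None,
) -> list[tuple[FlankTemplate, PrimerPair | None]]:
    """Extract flanks and design a primer pair for each variant (None where no
    pair satisfies the constraints; absence is a value, counted by callers)."""
    constraints = constraints or DesignConstraints()
    if index is None:
        index = GenomeIndex(reference, k=constraints.primer_len[0])
    results = []
    for v in variants:
        t = extract_flanks(reference, v, flank=flank)
        pair = design_pair(t, constraints, index) if t.designable else None
        results.append((t, pair))
    return results
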