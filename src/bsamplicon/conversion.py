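"""In-silico bisulfite conversion of reference sequences.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine is protected.  On the reference this is
modelled per strand: converting the forward strand turns every C into T;
converting the reverse strand, expressed in forward-strand coordinates,
turns every G into A.  Because methylation of a CpG protects its cytosine,
the sequence actually observed at a CpG is ambiguous -- C or T on the
forward strand, G or A on the reverse -- which is captured here with the
IUPAC codes Y (C/T) and R (G/A).

All coordinates are 0-based half-open internally; user-facing reports are
1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "ConvertedReference",
    "CpGSite",
    "convert_forward",
    "convert_reverse",
    "ambiguous_amplicon",
    "enumerate_cpgs",
    "build_converted_reference",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNYRacgtnyr", "TGCANRYtgcanry")
_VALID = re.compile(r"^[ACGTN]*$")


def _check_nucleotides(seq: str) -> None:
    m = re.search(r"[^ACGTN]", seq)
    if m:
        raise ValueError(
            f"non-nucleotide character {seq[m.start()]!r} at position {m.start()}"
        )


def revcomp(seq: str) -> str:
    """Reverse complement; supports the ambiguity codes Y and R."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def as_1based(self) -> str:
        """Genome-browser style ``chrom:start-end`` (1-based inclusive)."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class CpGSite:
    """A CpG dinucleotide, addressed by the forward-strand C position.

    ``polymorphic`` marks sites created (or destroyed) by allelic variation;
    ``present_in_sample`` then records which samples actually carry a CpG at
    this position, following the convention of reporting "NA" for samples
    whose genotype removes the site.
    """

    chrom: str
    pos: int
    strand_support: str = "both"  # forward | reverse | both
    polymorphic: bool = False
    present_in_sample: dict = field(default_factory=dict, compare=False, hash=False)


def convert_forward(seq: str) -> str:
    """Fully bisulfite-convert the forward strand: every C becomes T."""
    _check_nucleotides(seq)
    return seq.replace("C", "T")


def convert_reverse(seq: str) -> str:
    """Bisulfite-convert the reverse strand, in forward coordinates.

    Converting the reverse-complement strand and mapping back onto forward
    coordinates replaces every G with A:
    ``convert_reverse(s) == revcomp(convert_forward(revcomp(s)))``.
    """
    _check_nucleotides(seq)
    return seq.replace("G", "A")


def _cpg_c_positions(seq: str) -> list[int]:
    return [m.start() for m in re.finditer("(?=CG)", seq)]


def ambiguous_amplicon(original_seq: str, strand: str) -> str:
    """Ambiguity-coded converted sequence in forward coordinates.

    Forward strand: CpG-context C -> Y (methylation-dependent C/T), any
    other C -> T.  Reverse strand: the G of a CpG -> R (G/A), any other
    G -> A.  CpG context is determined on the original sequence only.
    """
    _check_nucleotides(original_seq)
    out = list(original_seq)
    if strand == "forward":
        for i, b in enumerate(out):
            if b == "C":
                out[i] = "Y" if original_seq[i + 1 : i + 2] == "G" else "T"
    elif strand == "reverse":
        for i, b in enumerate(out):
            if b == "G":
                out[i] = "R" if original_seq[i - 1 : i] == "C" and i > 0 else "A"
    else:
        raise ValueError(f"strand must be 'forward' or 'reverse', got {strand!r}")
    return "".join(out)


def enumerate_cpgs(
    seq: str,
    variants=None,
    chrom: str = "",
    offset: int = 0,
) -> list[CpGSite]:
    """All CpG sites in ``seq``, plus sites created by alternate alleles.

    ``variants`` is an optional iterable of records with attributes/keys
    ``pos`` (offset into seq), ``ref``, ``alt`` and optionally ``genotypes``
    (sample -> number of alt alleles, 0/1/2).  A variant whose alternate
    allele creates a CpG (by substituting at the C or the G position) adds a
    site flagged polymorphic; per-sample presence is computed from the
    genotypes (a site on at least one allele counts as present).
    """
    sites = {
        p: CpGSite(chrom=chrom, pos=offset + p, strand_support="both")
        for p in _cpg_c_positions(seq)
    }
    for var in variants or ():
        pos = var["pos"] if isinstance(var, dict) else var.pos
        ref = (var["ref"] if isinstance(var, dict) else var.ref).upper()
        alt = (var["alt"] if isinstance(var, dict) else var.alt).upper()
        genotypes = (
            var.get("genotypes") if isinstance(var, dict) else getattr(var, "genotypes", None)
        ) or {}
        if not (0 <= pos < len(seq)):
            raise ValueError(f"variant position {pos} outside sequence of length {len(seq)}")
        if len(ref) != 1 or len(alt) != 1:
            continue  # indels are out of scope for CpG bookkeeping
        mutated = seq[:pos] + alt + seq[pos + 1 :]
        created = []
        # substitution can create a CpG with its right or left neighbour
        if alt == "C" and mutated[pos + 1 : pos + 2] == "G":
            created.append(pos)
        if alt == "G" and pos > 0 and mutated[pos - 1] == "C":
            created.append(pos - 1)
        for c_pos in created:
            if c_pos in sites and not sites[c_pos].polymorphic:
                continue
            presence = {s: g > 0 for s, g in genotypes.items()}
            sites[c_pos] = CpGSite(
                chrom=chrom,
                pos=offset + c_pos,
                strand_support="both",
                polymorphic=True,
                present_in_sample=presence,
            )
        # a variant hitting an existing CpG's C or G destroys it on alt alleles
        for c_pos in (pos, pos - 1):
            site = sites.get(c_pos)
            if site is None or site.polymorphic:
                continue
            destroyed = (c_pos == pos and ref == "C" and alt != "C") or (
                c_pos == pos - 1 and ref == "G" and alt != "G"
            )
            if destroyed:
                presence = {s: g < 2 for s, g in genotypes.items()}
                sites[c_pos] = CpGSite(
                    chrom=chrom,
                    pos=offset + c_pos,
                    strand_support="both",
                    polymorphic=True,
                    present_in_sample=presence,
                )
    return [sites[p] for p in sorted(sites)]


@dataclass
class ConvertedReference:
    """One strand's bisulfite-converted view of a genomic interval.

    ``converted_seq`` is the fully converted sequence (what a completely
    unmethylated molecule would read); ``ambiguous_seq`` additionally codes
    every CpG position with Y (forward) or R (reverse).  ``cpg_positions``
    are offsets of the informative base on this strand: the C itself for the
    forward strand, the G (C position + 1) for the reverse strand.
    """

    source_interval: GenomicInterval
    strand: str
    original_seq: str
    converted_seq: str
    ambiguous_seq: str
    cpg_positions: list[int]

    @property
    def record_id(self) -> str:
        return f"{self.source_interval.name or self.source_interval.chrom}|{self.strand}"


def build_converted_reference(
    interval: GenomicInterval, seq: str, strand: str
) -> ConvertedReference:
    if strand == "forward":
        converted = convert_forward(seq)
        positions = _cpg_c_positions(seq)
    elif strand == "reverse":
        converted = convert_reverse(seq)
        positions = [p + 1 for p in _cpg_c_positions(seq)]
    else:
        raise ValueError(f"unknown strand {strand!r}")
    return ConvertedReference(
        source_interval=interval,
        strand=strand,
        original_seq=seq,
        converted_seq=converted,
        ambiguous_seq=ambiguous_amplicon(seq, strand),
        cpg_positions=positions,
    )
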