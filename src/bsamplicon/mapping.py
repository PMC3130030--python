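"""Assignment and alignment of bisulfite amplicon reads.

Reads are unoriented single-end sequences.  Each read is first searched for
panel primers with an Ukkonen-style approximate string match allowing at
most two unit-cost differences per primer (edlib's bit-parallel edit
distance); the best hit fixes the read's orientation and the candidate
amplicon set.  The read is then aligned to each candidate's ambiguity-coded
amplicon by dynamic programming in which Y matches C or T and R matches G
or A, so that the methylation state itself never counts against sequence
identity.  Reads need at least 50 matching bases and greater than 95%
identity to be kept; reads whose best alignments fall in different target
regions are discarded as ambiguous.  Primer footprints are trimmed before
any methylation scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices

from .conversion import ConvertedReference, revcomp
from .primers import PanelDesign, PrimerPair

__all__ = [
    "Amplicon",
    "PrimerHit",
    "MappedRead",
    "build_amplicons",
    "match_primers",
    "align_to_amplicons",
    "apply_filters",
    "trim_primers",
    "map_reads",
    "MIN_MATCHING_BASES",
    "MIN_IDENTITY",
    "MAX_PRIMER_DIFFERENCES",
]

MAX_PRIMER_DIFFERENCES = 2
MIN_MATCHING_BASES = 50
MIN_IDENTITY = 0.95  # strict: identity must exceed this

_ALPHABET = "ACGTNYR"
_COMPATIBLE = {
    "A": "AR",
    "C": "CY",
    "G": "GR",
    "T": "TY",
    "Y": "CTY",
    "R": "AGR",
    "N": "",
}


def bases_compatible(ref_base: str, read_base: str) -> bool:
    """True when a read base is consistent with an ambiguity-coded reference base."""
    return ref_base in _COMPATIBLE.get(read_base, "")


def _make_aligner() -> PairwiseAligner:
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = 1.0 if (bases_compatible(a, b) or bases_compatible(b, a)) else -1.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aligner.end_deletion_score = 0  # free reference overhang: reference-local, read-global
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product: the unit reads are aligned against.

    ``seq_ambig`` is the product's top strand (the strand beginning with the
    left primer) with every CpG position ambiguity-coded.  ``sites`` maps
    each CpG in the product to (genomic C position, offset of the
    informative base in the product); the informative base is C/T on
    forward-conversion amplicons and G/A on reverse-conversion ones.
    """

    amplicon_id: str
    region: str
    strand: str
    chrom: str
    start: int
    end: int
    seq_ambig: str
    left_len: int
    right_len: int
    sites: tuple[tuple[int, int], ...]
    pair: PrimerPair | None = None

    @property
    def meth_unmeth_bases(self) -> tuple[str, str]:
        return ("C", "T") if self.strand == "forward" else ("G", "A")

    @property
    def trimmed_span(self) -> tuple[int, int]:
        """Product offsets outside both primer footprints (half-open)."""
        return self.left_len, len(self.seq_ambig) - self.right_len


@dataclass(frozen=True)
class PrimerHit:
    read_id: str
    primer_id: str
    amplicon_id: str
    orientation: str  # "as-is" | "reverse-complement"
    edit_distance: int
    read_offset: int


@dataclass
class MappedRead:
    read_id: str
    read_len: int
    status: str = "no_primer"  # mapped | no_primer | low_identity | ambiguous
    amplicon_id: str | None = None
    region: str | None = None
    orientation: str | None = None
    matching_bases: int = 0
    aligned_columns: int = 0
    identity: float = 0.0
    site_bases: dict[int, str] = field(default_factory=dict)
    trimmed_read_bp: int = 0
    competing_regions: tuple[str, ...] = ()


def build_amplicons(
    panel: PanelDesign, region_refs: list[ConvertedReference]
) -> list[Amplicon]:
    """Instantiate ambiguity-coded amplicons for every selected primer pair."""
    amplicons = []
    for i, pair in enumerate(panel.selected_pairs):
        ref = next(
            (
                r
                for r in region_refs
                if r.strand == pair.strand
                and r.source_interval.chrom == pair.product_interval.chrom
                and r.source_interval.start <= pair.product_interval.start
                and pair.product_interval.end <= r.source_interval.end
            ),
            None,
        )
        if ref is None:
            raise ValueError(f"no converted reference covers pair {pair.pair_id}")
        region = ref.source_interval
        lo = pair.product_interval.start - region.start
        hi = pair.product_interval.end - region.start
        sites = []
        for p in ref.cpg_positions:
            if lo <= p < hi:
                c_pos = region.start + (p if ref.strand == "forward" else p - 1)
                sites.append((c_pos, p - lo))
        amplicons.append(
            Amplicon(
                amplicon_id=f"amp{i:04d}",
                region=region.name or region.as_1based(),
                strand=pair.strand,
                chrom=pair.product_interval.chrom,
                start=pair.product_interval.start,
                end=pair.product_interval.end,
                seq_ambig=ref.ambiguous_seq[lo:hi],
                left_len=len(pair.left_seq),
                right_len=len(pair.right_seq),
                sites=tuple(sites),
                pair=pair,
            )
        )
    return amplicons


def _primer_library(amplicons: list[Amplicon]):
    """Unique (sequence, orientation) probes -> amplicons sharing them.

    A top-strand read starts with the left primer and ends with the reverse
    complement of the right primer; a bottom-strand read shows the right
    primer and the reverse complement of the left one.
    """
    probes: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for amp in amplicons:
        left = amp.pair.left_seq if amp.pair else amp.seq_ambig[: amp.left_len]
        right = amp.pair.right_seq if amp.pair else revcomp(amp.seq_ambig[-amp.right_len :])
        entries = [
            (left, "as-is", f"{amp.amplicon_id}:left"),
            (revcomp(right), "as-is", f"{amp.amplicon_id}:right"),
            (right, "reverse-complement", f"{amp.amplicon_id}:right"),
            (revcomp(left), "reverse-complement", f"{amp.amplicon_id}:left"),
        ]
        for seq, orientation, pid in entries:
            probes.setdefault((seq, orientation), []).append((amp.amplicon_id, pid))
    return probes


def match_primers(
    read_id: str,
    read_seq: str,
    probes,
    max_differences: int = MAX_PRIMER_DIFFERENCES,
) -> list[PrimerHit]:
    """All primer probes locatable in the read with <= max_differences edits.

    Probes are matched as infix patterns (edit distance over the best
    placement inside the read); both read orientations are represented in
    the probe library, so the read itself is never reverse-complemented
    here.
    """
    if not probes:
        raise ValueError("empty primer library")
    hits = []
    for (seq, orientation), owners in probes.items():
        res = edlib.align(seq, read_seq, mode="HW", task="locations", k=max_differences)
        if res["editDistance"] == -1:
            continue
        offset = res["locations"][0][0] if res["locations"] else 0
        for amplicon_id, primer_id in owners:
            hits.append(
                PrimerHit(
                    read_id=read_id,
                    primer_id=primer_id,
                    amplicon_id=amplicon_id,
                    orientation=orientation,
                    edit_distance=res["editDistance"],
                    read_offset=offset or 0,
                )
            )
    return hits


def _column_stats(alignment, ref_seq: str, read_seq: str):
    """(matching_bases, total_columns, ref_offset -> read base map).

    Columns are counted over the read's span on the reference: aligned
    block columns plus internal insertion/deletion columns plus any read
    overhang beyond the reference; the reference outside the read span is
    free (reference-local alignment).
    """
    ref_blocks, read_blocks = alignment.aligned
    matching = 0
    columns = 0
    base_map: dict[int, str | None] = {}
    prev_r = prev_q = None
    for (r0, r1), (q0, q1) in zip(ref_blocks, read_blocks):
        if prev_r is not None:
            columns += (r0 - prev_r) + (q0 - prev_q)
            for gap_pos in range(prev_r, r0):  # deletion: no read base at these refs
                base_map[gap_pos] = None
        columns += r1 - r0
        for k in range(r1 - r0):
            rb, qb = ref_seq[r0 + k], read_seq[q0 + k]
            if bases_compatible(rb, qb):
                matching += 1
            base_map[r0 + k] = qb
        prev_r, prev_q = r1, q1
    if len(read_blocks):
        q_first = read_blocks[0][0]
        q_last = read_blocks[-1][1]
        columns += q_first + (len(read_seq) - q_last)  # unaligned read ends
    return matching, columns, base_map


def align_to_amplicons(
    read_id: str,
    read_seq: str,
    candidates: list[Amplicon],
    orientation: str = "as-is",
) -> MappedRead:
    """Align a read to every candidate amplicon; keep the best by matching bases.

    Identity is matching (ambiguity-compatible) columns over all aligned
    columns, gap columns included.  Candidates from a different target
    region that tie the winner, or that independently pass the mapping
    thresholds, mark the read as ambiguous downstream.
    """
    mr = MappedRead(read_id=read_id, read_len=len(read_seq))
    if not candidates:
        return mr
    seq = read_seq if orientation == "as-is" else revcomp(read_seq)
    results = []
    for amp in sorted(candidates, key=lambda a: a.amplicon_id):
        alignment = _ALIGNER.align(amp.seq_ambig, seq)[0]
        matching, columns, base_map = _column_stats(alignment, amp.seq_ambig, seq)
        identity = matching / columns if columns else 0.0
        results.append((matching, identity, columns, amp, base_map))
    results.sort(key=lambda r: (-r[0], r[3].amplicon_id))
    best = results[0]
    mr.status = "aligned"
    mr.amplicon_id = best[3].amplicon_id
    mr.region = best[3].region
    mr.orientation = orientation
    mr.matching_bases = best[0]
    mr.identity = best[1]
    mr.aligned_columns = best[2]
    competing = set()
    for matching, identity, _cols, amp, _bm in results[1:]:
        if amp.region == best[3].region:
            continue
        if matching == best[0] or (
            matching >= MIN_MATCHING_BASES and identity > MIN_IDENTITY
        ):
            competing.add(amp.region)
    mr.competing_regions = tuple(sorted(competing))
    # record bases at this amplicon's CpG sites (offset -> genomic position)
    meth, unmeth = best[3].meth_unmeth_bases
    site_bases = {}
    for genomic_pos, offset in best[3].sites:
        b = best[4].get(offset, "absent")
        if b == "absent":
            continue  # read does not span this site
        if b is None:
            site_bases[genomic_pos] = None  # gap at the site
        elif b == meth:
            site_bases[genomic_pos] = "C"
        elif b == unmeth:
            site_bases[genomic_pos] = "T"
        else:
            site_bases[genomic_pos] = "other"
    mr.site_bases = site_bases
    mr._best_amplicon = best[3]
    mr._base_map = best[4]
    return mr


def trim_primers(mr: MappedRead, amplicon: Amplicon) -> MappedRead:
    """Restrict scored sites and counted bases to the primer-free span."""
    lo, hi = amplicon.trimmed_span
    keep = {
        gpos for gpos, off in amplicon.sites if lo <= off < hi
    }
    mr.site_bases = {g: b for g, b in mr.site_bases.items() if g in keep}
    base_map = getattr(mr, "_base_map", {})
    mr.trimmed_read_bp = sum(
        1 for off, b in base_map.items() if lo <= off < hi and b is not None
    )
    return mr


def apply_filters(mapped_reads: list[MappedRead]) -> list[MappedRead]:
    """Final statuses: mapping thresholds and cross-region ambiguity."""
    for mr in mapped_reads:
        if mr.status == "no_primer":
            continue
        if mr.competing_regions:
            mr.status = "ambiguous"
        elif mr.matching_bases >= MIN_MATCHING_BASES and mr.identity > MIN_IDENTITY:
            mr.status = "mapped"
        else:
            mr.status = "low_identity"
    return mapped_reads


def map_reads(
    reads,
    amplicons: list[Amplicon],
    max_differences: int = MAX_PRIMER_DIFFERENCES,
) -> list[MappedRead]:
    """Run the full per-read pipeline: primer search, alignment, filters, trim.

    ``reads`` yields (read_id, sequence) pairs.  Returns one MappedRead per
    input read; statuses partition the input exactly
    (no_primer + low_identity + ambiguous + mapped = total).
    """
    probes = _primer_library(amplicons)
    amp_by_id = {a.amplicon_id: a for a in amplicons}
    out = []
    for read_id, seq in reads:
        hits = match_primers(read_id, seq, probes, max_differences)
        if not hits:
            out.append(MappedRead(read_id=read_id, read_len=len(seq)))
            continue
        best_d = min(h.edit_distance for h in hits)
        orientations = {h.orientation for h in hits if h.edit_distance == best_d}
        orientation = "as-is" if "as-is" in orientations else "reverse-complement"
        candidate_ids = {h.amplicon_id for h in hits if h.orientation == orientation}
        candidates = [amp_by_id[a] for a in sorted(candidate_ids)]
        mr = align_to_amplicons(read_id, seq, candidates, orientation)
        if mr.amplicon_id is not None:
            trim_primers(mr, amp_by_id[mr.amplicon_id])
        out.append(mr)
    return apply_filters(out)
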