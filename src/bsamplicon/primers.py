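"""Redundant PCR primer panel design on bisulfite-converted target DNA.

Converted DNA is effectively three-letter (the forward strand has lost its
non-CpG cytosines), which makes specific primer design hard; the strategy
implemented here compensates with redundancy.  Each target is cut into
overlapping 200/300/400 bp segments (5 bp spacing), primer pairs are
enumerated per segment under melting-temperature / length / GC constraints,
pairs touching common variants (MAF > 0.1) or CpG dinucleotides are masked,
survivors are screened in silico against the converted genome for off-target
products up to 2 kb, and a panel is selected greedily by increasing primer
GC content until each base reaches its size class's fold target (2-fold for
300 bp, 3-fold for 200 and 400 bp amplicons).  Regions left uncovered are
re-designed with the Tm window relaxed from 56+/-2 to 56+/-6 degC.
"""

from __future__ import annotations

import functools
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .conversion import ConvertedReference, GenomicInterval, revcomp

__all__ = [
    "DesignConstraints",
    "PrimerPair",
    "PanelDesign",
    "segment_targets",
    "melting_temperature",
    "generate_candidates",
    "mask_variant_and_cpg",
    "epcr_screen",
    "select_by_coverage",
    "relaxed_redesign",
    "design_panel",
    "calculated_peak_profile",
]

DEFAULT_SIZES = (200, 300, 400)
DEFAULT_FOLDS = {200: 3, 300: 2, 400: 3}
SEGMENT_SPACING = 5


@dataclass(frozen=True)
class DesignConstraints:
    """Primer3-style constraint set; defaults follow the converted-DNA design."""

    tm_opt: float = 56.0
    tm_tol: float = 2.0  # hard window tm_opt +/- tm_tol; relaxed mode uses 6
    tm_pair_max_diff: float = 2.0
    size_min: int = 18
    size_opt: int = 20
    size_max: int = 25
    gc_min: float = 20.0
    gc_opt: float = 60.0
    gc_max: float = 90.0
    product_slack: int = 50  # product size range = segment size +/- slack
    n_best: int = 5
    maf_threshold: float = 0.1
    max_offtarget_product: int = 2000

    def relaxed(self) -> "DesignConstraints":
        return replace(self, tm_tol=6.0)


@dataclass(frozen=True)
class PrimerPair:
    left_seq: str
    right_seq: str
    left_tm: float
    right_tm: float
    left_gc: float
    right_gc: float
    product_interval: GenomicInterval
    strand: str
    penalty: float
    source_segment: GenomicInterval
    size_class: int
    design_mode: str = "standard"

    @property
    def pair_id(self) -> str:
        return (
            f"{self.product_interval.chrom}|{self.strand}"
            f":{self.product_interval.start}-{self.product_interval.end}"
        )

    @property
    def product_length(self) -> int:
        return len(self.product_interval)

    @property
    def mean_gc(self) -> float:
        return 0.5 * (self.left_gc + self.right_gc)

    def footprints(self) -> tuple[GenomicInterval, GenomicInterval]:
        p = self.product_interval
        left = GenomicInterval(p.chrom, p.start, p.start + len(self.left_seq))
        right = GenomicInterval(p.chrom, p.end - len(self.right_seq), p.end)
        return left, right


@dataclass
class PanelDesign:
    selected_pairs: list[PrimerPair] = field(default_factory=list)
    # per-target coverage arrays over all selected amplicons (any size class)
    coverage: dict[str, np.ndarray] = field(default_factory=dict)
    targets: list[GenomicInterval] = field(default_factory=list)
    uncovered_intervals: list[GenomicInterval] = field(default_factory=list)

    def recompute_coverage(self) -> None:
        self.coverage = {
            t.name or t.as_1based(): np.zeros(len(t), dtype=int) for t in self.targets
        }
        for pair in self.selected_pairs:
            for t in self.targets:
                if pair.product_interval.overlaps(t):
                    key = t.name or t.as_1based()
                    lo = max(pair.product_interval.start, t.start) - t.start
                    hi = min(pair.product_interval.end, t.end) - t.start
                    self.coverage[key][lo:hi] += 1
        self.uncovered_intervals = []
        for t in self.targets:
            key = t.name or t.as_1based()
            self.uncovered_intervals.extend(_zero_runs(self.coverage[key], t))

    @property
    def covered_fraction(self) -> float:
        total = sum(len(t) for t in self.targets)
        if total == 0:
            return float("nan")
        covered = sum(int((c > 0).sum()) for c in self.coverage.values())
        return covered / total


def _zero_runs(cov: np.ndarray, target: GenomicInterval) -> list[GenomicInterval]:
    out = []
    in_run = False
    for i, c in enumerate(cov):
        if c == 0 and not in_run:
            run_start, in_run = i, True
        elif c > 0 and in_run:
            out.append(
                GenomicInterval(
                    target.chrom, target.start + run_start, target.start + i, name=target.name
                )
            )
            in_run = False
    if in_run:
        out.append(
            GenomicInterval(target.chrom, target.start + run_start, target.end, name=target.name)
        )
    return out


def segment_targets(
    region: GenomicInterval,
    sizes=DEFAULT_SIZES,
    spacing: int = SEGMENT_SPACING,
) -> list[GenomicInterval]:
    """Overlapping fixed-size windows across a target region.

    For each size, windows start at region.start, region.start+spacing, ...
    while they fit inside the region.
    """
    segments = []
    for size in sizes:
        start = region.start
        while start + size <= region.end:
            segments.append(
                GenomicInterval(region.chrom, start, start + size, name=region.name)
            )
            start += spacing
    return segments


@functools.lru_cache(maxsize=1 << 20)
def melting_temperature(seq: str) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    SantaLucia unified NN parameters, 50 mM monovalent cation, 50 nM oligo,
    no divalent correction; deterministic for a given sequence.
    """
    if len(seq) < 8:
        raise ValueError("sequence too short for nearest-neighbor Tm")
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"ambiguity codes not allowed in Tm computation: {seq}")
    return float(
        MeltingTemp.Tm_NN(
            seq,
            nn_table=MeltingTemp.DNA_NN3,
            Na=50,
            K=0,
            Tris=0,
            Mg=0,
            dNTPs=0,
            dnac1=50,
            dnac2=0,
            saltcorr=5,
        )
    )


def _gc_percent(seq: str) -> float:
    return 100.0 * gc_fraction(seq)


def _enumerate_side(
    converted: str,
    rel_lo: int,
    rel_hi: int,
    side: str,
    c: DesignConstraints,
) -> list[tuple[int, int, str, float, float]]:
    """Feasible single primers on one side.

    For the left side the returned coordinate is the primer start; for the
    right side it is the product end (primer 3' end + 1).  Right primers are
    the reverse complement of the template slice.
    """
    out = []
    for anchor in range(rel_lo, rel_hi + 1):
        for length in range(c.size_min, c.size_max + 1):
            if side == "left":
                s, e = anchor, anchor + length
            else:
                s, e = anchor - length, anchor
            if s < 0 or e > len(converted):
                continue
            tmpl = converted[s:e]
            if "N" in tmpl:
                continue
            seq = tmpl if side == "left" else revcomp(tmpl)
            gc = _gc_percent(seq)
            if not (c.gc_min <= gc <= c.gc_max):
                continue
            tm = melting_temperature(seq)
            if abs(tm - c.tm_opt) > c.tm_tol:
                continue
            out.append((anchor, length, seq, tm, gc))
    return out


def _pair_penalty(ltm: float, rtm: float, llen: int, rlen: int, c: DesignConstraints) -> float:
    return (
        abs(ltm - c.tm_opt)
        + abs(rtm - c.tm_opt)
        + 0.5 * (abs(llen - c.size_opt) + abs(rlen - c.size_opt))
        + abs(ltm - rtm)
    )


def generate_candidates(
    region_ref: ConvertedReference,
    segment: GenomicInterval,
    constraints: DesignConstraints | None = None,
) -> list[PrimerPair]:
    """The n_best lowest-penalty primer pairs for one segment.

    Primers are enumerated on the fully converted template (left primers as
    template prefixes of the product, right primers as reverse complements
    of its suffix); hard constraints are Tm window, length, GC bounds,
    pairwise Tm difference and product size within segment size +/- slack
    (clipped to the segment).  Penalty is |Tm-opt| per primer plus
    0.5*|len-opt| per primer plus the pair's Tm difference.
    """
    c = constraints or DesignConstraints()
    region = region_ref.source_interval
    size = len(segment)
    rel_start = segment.start - region.start
    rel_end = segment.end - region.start
    converted = region_ref.converted_seq

    lefts = _enumerate_side(
        converted, rel_start, min(rel_start + c.product_slack, rel_end - c.size_min), "left", c
    )
    rights = _enumerate_side(
        converted, max(rel_end - c.product_slack, rel_start + c.size_min), rel_end, "right", c
    )
    min_len = max(size - c.product_slack, 2 * c.size_min)
    max_len = size + c.product_slack

    pairs = []
    for ls, llen, lseq, ltm, lgc in lefts:
        for ranchor, rlen, rseq, rtm, rgc in rights:
            plen = ranchor - ls
            if not (min_len <= plen <= max_len):
                continue
            if abs(ltm - rtm) > c.tm_pair_max_diff:
                continue
            pairs.append(
                PrimerPair(
                    left_seq=lseq,
                    right_seq=rseq,
                    left_tm=ltm,
                    right_tm=rtm,
                    left_gc=lgc,
                    right_gc=rgc,
                    product_interval=GenomicInterval(
                        region.chrom, region.start + ls, region.start + ranchor
                    ),
                    strand=region_ref.strand,
                    penalty=_pair_penalty(ltm, rtm, llen, rlen, c),
                    source_segment=segment,
                    size_class=size,
                )
            )
    pairs.sort(key=lambda p: (p.penalty, p.left_seq, p.right_seq))
    return pairs[: c.n_best]


def mask_variant_and_cpg(
    candidates: list[PrimerPair],
    variants,
    region_ref: ConvertedReference,
    maf_threshold: float = 0.1,
) -> list[PrimerPair]:
    """Drop pairs whose primer footprints touch a common SNP or a CpG.

    A primer over a SNP with MAF above the threshold risks allelic
    amplification bias; a primer over a CpG would have methylation-dependent
    template sequence.  CpG positions are taken from the ambiguity-coded
    reference (Y/R columns).
    """
    region = region_ref.source_interval
    var_positions = [
        (v["pos"] if isinstance(v, dict) else v.pos)
        for v in variants or ()
        if (v["maf"] if isinstance(v, dict) else v.maf) > maf_threshold
    ]
    kept = []
    for pair in candidates:
        bad = False
        for fp in pair.footprints():
            if any(fp.start <= p < fp.end for p in var_positions):
                bad = True
                break
            rel = slice(fp.start - region.start, fp.end - region.start)
            if any(b in "YR" for b in region_ref.ambiguous_seq[rel]):
                bad = True
                break
        if not bad:
            kept.append(pair)
    return kept


def _binding_sites(primer: str, contig_seq: str, seed_len: int = 15, max_mm: int = 2):
    """(plus_starts, minus_starts) of primer annealing sites on one contig.

    Binding requires an exact match of the seed_len 3'-terminal bases and at
    most max_mm mismatches over the whole primer.  A plus site extends
    rightward (primer start positions); a minus site is the annealing of the
    primer to the opposite strand (reverse-complement match; positions are
    site start on the given contig).
    """
    n = len(primer)
    plus, minus = [], []
    seed = primer[-seed_len:]
    pos = contig_seq.find(seed)
    while pos != -1:
        start = pos - (n - seed_len)
        if start >= 0:
            window = contig_seq[start : start + n]
            if sum(a != b for a, b in zip(primer, window)) <= max_mm:
                plus.append(start)
        pos = contig_seq.find(seed, pos + 1)
    rc = revcomp(primer)
    seed_rc = rc[:seed_len]  # primer 3' end maps to the start of the rc match
    pos = contig_seq.find(seed_rc)
    while pos != -1:
        if pos + n <= len(contig_seq):
            window = contig_seq[pos : pos + n]
            if sum(a != b for a, b in zip(rc, window)) <= max_mm:
                minus.append(pos)
        pos = contig_seq.find(seed_rc, pos + 1)
    return plus, minus


def epcr_screen(
    pairs: list[PrimerPair],
    converted_genome: list[ConvertedReference],
    max_product: int = 2000,
) -> list[PrimerPair]:
    """In-silico PCR: drop pairs with any off-target product <= max_product.

    The background is every supplied converted contig (both conversion
    strands of the genome).  Any convergent placement of the pair's two
    primers (in either role) within max_product, other than the intended
    product, disqualifies the pair.
    """
    if not converted_genome:
        raise ValueError("e-PCR screen requires a converted background genome")
    kept = []
    for pair in pairs:
        intended = pair.product_interval
        offtarget = False
        for contig in converted_genome:
            seq = contig.converted_seq
            fwd_sites, rev_sites = [], []
            for primer in (pair.left_seq, pair.right_seq):
                plus, minus = _binding_sites(primer, seq)
                fwd_sites.extend((s, len(primer)) for s in plus)
                rev_sites.extend((s, len(primer)) for s in minus)
            for fs, flen in fwd_sites:
                for rs, rlen in rev_sites:
                    if rs + rlen - fs < flen + rlen:  # must not overlap-invert
                        continue
                    product_len = rs + rlen - fs
                    if product_len > max_product:
                        continue
                    is_intended = (
                        contig.source_interval.chrom == intended.chrom
                        and contig.strand == pair.strand
                        and contig.source_interval.start + fs == intended.start
                        and contig.source_interval.start + rs + rlen == intended.end
                    )
                    if not is_intended:
                        offtarget = True
                        break
                if offtarget:
                    break
            if offtarget:
                break
        if not offtarget:
            kept.append(pair)
    return kept


def deduplicate(pairs: list[PrimerPair]) -> list[PrimerPair]:
    """Remove redundant pairs (identical left+right primer sequences)."""
    seen = set()
    out = []
    for p in pairs:
        key = (p.left_seq, p.right_seq)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def select_by_coverage(
    pairs: list[PrimerPair],
    targets: list[GenomicInterval],
    fold_targets: dict[int, int] | None = None,
    panel: PanelDesign | None = None,
) -> PanelDesign:
    """Greedy coverage selection by increasing primer GC content.

    Within each amplicon size class, candidates are visited in order of
    increasing mean primer GC (ties broken lexicographically by primer
    sequence) and selected whenever any base of their product is still below
    the class's fold target.  An existing panel may be passed to extend
    (used by the relaxed redesign round).
    """
    folds = fold_targets or DEFAULT_FOLDS
    panel = panel or PanelDesign(targets=list(targets))
    pairs = deduplicate(pairs)
    class_cov: dict[tuple[int, str], np.ndarray] = {}
    for t in targets:
        key = t.name or t.as_1based()
        for size in folds:
            class_cov[(size, key)] = np.zeros(len(t), dtype=int)
    for p in panel.selected_pairs:  # account for previously selected amplicons
        for t in targets:
            if p.product_interval.overlaps(t):
                key = t.name or t.as_1based()
                lo = max(p.product_interval.start, t.start) - t.start
                hi = min(p.product_interval.end, t.end) - t.start
                if (p.size_class, key) in class_cov:
                    class_cov[(p.size_class, key)][lo:hi] += 1

    for size in sorted(folds):
        fold = folds[size]
        class_pairs = sorted(
            (p for p in pairs if p.size_class == size),
            key=lambda p: (p.mean_gc, p.left_seq, p.right_seq),
        )
        for p in class_pairs:
            useful = False
            for t in targets:
                if not p.product_interval.overlaps(t):
                    continue
                key = t.name or t.as_1based()
                lo = max(p.product_interval.start, t.start) - t.start
                hi = min(p.product_interval.end, t.end) - t.start
                if (class_cov[(size, key)][lo:hi] < fold).any():
                    useful = True
            if useful:
                panel.selected_pairs.append(p)
                for t in targets:
                    if p.product_interval.overlaps(t):
                        key = t.name or t.as_1based()
                        lo = max(p.product_interval.start, t.start) - t.start
                        hi = min(p.product_interval.end, t.end) - t.start
                        class_cov[(size, key)][lo:hi] += 1
    panel.recompute_coverage()
    return panel


def _design_round(
    region_refs: list[ConvertedReference],
    intervals: list[GenomicInterval],
    variants,
    background: list[ConvertedReference],
    constraints: DesignConstraints,
    sizes,
    mode: str,
) -> list[PrimerPair]:
    candidates: list[PrimerPair] = []
    for ref in region_refs:
        region = ref.source_interval
        for interval in intervals:
            if not interval.overlaps(region):
                continue
            clipped = GenomicInterval(
                interval.chrom,
                max(interval.start, region.start),
                min(interval.end, region.end),
                name=interval.name,
            )
            for segment in segment_targets(clipped, sizes=sizes):
                best = generate_candidates(ref, segment, constraints)
                best = mask_variant_and_cpg(best, variants, ref, constraints.maf_threshold)
                candidates.extend(best)
    candidates = deduplicate(candidates)
    candidates = epcr_screen(candidates, background, constraints.max_offtarget_product)
    if mode != "standard":
        candidates = [replace(p, design_mode=mode) for p in candidates]
    return candidates


def relaxed_redesign(
    panel: PanelDesign,
    region_refs: list[ConvertedReference],
    variants,
    background: list[ConvertedReference],
    constraints: DesignConstraints,
    sizes=DEFAULT_SIZES,
    fold_targets: dict[int, int] | None = None,
) -> PanelDesign:
    """Re-run the design on uncovered intervals with the Tm window widened.

    Uncovered gaps shorter than the smallest amplicon size are padded
    symmetrically (clipped to their parent region) so that segmentation can
    produce windows spanning them.
    """
    if not panel.uncovered_intervals:
        return panel
    relaxed = constraints.relaxed()
    padded = []
    for gap in panel.uncovered_intervals:
        pad = max(0, min(sizes) - len(gap))
        region = next(
            (r.source_interval for r in region_refs if gap.overlaps(r.source_interval)), None
        )
        if region is None:
            continue
        start = max(region.start, gap.start - (pad // 2 + pad % 2))
        end = min(region.end, max(gap.end + pad // 2, start + min(sizes)))
        start = max(region.start, min(start, end - min(sizes)))
        if end - start >= min(sizes):
            padded.append(GenomicInterval(gap.chrom, start, end, name=gap.name))
    pairs = _design_round(
        region_refs, padded, variants, background, relaxed, sizes, mode="relaxed"
    )
    return select_by_coverage(pairs, panel.targets, fold_targets, panel=panel)


def design_panel(
    region_refs: list[ConvertedReference],
    targets: list[GenomicInterval],
    background: list[ConvertedReference],
    variants=None,
    constraints: DesignConstraints | None = None,
    sizes=DEFAULT_SIZES,
    fold_targets: dict[int, int] | None = None,
    relax: bool = True,
) -> PanelDesign:
    """Full panel design: segment, constrain, mask, screen, select, relax."""
    c = constraints or DesignConstraints()
    folds = {s: (fold_targets or DEFAULT_FOLDS).get(s, 3) for s in sizes}
    pairs = _design_round(
        region_refs, targets, variants, background, c, sizes, mode="standard"
    )
    panel = select_by_coverage(pairs, targets, folds)
    if relax and panel.uncovered_intervals:
        panel = relaxed_redesign(
            panel, region_refs, variants, background, c, sizes, folds
        )
    return panel


def calculated_peak_profile(panel: PanelDesign, bin_width: int = 10) -> dict[int, int]:
    """Histogram of amplicon product sizes assuming equimolar representation.

    Models the expected electrophoretic trace of the pooled PCR library:
    bins are left edges (multiples of bin_width); counts sum to the number
    of amplicons.
    """
    profile: Counter[int] = Counter()
    for pair in panel.selected_pairs:
        profile[(pair.product_length // bin_width) * bin_width] += 1
    return dict(sorted(profile.items()))
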