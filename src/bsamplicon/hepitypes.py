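"""Hepitypes: phased methylation patterns read from single molecules.

A read that continuously spans every CpG of a region reports the joint
methylation state of one DNA molecule -- its hepitype, written as a string
over {C, T} (C = methylated, T = unmethylated) in site order.  Hepitypes
below 1% of spanning reads are discarded as likely artefacts; frequencies
are reported relative to all spanning reads and are deliberately not
renormalised after filtering.

The deviating-site test asks whether single-site deviations arise equally
often on the methylated and the unmethylated background -- at an imprinted
locus, an excess of deviations on the all-methylated background points at
imperfect maintenance methylation.  Each spanning read is assigned to the
nearer background by Hamming distance (exact ties excluded but counted),
cross-classified by exact-match versus >=1 deviating site, and tested with
Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .conversion import GenomicInterval

__all__ = [
    "Hepitype",
    "DeviationTable",
    "MIN_HEPITYPE_FREQUENCY",
    "extract_patterns",
    "extract_hepitypes",
    "filter_hepitypes",
    "deviation_table",
    "fisher_exact",
]

MIN_HEPITYPE_FREQUENCY = 0.01


@dataclass(frozen=True)
class Hepitype:
    region: GenomicInterval
    pattern: str
    count: int
    frequency: float


@dataclass
class DeviationTable:
    """2x2 counts: rows = backgrounds, columns = {exact match, >=1 deviation}."""

    counts: np.ndarray
    fisher_p: float
    n_ties: int = 0

    @property
    def total_assigned(self) -> int:
        return int(self.counts.sum())


def extract_patterns(mapped_reads, region: GenomicInterval, cpg_sites) -> list[str]:
    """One {C,T} pattern per read fully spanning the region's CpG sites.

    A read contributes only if its trimmed alignment shows a C or a T
    (strand-normalised) at every site; reads with a gap, a missing site or
    a non-C/T base are excluded here (they remain usable for per-site
    calls).
    """
    positions = sorted(
        s.pos for s in cpg_sites if region.contains(s.chrom, s.pos)
    )
    if not positions:
        raise ValueError(f"region {region.as_1based()} contains no CpG sites")
    patterns = []
    for mr in mapped_reads:
        if mr.status != "mapped":
            continue
        bases = [mr.site_bases.get(p) for p in positions]
        if all(b in ("C", "T") for b in bases):
            patterns.append("".join(bases))
    return patterns


def extract_hepitypes(
    mapped_reads, region: GenomicInterval, cpg_sites
) -> list[Hepitype]:
    """Aggregate spanning-read patterns into hepitypes with frequencies.

    Frequencies are relative to all pattern-complete spanning reads and sum
    to 1 before any filtering; hepitypes are ordered by descending count,
    ties lexicographic.
    """
    patterns = extract_patterns(mapped_reads, region, cpg_sites)
    total = len(patterns)
    if total == 0:
        return []
    counts: dict[str, int] = {}
    for p in patterns:
        counts[p] = counts.get(p, 0) + 1
    out = [
        Hepitype(region=region, pattern=p, count=c, frequency=c / total)
        for p, c in counts.items()
    ]
    out.sort(key=lambda h: (-h.count, h.pattern))
    return out


def filter_hepitypes(
    hepitypes: list[Hepitype], min_frequency: float = MIN_HEPITYPE_FREQUENCY
) -> list[Hepitype]:
    """Keep hepitypes strictly above the frequency cutoff (default 1%).

    Frequencies are left as observed-read fractions; they are not
    renormalised over the survivors.
    """
    return [h for h in hepitypes if h.frequency > min_frequency]


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums hypergeometric probabilities, at fixed margins, of all tables as or
    less probable than the observed one.  A zero margin admits only one
    table, so p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def deviation_table(patterns: list[str], use_read_counts: bool = True) -> DeviationTable:
    """Deviating-site 2x2 table and Fisher p over spanning-read patterns.

    Each pattern is assigned to the all-C or all-T background by Hamming
    proximity; equidistant patterns are excluded (tallied in ``n_ties``).
    Row 1 is the methylated background, row 2 the unmethylated one; column
    1 counts exact background matches, column 2 patterns with at least one
    deviating site.  With ``use_read_counts`` False, each distinct pattern
    contributes once instead of once per read.
    """
    if not use_read_counts:
        patterns = sorted(set(patterns))
    counts = np.zeros((2, 2), dtype=np.int64)
    ties = 0
    for p in patterns:
        d_meth = sum(ch != "C" for ch in p)
        d_unmeth = sum(ch != "T" for ch in p)
        if d_meth == d_unmeth:
            ties += 1
            continue
        row = 0 if d_meth < d_unmeth else 1
        col = 0 if (d_meth == 0 or d_unmeth == 0) else 1
        counts[row, col] += 1
    if counts.sum() == 0:
        return DeviationTable(counts=counts, fisher_p=float("nan"), n_ties=ties)
    return DeviationTable(counts=counts, fisher_p=fisher_exact(counts), n_ties=ties)
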