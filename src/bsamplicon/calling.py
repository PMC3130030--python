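"""Per-CpG methylation quantification from mapped, primer-trimmed reads.

Methylation at a CpG is the proportion of C among the C/T bases the reads
show at that position (reverse-strand reads report G/A, which the mapper
already normalises to C/T).  Bases other than C/T at a site count toward
depth but never toward the methylation level, and alignment gaps contribute
nothing.  Sites under 20 reads are flagged rather than suppressed, matching
the reporting convention of marking low-coverage values instead of hiding
them; sites a sample's genotype removes are reported NA, and sites with no
reads as "-".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .conversion import CpGSite

__all__ = [
    "CpGSiteCall",
    "ConcordanceReport",
    "LOW_COVERAGE_THRESHOLD",
    "call_sites",
    "annotate_sample_cpg_presence",
    "strand_concordance",
    "export_methylation_table",
    "read_methylation_table",
]

LOW_COVERAGE_THRESHOLD = 20


@dataclass
class CpGSiteCall:
    site: CpGSite
    sample: str
    n_C: int = 0
    n_T: int = 0
    n_other: int = 0
    flags: set = field(default_factory=set)

    @property
    def depth(self) -> int:
        return self.n_C + self.n_T + self.n_other

    @property
    def methylation(self) -> float:
        """C / (C + T), or NaN when no informative base was seen."""
        informative = self.n_C + self.n_T
        if informative == 0 or "not_a_cpg_in_sample" in self.flags:
            return float("nan")
        return self.n_C / informative


@dataclass
class ConcordanceReport:
    spearman_rho: float
    n_sites: int
    values_a: list[float] = field(default_factory=list)
    values_b: list[float] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.spearman_rho)


def call_sites(
    mapped_reads,
    cpg_registry: list[CpGSite],
    sample: str,
    strand: str | None = None,
    amplicons=None,
) -> list[CpGSiteCall]:
    """Aggregate per-site C/T/other counts over a sample's mapped reads.

    ``strand`` optionally restricts to reads mapped to amplicons of one
    conversion strand (requires ``amplicons`` for the lookup) -- used for
    cross-strand concordance.  Reads must already be primer-trimmed: a
    read's ``site_bases`` carries one normalised base ('C', 'T', 'other',
    or None for an alignment gap) per spanned CpG.
    """
    strand_of = {}
    if amplicons is not None:
        strand_of = {a.amplicon_id: a.strand for a in amplicons}
    calls = {s.pos: CpGSiteCall(site=s, sample=sample) for s in cpg_registry}
    for mr in mapped_reads:
        if mr.status != "mapped":
            continue
        if strand is not None and strand_of.get(mr.amplicon_id) != strand:
            continue
        for pos, base in mr.site_bases.items():
            call = calls.get(pos)
            if call is None or base is None:
                continue
            if base == "C":
                call.n_C += 1
            elif base == "T":
                call.n_T += 1
            else:
                call.n_other += 1
    for call in calls.values():
        if call.depth == 0:
            call.flags.add("no_reads")
        elif call.depth < LOW_COVERAGE_THRESHOLD:
            call.flags.add("low_coverage")
    return [calls[s.pos] for s in cpg_registry]


def annotate_sample_cpg_presence(
    calls: list[CpGSiteCall], genotype_table=None
) -> list[CpGSiteCall]:
    """Flag sites absent from a sample's genotype as not_a_cpg_in_sample.

    ``genotype_table`` maps sample -> {position -> bool presence}; sites of
    polymorphic CpGs missing on both alleles are reported NA.  With no
    table, the site's own ``present_in_sample`` annotation (from the CpG
    registry) is used; sites present on at least one allele are retained.
    """
    for call in calls:
        present = None
        if genotype_table is not None:
            present = genotype_table.get(call.sample, {}).get(call.site.pos)
        elif call.site.polymorphic and call.site.present_in_sample:
            present = call.site.present_in_sample.get(call.sample)
        if present is False:
            call.flags.add("not_a_cpg_in_sample")
    return calls


def strand_concordance(
    calls_forward: list[CpGSiteCall], calls_reverse: list[CpGSiteCall]
) -> ConcordanceReport:
    """Spearman rank correlation of site methylation between two call sets.

    Computed only over sites defined in both series (average ranks for
    ties); fewer than 3 shared sites yields an undefined (NaN) report.
    """
    by_pos = {c.site.pos: c for c in calls_reverse}
    a, b = [], []
    for cf in calls_forward:
        cr = by_pos.get(cf.site.pos)
        if cr is None:
            continue
        ma, mb = cf.methylation, cr.methylation
        if math.isnan(ma) or math.isnan(mb):
            continue
        a.append(ma)
        b.append(mb)
    if len(a) < 3:
        return ConcordanceReport(spearman_rho=float("nan"), n_sites=len(a))
    rho = stats.spearmanr(a, b).statistic
    return ConcordanceReport(spearman_rho=float(rho), n_sites=len(a), values_a=a, values_b=b)


def export_methylation_table(calls_by_sample: dict[str, list]) -> pd.DataFrame:
    """Wide site x sample table of percent methylation.

    "-" marks sites with no reads, "NA" sites the sample's genotype removes;
    an extra flag column preserves low-coverage / polymorphic markup.
    """
    rows = {}
    flags = {}
    for sample, calls in calls_by_sample.items():
        for call in calls:
            key = (call.site.chrom, call.site.pos + 1)  # 1-based in reports
            rows.setdefault(key, {})
            if "not_a_cpg_in_sample" in call.flags:
                rows[key][sample] = "NA"
            elif "no_reads" in call.flags:
                rows[key][sample] = "-"
            else:
                rows[key][sample] = f"{100.0 * call.methylation:.1f}"
            fl = flags.setdefault(key, set())
            if "low_coverage" in call.flags:
                fl.add(f"low_coverage:{sample}")
            if call.site.polymorphic:
                fl.add("snp_created")
    index = sorted(rows)
    df = pd.DataFrame(
        [rows[k] for k in index],
        index=pd.MultiIndex.from_tuples(index, names=["chrom", "pos"]),
    )
    df["flags"] = [";".join(sorted(flags[k])) if flags[k] else "" for k in index]
    return df.reset_index()


def read_methylation_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
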