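"""Readers and writers for the pipeline's external formats.

FASTA/FASTQ go through Biopython; targets are plain BED; panels, per-read
assignments, methylation tables, hepitype tables and run summaries are TSV;
trees are Newick; configuration is YAML.  Every writer has a matching
reader so each artefact round-trips.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conversion import ConvertedReference, GenomicInterval
from .primers import DesignConstraints, PanelDesign, PrimerPair

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "write_converted_fasta",
    "write_cpg_registry",
    "write_panel",
    "read_panel",
    "write_read_assignments",
    "file_digest",
    "load_config",
    "save_config",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path):
    """Yield (read_id, sequence); FASTA input is accepted transparently."""
    path = str(path)
    fmt = "fastq"
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        fmt = "fasta"
    for rec in SeqIO.parse(path, fmt):
        yield rec.id, str(rec.seq).upper()


def write_fastq(path, reads) -> None:
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [30] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        name = fields[3] if len(fields) > 3 else ""
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name=name))
    return out


def write_bed(path, intervals: list[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def write_converted_fasta(path, refs: list[ConvertedReference]) -> None:
    """Converted references as FASTA; strand is suffixed to the record id."""
    write_fasta(path, {r.record_id: r.converted_seq for r in refs})


def write_cpg_registry(path, sites, samples: list[str] | None = None) -> None:
    rows = []
    for s in sites:
        row = {
            "chrom": s.chrom,
            "pos": s.pos + 1,  # 1-based in reports
            "strand_support": s.strand_support,
            "polymorphic": s.polymorphic,
        }
        for sample in samples or []:
            row[f"present:{sample}"] = s.present_in_sample.get(sample, True)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_PANEL_COLUMNS = [
    "pair_id",
    "left_seq",
    "right_seq",
    "left_tm",
    "right_tm",
    "left_gc",
    "right_gc",
    "chrom",
    "product_start",
    "product_end",
    "strand",
    "penalty",
    "size_class",
    "design_mode",
    "segment_start",
    "segment_end",
]


def write_panel(path, panel: PanelDesign) -> None:
    rows = []
    for p in panel.selected_pairs:
        rows.append(
            {
                "pair_id": p.pair_id,
                "left_seq": p.left_seq,
                "right_seq": p.right_seq,
                "left_tm": round(p.left_tm, 2),
                "right_tm": round(p.right_tm, 2),
                "left_gc": round(p.left_gc, 2),
                "right_gc": round(p.right_gc, 2),
                "chrom": p.product_interval.chrom,
                "product_start": p.product_interval.start,
                "product_end": p.product_interval.end,
                "strand": p.strand,
                "penalty": round(p.penalty, 4),
                "size_class": p.size_class,
                "design_mode": p.design_mode,
                "segment_start": p.source_segment.start,
                "segment_end": p.source_segment.end,
            }
        )
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel(path, targets: list[GenomicInterval] | None = None) -> PanelDesign:
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for _, r in df.iterrows():
        pairs.append(
            PrimerPair(
                left_seq=r["left_seq"],
                right_seq=r["right_seq"],
                left_tm=float(r["left_tm"]),
                right_tm=float(r["right_tm"]),
                left_gc=float(r["left_gc"]),
                right_gc=float(r["right_gc"]),
                product_interval=GenomicInterval(
                    r["chrom"], int(r["product_start"]), int(r["product_end"])
                ),
                strand=r["strand"],
                penalty=float(r["penalty"]),
                source_segment=GenomicInterval(
                    r["chrom"], int(r["segment_start"]), int(r["segment_end"])
                ),
                size_class=int(r["size_class"]),
                design_mode=r["design_mode"],
            )
        )
    panel = PanelDesign(selected_pairs=pairs, targets=list(targets or []))
    if targets:
        panel.recompute_coverage()
    return panel


def write_read_assignments(path, mapped_reads) -> None:
    rows = [
        {
            "read_id": mr.read_id,
            "amplicon": mr.amplicon_id or "",
            "region": mr.region or "",
            "status": mr.status,
            "matching_bases": mr.matching_bases,
            "identity": round(mr.identity, 4),
            "read_len": mr.read_len,
            "trimmed_read_bp": mr.trimmed_read_bp,
        }
        for mr in mapped_reads
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def constraints_from_config(cfg: dict) -> DesignConstraints:
    allowed = set(DesignConstraints.__dataclass_fields__)
    return DesignConstraints(**{k: v for k, v in (cfg or {}).items() if k in allowed})
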