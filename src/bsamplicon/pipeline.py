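"""End-to-end orchestration: simulate -> design -> map -> call -> hepitype.

``run_pipeline`` executes the requested stages in order, persists every
intermediate artefact under an output directory, and writes a run manifest
with input digests, seeds and per-stage read accounting.  The summary table
follows the run-report convention: raw reads, total bases, mapped reads,
mapped bases excluding primer footprints, and per-amplicon read yield
normalised to 100,000 reads per library.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import (
    annotate_sample_cpg_presence,
    call_sites,
    export_methylation_table,
    strand_concordance,
)
from .conversion import GenomicInterval, enumerate_cpgs
from .hepitypes import (
    MIN_HEPITYPE_FREQUENCY,
    deviation_table,
    extract_hepitypes,
    extract_patterns,
    filter_hepitypes,
)
from .io import (
    file_digest,
    write_bed,
    write_converted_fasta,
    write_cpg_registry,
    write_fasta,
    write_fastq,
    write_panel,
    write_read_assignments,
)
from .mapping import build_amplicons, map_reads
from .parsimony import bootstrap_support, parsimony_tree
from .primers import DesignConstraints, calculated_peak_profile, design_panel
from .simulate import (
    SimConfig,
    converted_references_for,
    draw_reads,
    make_reference,
    scenario_presets,
)

logger = logging.getLogger("bsamplicon")

__all__ = ["RunManifest", "run_pipeline", "summarize_run"]


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    accounting: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def summarize_run(mapped_reads, sample: str = "sample") -> pd.DataFrame:
    """Per-sample run summary plus normalised per-amplicon yield.

    One row per sample with raw read count, total bases, mapped reads and
    mapped bases excluding primers; per-amplicon reads are scaled to a
    library of 100,000 reads.
    """
    statuses = pd.Series([mr.status for mr in mapped_reads])
    raw = len(mapped_reads)
    summary = pd.DataFrame(
        [
            {
                "sample": sample,
                "reads": raw,
                "total_bp": sum(mr.read_len for mr in mapped_reads),
                "mapped_reads": int((statuses == "mapped").sum()),
                "mapped_bp_wo_primers": sum(
                    mr.trimmed_read_bp for mr in mapped_reads if mr.status == "mapped"
                ),
                "no_primer": int((statuses == "no_primer").sum()),
                "low_identity": int((statuses == "low_identity").sum()),
                "ambiguous": int((statuses == "ambiguous").sum()),
            }
        ]
    )
    per_amp = (
        pd.Series(
            [mr.amplicon_id for mr in mapped_reads if mr.status == "mapped"],
            dtype="object",
        )
        .value_counts()
        .rename("reads")
        .rename_axis("amplicon")
        .reset_index()
    )
    per_amp["normalized_yield"] = per_amp["reads"] * (100_000 / raw) if raw else 0.0
    return summary, per_amp


def run_pipeline(config: dict, outdir) -> RunManifest:
    """Run the configured stages; see the CLI for the config schema.

    Recognised stages: simulate, design, map, call, hepitype.  A stage that
    needs a missing upstream artefact fails naming it.  Reruns with the
    same config and seed are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config)
    stages = config.get("stages", ["simulate", "design", "map", "call", "hepitype"])
    seed = int(config.get("seed", 0))
    manifest.seeds["master"] = seed

    preset_name = config.get("preset", "imprinted")
    preset = scenario_presets()[preset_name]
    timepoint = int(config.get("timepoint", 0))
    simcfg = SimConfig(
        seed=seed,
        depth=int(config.get("depth", preset.config.depth)),
        conversion_efficiency=float(
            config.get("conversion_efficiency", preset.config.conversion_efficiency)
        ),
        substitution_rate=float(config.get("substitution_rate", 0.0)),
        read_length_mean=float(config.get("read_length_mean", 204.0)),
        read_length_sd=float(config.get("read_length_sd", 15.0)),
    )

    genome, targets = make_reference(
        n_regions=int(config.get("n_regions", 1)),
        region_length=int(config.get("region_length", 260)),
        cpgs_per_region=int(config.get("cpgs_per_region", 8)),
        seed=seed,
        decoy=bool(config.get("decoy", False)),
    )
    write_fasta(outdir / "reference.fasta", genome)
    write_bed(outdir / "targets.bed", targets)
    manifest.input_digests["reference.fasta"] = file_digest(outdir / "reference.fasta")

    region_refs = converted_references_for(genome, targets)
    background = converted_references_for(genome)
    write_converted_fasta(outdir / "converted_targets.fasta", region_refs)
    registry = []
    for t in targets:
        registry.extend(
            enumerate_cpgs(genome[t.chrom][t.start : t.end], chrom=t.chrom, offset=t.start)
        )
    write_cpg_registry(outdir / "cpg_registry.tsv", registry)

    panel = None
    if "design" in stages:
        sizes = tuple(config.get("amplicon_sizes", (200,)))
        folds = {int(k): int(v) for k, v in config.get("fold_targets", {200: 2}).items()}
        constraints = DesignConstraints(
            tm_tol=float(config.get("tm_tol", 2.0)),
            n_best=int(config.get("n_best", 5)),
        )
        panel = design_panel(
            region_refs,
            targets,
            background,
            constraints=constraints,
            sizes=sizes,
            fold_targets=folds,
        )
        write_panel(outdir / "panel.tsv", panel)
        profile = calculated_peak_profile(panel)
        pd.DataFrame(
            [{"size_bin": k, "amplicons": v} for k, v in profile.items()]
        ).to_csv(outdir / "peak_profile.tsv", sep="\t", index=False)
        manifest.accounting["panel_pairs"] = len(panel.selected_pairs)
        manifest.accounting["covered_fraction"] = panel.covered_fraction
        logger.info(
            "designed %d pairs, %.1f%% target coverage",
            len(panel.selected_pairs),
            100 * panel.covered_fraction,
        )
    if panel is None:
        raise ValueError("pipeline stages beyond design require the 'design' stage")

    amplicons = build_amplicons(panel, region_refs)
    reads = []
    if "simulate" in stages:
        sites = tuple(s.pos for s in registry if targets[0].contains(s.chrom, s.pos))
        population = preset.population(sites, timepoint=timepoint)
        sim_reads = draw_reads(population, amplicons, region_refs, simcfg)
        reads = [(r.read_id, r.seq) for r in sim_reads]
        write_fastq(outdir / "reads.fastq", reads)
        pd.DataFrame(
            [
                {
                    "read_id": r.read_id,
                    "amplicon": r.amplicon_id,
                    "clone": r.clone,
                    "orientation": r.orientation,
                    "states": "".join(
                        "CT"[1 - r.states[g]] for g in sorted(r.states)
                    ),
                }
                for r in sim_reads
            ]
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        manifest.accounting["simulated_reads"] = len(reads)

    mapped = []
    if "map" in stages:
        if "simulate" not in stages:
            reads_file = config.get("reads_file")
            if not reads_file:
                raise ValueError(
                    "map stage is missing its input: no 'reads.fastq' from a "
                    "simulate stage and no 'reads_file' in the config"
                )
            from .io import read_fastq

            reads = list(read_fastq(reads_file))
        mapped = map_reads(reads, amplicons)
        write_read_assignments(outdir / "assignments.tsv", mapped)
        summary, per_amp = summarize_run(mapped, sample=config.get("sample", "sample"))
        summary.to_csv(outdir / "run_summary.tsv", sep="\t", index=False)
        per_amp.to_csv(outdir / "amplicon_yield.tsv", sep="\t", index=False)
        manifest.accounting["read_statuses"] = (
            summary.iloc[0][["mapped_reads", "no_primer", "low_identity", "ambiguous"]]
            .astype(int)
            .to_dict()
        )

    if "call" in stages:
        sample = config.get("sample", "sample")
        calls = call_sites(mapped, registry, sample)
        calls = annotate_sample_cpg_presence(calls)
        table = export_methylation_table({sample: calls})
        table.to_csv(outdir / "methylation.tsv", sep="\t", index=False)
        fwd = call_sites(mapped, registry, sample, strand="forward", amplicons=amplicons)
        rev = call_sites(mapped, registry, sample, strand="reverse", amplicons=amplicons)
        report = strand_concordance(fwd, rev)
        pd.DataFrame(
            [{"spearman_rho": report.spearman_rho, "n_sites": report.n_sites}]
        ).to_csv(outdir / "strand_concordance.tsv", sep="\t", index=False)
        manifest.accounting["called_sites"] = len(calls)

    if "hepitype" in stages:
        region = targets[0]
        sites_in_region = [s for s in registry if region.contains(s.chrom, s.pos)]
        heps = extract_hepitypes(mapped, region, sites_in_region)
        kept = filter_hepitypes(
            heps, float(config.get("min_frequency", MIN_HEPITYPE_FREQUENCY))
        )
        pd.DataFrame(
            [
                {
                    "pattern": h.pattern,
                    "count": h.count,
                    "frequency": round(h.frequency, 5),
                    "kept": h in kept,
                }
                for h in heps
            ]
        ).to_csv(outdir / "hepitypes.tsv", sep="\t", index=False)
        if len(kept) >= 2:
            replicates = int(config.get("bootstrap", 0))
            if replicates and len(kept) >= 4:
                result = bootstrap_support(kept, replicates=replicates, seed=seed)
            else:
                result = parsimony_tree(kept)
            (outdir / "tree.nwk").write_text(result.newick + "\n")
            manifest.accounting["tree_length"] = result.tree_length
        patterns = extract_patterns(mapped, region, sites_in_region)
        dev = deviation_table(patterns)
        pd.DataFrame(
            {
                "background": ["methylated", "unmethylated"],
                "exact": dev.counts[:, 0],
                "deviating": dev.counts[:, 1],
            }
        ).to_csv(outdir / "deviation_table.tsv", sep="\t", index=False)
        manifest.accounting["deviation_fisher_p"] = dev.fisher_p
        manifest.accounting["spanning_reads"] = len(patterns)

    manifest.outputs = {p.name: file_digest(p) for p in sorted(outdir.iterdir()) if p.is_file()}
    manifest.save(outdir / "manifest.json")
    return manifest
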