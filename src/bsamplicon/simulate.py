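"""Synthetic references, clone mixtures and bisulfite amplicon reads.

The generator emulates the assay end to end: a random genome with
CpG-enriched target islands (GC-rich, as real islands are), clonal mixtures
of phased methylation patterns with per-site maintenance noise, in-silico
bisulfite conversion with a stated efficiency, and single-end reads of
454-like length (mean 204 bp) with optional substitution and homopolymer
errors.  Every read carries a ground-truth record (clone, per-site states,
source amplicon) so downstream estimates can be checked against what was
simulated.

Reads are emitted strand-balanced in orientation (a read is reported from
either end of the product with equal probability) and, when the panel
covers both conversion strands, from both strands' amplicons.  Homopolymer
indels are off by default so exact-identity checks hold; substitution
errors spare primer footprints in the default "clean-primer" mode so that
primer-match tolerance can be exercised separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .conversion import (
    ConvertedReference,
    GenomicInterval,
    build_converted_reference,
    revcomp,
)
from .mapping import Amplicon

__all__ = [
    "ClonePopulation",
    "SimConfig",
    "ScenarioPreset",
    "make_reference",
    "draw_reads",
    "scenario_presets",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ClonePopulation:
    """A mixture of clonal methylation patterns over a region's CpG sites.

    Each clone is (pattern, mixing fraction); a pattern is a {C,T} string
    over ``sites`` or an array of per-site methylation probabilities.
    Maintenance noise is applied per molecule and per site: a methylated
    site is lost with ``loss_rate``, an unmethylated one spuriously gained
    with ``gain_rate``.
    """

    sites: tuple[int, ...]
    clones: tuple[tuple[object, float], ...]
    loss_rate: float = 0.0
    gain_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone fractions sum to {total}, not 1")
        for rate in (self.loss_rate, self.gain_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")

    def _clone_probs(self, idx: int) -> np.ndarray:
        pattern = self.clones[idx][0]
        if isinstance(pattern, str):
            if len(pattern) != len(self.sites):
                raise ValueError("pattern length != number of sites")
            return np.array([1.0 if ch == "C" else 0.0 for ch in pattern])
        arr = np.asarray(pattern, dtype=float)
        if arr.shape != (len(self.sites),):
            raise ValueError("pattern length != number of sites")
        return arr

    def draw_molecule(self, rng: np.random.Generator) -> tuple[int, np.ndarray]:
        """(clone index, per-site 0/1 states) for one DNA molecule."""
        fractions = np.array([f for _, f in self.clones])
        idx = int(rng.choice(len(self.clones), p=fractions))
        probs = self._clone_probs(idx)
        states = (rng.random(len(self.sites)) < probs).astype(np.int8)
        flip_loss = (states == 1) & (rng.random(len(states)) < self.loss_rate)
        flip_gain = (states == 0) & (rng.random(len(states)) < self.gain_rate)
        states[flip_loss] = 0
        states[flip_gain] = 1
        return idx, states


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    read_length_mean: float = 204.0
    read_length_sd: float = 15.0
    depth: int = 200  # reads per amplicon
    conversion_efficiency: float = 0.99
    substitution_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    clean_primers: bool = True
    orientation_balance: bool = True

    def __post_init__(self) -> None:
        for p in (
            self.conversion_efficiency,
            self.substitution_rate,
            self.homopolymer_indel_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def _scrub_cpg(seq: list[str], rng: np.random.Generator) -> None:
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A" if rng.random() < 0.5 else "T"


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(_BASES[rng.choice(4, size=n, p=p)])


def make_reference(
    n_regions: int = 2,
    region_length: int = 600,
    cpgs_per_region: int = 12,
    seed: int = 0,
    island_gc: float = 0.6,
    background_gc: float = 0.4,
    spacer_length: int = 500,
    decoy: bool = False,
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """A synthetic genome with CpG-island targets; deterministic per seed.

    Targets are GC-rich islands with exactly ``cpgs_per_region`` planted
    CpG dinucleotides (the only CpGs inside targets); inter-target spacers
    use the background composition.  With ``decoy=True`` an extra contig
    duplicates the middle of the first target verbatim, planting an
    off-target locus for the in-silico PCR screen and the read-ambiguity
    filter.
    """
    if n_regions < 1 or region_length < 50:
        raise ValueError("need at least one region of >= 50 bp")
    if cpgs_per_region > region_length // 4:
        raise ValueError("CpG density infeasible for the region length")
    rng = np.random.default_rng(seed)
    chrom_parts: list[str] = []
    targets: list[GenomicInterval] = []
    pos = 0
    for r in range(n_regions):
        spacer = _random_seq(spacer_length, background_gc, rng)
        chrom_parts.append("".join(spacer))
        pos += spacer_length
        island = _random_seq(region_length, island_gc, rng)
        _scrub_cpg(island, rng)
        if cpgs_per_region:
            # plant CpGs in a centered island core, leaving CpG-free flanks so
            # that primers (which must avoid CpGs) have somewhere to sit
            width = 4 * cpgs_per_region + 4
            lo = max(5, region_length // 2 - width // 2)
            slots = np.arange(lo, min(lo + width, region_length - 6), 4)
            if len(slots) < cpgs_per_region:
                raise ValueError("CpG density infeasible for the region length")
            chosen = rng.choice(slots, size=cpgs_per_region, replace=False)
            for c in sorted(chosen):
                island[c], island[c + 1] = "C", "G"
        chrom_parts.append("".join(island))
        targets.append(
            GenomicInterval("chr1", pos, pos + region_length, name=f"region{r}")
        )
        pos += region_length
    chrom_parts.append("".join(_random_seq(spacer_length, background_gc, rng)))
    genome = {"chr1": "".join(chrom_parts)}
    if decoy:
        t0 = targets[0]
        chunk = genome["chr1"][t0.start + 50 : t0.start + min(len(t0), 500) - 50]
        pad_l = "".join(_random_seq(300, background_gc, rng))
        pad_r = "".join(_random_seq(300, background_gc, rng))
        genome["decoy1"] = pad_l + chunk + pad_r
    return genome, targets


@dataclass
class SimRead:
    read_id: str
    seq: str
    amplicon_id: str
    clone: int
    states: dict[int, int]  # genomic C position -> 0/1
    orientation: str


def _convert_molecule(
    original: str,
    strand: str,
    cpg_offsets: dict[int, int],
    eff: float,
    rng: np.random.Generator,
) -> str:
    """Bisulfite-convert one molecule of an amplicon's top strand.

    ``cpg_offsets`` maps the informative-base offset to its methylation
    state.  Unmethylated (and non-CpG) cytosines convert with probability
    ``eff``; methylated CpG cytosines are fully protected.
    """
    sensitive, converted_to = ("C", "T") if strand == "forward" else ("G", "A")
    out = list(original)
    for i, b in enumerate(out):
        if b != sensitive:
            continue
        state = cpg_offsets.get(i)
        if state == 1:
            continue  # protected by methylation
        if rng.random() < eff:
            out[i] = converted_to
    return "".join(out)


def _apply_substitutions(
    seq: str, rate: float, protected: tuple[int, int] | None, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        if protected and not (protected[0] <= i < protected[1]):
            continue
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def _apply_homopolymer_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if len(run) >= 3 and rng.random() < rate:
            run = run + run[0] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        i = j
    return "".join(out)


def draw_reads(
    population: ClonePopulation,
    amplicons: list[Amplicon],
    region_refs: list[ConvertedReference],
    config: SimConfig,
) -> list[SimRead]:
    """Simulate ``config.depth`` reads from every amplicon.

    Per read: draw a clone molecule, convert the amplicon's template
    strand, apply sequencing errors, orient (5'->3' from either product
    end with equal probability) and truncate to a sampled read length.
    The returned records carry the full ground truth.
    """
    rng = np.random.default_rng(config.seed)
    ref_by_key = {(r.strand, r.source_interval.chrom): r for r in region_refs}
    reads: list[SimRead] = []
    counter = 0
    for amp in amplicons:
        ref = next(
            (
                r
                for r in region_refs
                if r.strand == amp.strand
                and r.source_interval.chrom == amp.chrom
                and r.source_interval.start <= amp.start
                and amp.end <= r.source_interval.end
            ),
            ref_by_key.get((amp.strand, amp.chrom)),
        )
        if ref is None:
            raise ValueError(f"no reference for amplicon {amp.amplicon_id}")
        lo = amp.start - ref.source_interval.start
        original = ref.original_seq[lo : amp.end - ref.source_interval.start]
        site_offset = {gpos: off for gpos, off in amp.sites}
        for _ in range(config.depth):
            clone, states = population.draw_molecule(rng)
            state_by_pos = dict(zip(population.sites, (int(s) for s in states)))
            cpg_offsets = {
                off: state_by_pos.get(gpos, 0) for gpos, off in amp.sites
            }
            molecule = _convert_molecule(
                original, amp.strand, cpg_offsets, config.conversion_efficiency, rng
            )
            protected = amp.trimmed_span if config.clean_primers else None
            molecule = _apply_substitutions(
                molecule, config.substitution_rate, protected, rng
            )
            molecule = _apply_homopolymer_indels(
                molecule, config.homopolymer_indel_rate, rng
            )
            orientation = "as-is"
            if config.orientation_balance and rng.random() < 0.5:
                molecule = revcomp(molecule)
                orientation = "reverse-complement"
            length = int(round(rng.normal(config.read_length_mean, config.read_length_sd)))
            length = max(30, length)
            seq = molecule[:length]
            reads.append(
                SimRead(
                    read_id=f"read{counter:06d}",
                    seq=seq,
                    amplicon_id=amp.amplicon_id,
                    clone=clone,
                    states={g: state_by_pos.get(g, 0) for g in site_offset},
                    orientation=orientation,
                )
            )
            counter += 1
    return reads


@dataclass(frozen=True)
class ScenarioPreset:
    """A named study condition: clone mixtures per pseudo-timepoint."""

    name: str
    timepoint_clones: tuple[tuple[tuple[str, float], ...], ...]  # symbolic patterns
    loss_rate: float
    gain_rate: float
    config: SimConfig = field(default_factory=SimConfig)

    def population(self, sites: tuple[int, ...], timepoint: int = 0) -> ClonePopulation:
        clones = tuple(
            (("C" if symbol == "M" else "T") * len(sites), frac)
            for symbol, frac in self.timepoint_clones[timepoint]
        )
        return ClonePopulation(
            sites=sites, clones=clones, loss_rate=self.loss_rate, gain_rate=self.gain_rate
        )


def scenario_presets() -> dict[str, ScenarioPreset]:
    """The three study conditions the analyses are exercised on.

    "imprinted": a 50/50 mixture of a fully methylated and a fully
    unmethylated epiallele with asymmetric maintenance failure (loss on the
    methylated allele exceeds spurious gain on the unmethylated one), as at
    an imprinted locus.  "demethylating": an all-methylated ancestor losing
    ground to an unmethylated clone between two pseudo-timepoints, as for a
    tumor-demethylated locus.  "methylating": the mirror image, progressive
    methylation of an unmethylated ancestor.
    """
    return {
        "imprinted": ScenarioPreset(
            name="imprinted",
            timepoint_clones=((("M", 0.5), ("U", 0.5)),),
            loss_rate=0.05,
            gain_rate=0.005,
        ),
        "demethylating": ScenarioPreset(
            name="demethylating",
            timepoint_clones=(
                (("M", 0.8), ("U", 0.2)),
                (("M", 0.35), ("U", 0.65)),
            ),
            loss_rate=0.01,
            gain_rate=0.01,
        ),
        "methylating": ScenarioPreset(
            name="methylating",
            timepoint_clones=(
                (("U", 0.8), ("M", 0.2)),
                (("U", 0.3), ("M", 0.7)),
            ),
            loss_rate=0.01,
            gain_rate=0.01,
        ),
    }


def converted_references_for(
    genome: dict[str, str], targets: list[GenomicInterval] | None = None
) -> list[ConvertedReference]:
    """Both conversion strands for each target (or each whole contig)."""
    refs = []
    if targets:
        for t in targets:
            seq = genome[t.chrom][t.start : t.end]
            for strand in ("forward", "reverse"):
                refs.append(build_converted_reference(t, seq, strand))
    else:
        for chrom, seq in genome.items():
            iv = GenomicInterval(chrom, 0, len(seq), name=chrom)
            for strand in ("forward", "reverse"):
                refs.append(build_converted_reference(iv, seq, strand))
    return refs
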