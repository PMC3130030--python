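# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `bsamplicon`, in the order of the pipeline.

## Coordinates and conversion model

All coordinates are 0-based half-open internally; every user-facing table
prints 1-based inclusive positions (genome-browser convention). Bisulfite
conversion is modelled per strand on the reference: the forward strand
converts C→T, the reverse strand (expressed in forward coordinates) G→A.
CpG context is decided on the original, unconverted sequence only — sample
methylation never changes the reference. The ambiguity-coded amplicon
writes Y at CpG cytosines (forward) and R at CpG guanines (reverse), so a
single reference string matches any methylation state. `N` bases pass
through conversion unchanged; candidate primers containing `N` are
discarded. Non-CpG (CHG/CHH) contexts are out of scope.

Variant handling is deliberately minimal: single-nucleotide substitutions
that create or destroy a CpG mark the site polymorphic, and per-sample
presence is derived from genotypes (present on ≥ 1 allele). Indels are
ignored for CpG bookkeeping.

## Primer design

Segmentation: each target is tiled into windows of 200, 300 and 400 bp at
5 bp spacing; a window must fit entirely inside the target.

Melting temperature: nearest-neighbor thermodynamics with the unified
parameter set, at 50 mM monovalent cation, 50 nM oligo, no divalent
correction (computed via Biopython's `Tm_NN`; an independent hand-rolled
NN-table implementation serves as the test oracle). These conditions are a
deliberate, documented choice — the design constraints only need a
deterministic, monotone Tm model, not agreement with any particular
instrument.

Hard constraints per primer: length 18–25 (optimum 20), Tm 56 ± 2 °C
(± 6 °C in relaxed mode), GC 20–90 %; per pair: ΔTm ≤ 2 °C and product
size within segment size ± 50 bp (clipped to the segment, which confines
left primers to the first 50 bp and right primers to the last 50 bp of a
window). Pair penalty = Σ|Tm − 56| + 0.5·Σ|len − 20| + |ΔTm|; the five
lowest-penalty pairs per segment are kept. The penalty is intentionally
simple: monotone in each stated optimality criterion, with fixed weights.

Masking removes any pair whose primer footprint covers a variant with
MAF > 0.1 or any CpG dinucleotide (CpG-level masking is a conservative
superset of island-level masking; islands are not redefined here).

In-silico PCR: binding requires an exact match of the 15 3′-terminal bases
and ≤ 2 mismatches over the whole primer; any convergent placement of the
pair's primers (in either role) within 2 kb on either converted strand of
the genome, other than the intended product, disqualifies the pair. The
word-match semantics were chosen to be brute-forceable, and the tests audit
the screen with a full placement scan.

Selection: after exact-duplicate removal (key: left+right sequence),
candidates are taken per size class in order of increasing mean primer GC
(ties lexicographic by primer sequence — this makes panels deterministic),
selecting a pair whenever any base of its product is below the class's
fold target (2× for 300 bp, 3× for 200/400 bp). Uncovered intervals are
padded to the smallest amplicon size and re-designed with the Tm window
relaxed to 56 ± 6 °C; such pairs are tagged `relaxed`. The calculated peak
profile is a plain histogram of product sizes assuming equimolar
amplification.

## Read processing

Reads are single-end and unoriented. The primer library holds, for every
amplicon, the left primer and the reverse complement of the right primer
(as-is orientation) plus their reverse complements (flipped orientation);
probes are matched as infix patterns with unit-cost edit distance ≤ 2
(edlib's bit-parallel algorithm; a full-DP oracle backs it in tests). The
best hit fixes orientation (ties prefer as-is) and the candidate set.

Alignment is read-global / reference-local dynamic programming against the
ambiguity-coded amplicon: match +1, mismatch −1, gap −2, free reference
end gaps. Matching bases count exact or ambiguity-compatible columns
(Y≡C/T, R≡G/A) — otherwise methylation itself would penalise identity.
Identity = matching / all aligned columns, gap columns included, read
overhang beyond the reference counted. Thresholds: ≥ 50 matching bases and
identity strictly > 0.95. Ties among amplicons within one target region
resolve to the lowest amplicon id; a tie or an independently passing
alignment in a *different* region makes the read `ambiguous`. Statuses
partition the input exactly: no_primer + low_identity + ambiguous +
mapped = total. Primer footprints are trimmed before scoring; CpGs under a
primer are never scored.

Quality scores, paired-end logic and flowgram-aware realignment are out of
scope.

## Methylation calling

Per site and sample, methylation = n_C / (n_C + n_T) (reverse-strand
amplicons report G/A, normalised to C/T by the mapper). The proportion
reading — rather than a literal C:T odds ratio — is forced by percent
semantics in [0, 100]. Bases other than C/T at a site count toward depth
but never toward the level (sequencing-error tolerance without bias);
alignment gaps contribute nothing. Sites with < 20 reads are flagged
`low_coverage`, not suppressed; no reads exports "-", genotype-removed
sites "NA". Cross-strand and cross-method agreement use Spearman's ρ with
average ranks for ties (ties matter at saturated 0 %/100 % sites); fewer
than 3 shared sites yields an undefined report.

## Hepitypes, trees and the deviating-site test

A read contributes a hepitype only if its trimmed alignment shows C or T
at *every* CpG of the region; frequencies are relative to all
pattern-complete spanning reads, and are not renormalised after the strict
> 1 % filter (tree and report semantics stay in observed-read fractions).

Parsimony: Fitch length over binary {C,T} characters on unrooted binary
topologies. Search is exhaustive over all (2n−5)!! topologies for ≤ 9
leaves; above that, beam-search stepwise addition (beam 8, leaves added by
descending frequency, ties lexicographic) followed by first-improvement
SPR refinement of every beam entry. All tie-breaks follow a documented
enumeration order, so results are deterministic for a given input.
Bootstrap (default 1000 replicates, single seeded RNG stream) resamples
CpG columns with replacement, rebuilds the tree with the same search
settings, and reports per-internal-edge bipartition frequencies. Branch
lengths are per-edge change counts from one (of possibly many)
most-parsimonious ancestral assignments and are not to scale.

Deviating-site test: each spanning read is assigned to the all-C or all-T
background by Hamming proximity (exact ties are excluded and counted — the
assignment rule is the package's choice, as is counting *reads* rather
than distinct patterns; a flag switches to pattern-level counting). The
2×2 table (background × {exact match, ≥ 1 deviation}) is tested two-sided
with Fisher's exact test (hypergeometric tail sum; a zero margin returns
p = 1 by convention). Joint SNP+methylation hepitype strings and
likelihood/distance tree methods are not implemented.

## Simulator

The generator emulates the assay's study conditions: GC-rich CpG-island
targets (island GC 0.60, background 0.40 — islands are GC-rich in real
genomes) with an exact number of CpGs planted in a centered core, leaving
CpG-free flanks where primers can sit, as in real island assays; an
optional decoy contig duplicates the middle of the first target to plant
an off-target locus. Clone mixtures are lists of (pattern, fraction) —
patterns may also be per-site Bernoulli probabilities — with per-molecule
maintenance noise: a methylated site lost with `loss_rate`, an
unmethylated one gained with `gain_rate`. Conversion failures leave
unmethylated cytosines (CpG or not) unconverted with probability
1 − efficiency (default efficiency 0.99). Reads have Gaussian lengths
(mean 204 bp, sd 15, floor 30 — the read-length scale of long-read
amplicon chemistry), are emitted from either product end with equal
probability, and carry full ground truth. Substitution errors spare primer
footprints in the default clean-primer mode so primer-match tolerance can
be tested in isolation; homopolymer indels are off by default so
exact-identity assertions hold. Droplet/emulsion statistics and flowgrams
are not modelled.

What passing simulation tests do not show: real libraries add PCR
amplification bias, chimeras, quality-dependent errors, incomplete
conversion correlated along molecules, and mapping ambiguity from genomic
repeats — none of which the generator emulates. Results on synthetic data
bound algorithmic correctness, not assay performance.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use one-island genomes
(260–800 bp targets, 8–100 CpGs), panels of ~5–15 pairs, and depths of
25–500 reads per amplicon — small enough to audit with brute-force oracles
(full placement scans, full DP edit distance, exhaustive topology
enumeration, exact hypergeometric sums) while exercising every pipeline
stage. Every stochastic step takes an explicit seed; identical
configurations produce byte-identical outputs, and the acceptance script
derives all of its RNG streams from the single `--seed` argument.
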