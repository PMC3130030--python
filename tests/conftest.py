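"""Shared fixtures: a small designed panel on a seeded synthetic genome.

Everything is generated programmatically; fixture scope is session-wide so
the (comparatively expensive) panel design runs once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from bsamplicon.conversion import enumerate_cpgs
from bsamplicon.mapping import build_amplicons
from bsamplicon.primers import design_panel
from bsamplicon.simulate import converted_references_for, make_reference


@dataclass
class DesignedFixture:
    genome: dict
    targets: list
    refs: list
    background: list
    panel: object
    amplicons: list
    registry: list


@pytest.fixture(scope="session")
def designed() -> DesignedFixture:
    """One 260 bp CpG-island target, designed 200 bp panel, 8 CpG sites."""
    genome, targets = make_reference(
        n_regions=1, region_length=260, cpgs_per_region=8, seed=1
    )
    refs = converted_references_for(genome, targets)
    background = converted_references_for(genome)
    panel = design_panel(refs, targets, background, sizes=(200,), fold_targets={200: 2})
    amplicons = build_amplicons(panel, refs)
    registry = []
    for t in targets:
        registry.extend(
            enumerate_cpgs(genome[t.chrom][t.start : t.end], chrom=t.chrom, offset=t.start)
        )
    assert amplicons, "fixture panel must contain amplicons"
    return DesignedFixture(
        genome=genome,
        targets=targets,
        refs=refs,
        background=background,
        panel=panel,
        amplicons=amplicons,
        registry=registry,
    )
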