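"""Shared fixtures: a small simulated cohort and transcript factories."""

from __future__ import annotations

import numpy as np
import pytest

from varkat import splicing
from varkat.simulate import CohortSpec, simulate_cohort
from varkat.variants import annotate_population_afs

BASES = list("ACGT")


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated two-family cohort (1,000 background variants, fixed seed),
    with population AFs annotated in place."""
    spec = CohortSpec(n_background_variants=1000, seed=11)
    records, ped, extra = simulate_cohort(spec)
    annotate_population_afs(records, extra["af_table"])
    return spec, records, ped, extra


def make_transcript(
    exon_lengths: list[int],
    rng: np.random.Generator | None = None,
    strand: str = "+",
    intron_length: int = 500,
    with_cds: bool = True,
) -> splicing.TranscriptModel:
    """Transcript with the given coding-exon lengths; random CDS starting
    with ATG and ending with a stop, no internal stops in frame."""
    total = sum(exon_lengths)
    assert total % 3 == 0
    rng = rng or np.random.default_rng(0)
    exons = []
    g = 10_000
    lengths = exon_lengths if strand == "+" else exon_lengths[::-1]
    for L in lengths:
        exons.append(splicing.Exon(g, g + L - 1))
        g += L + intron_length
    if strand == "-":
        exons = exons[::-1]
    cds = None
    if with_cds:
        # build codon-wise to avoid internal stops
        stops = {"TAA", "TAG", "TGA"}
        codons = ["ATG"]
        while len(codons) < total // 3 - 1:
            c = "".join(rng.choice(BASES, 3))
            if c not in stops:
                codons.append(c)
        codons.append("TAA")
        cds = "".join(codons)
    return splicing.TranscriptModel(
        gene_id="GENE_T", strand=strand, exons=exons, cds_sequence=cds
    )


@pytest.fixture
def abcc9_like_transcript():
    """Transcript whose 8th exon occupies cDNA positions 1165-1320
    (156 nt), mirroring the geometry of the studied splice-donor variant."""
    lengths = [200, 300, 150, 180, 120, 100, 114, 156, 300, 1998]
    assert sum(lengths[:7]) == 1164
    return make_transcript(lengths)
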