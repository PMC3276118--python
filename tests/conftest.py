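"""Shared fixtures: simulated genus scenarios and hand-built toy genomes."""

from __future__ import annotations

import numpy as np
import pytest

from ssgenus.model import GeneModel, GenomeAnnotation, SPECIES
from ssgenus.orthology import detect_orthogroups
from ssgenus.simulate import EvolutionParams, simulate_genus


@pytest.fixture(scope="session")
def default_genus():
    """The standard study scenario (500 families, WGD retention 0.10,
    total loss 0.05 per unit branch, 2+4 translocations, seed 42)."""
    return simulate_genus(EvolutionParams())


@pytest.fixture(scope="session")
def nogap_genus():
    """Same scenario with assembly gaps disabled (loss-walk conditions)."""
    return simulate_genus(EvolutionParams(gap_rate=0.0))


@pytest.fixture(scope="session")
def default_orthogroups(default_genus):
    return detect_orthogroups(default_genus.genomes, default_genus.family_map)


@pytest.fixture(scope="session")
def nogap_orthogroups(nogap_genus):
    return detect_orthogroups(nogap_genus.genomes, nogap_genus.family_map)


def make_collinear_genomes(
    n_families: int = 15,
    spacing: int = 1000,
    length: int = 600,
    deletions: dict[str, list[int]] | None = None,
    duplicates: dict[str, list[int]] | None = None,
    extra: dict[str, list[GeneModel]] | None = None,
    scaffold: str = "chr1",
):
    """Five perfectly collinear single-scaffold genomes plus edits.

    ``deletions[sp]`` lists family indices absent in that species;
    ``duplicates[sp]`` lists family indices with a second (tandem) copy.
    Families are named F00, F01, ...  Returns (genomes, family_map).
    """
    deletions = deletions or {}
    duplicates = duplicates or {}
    extra = extra or {}
    fams = [f"F{i:02d}" for i in range(n_families)]
    genomes: dict[str, GenomeAnnotation] = {}
    family_map: dict[str, str] = {}
    for sp in SPECIES:
        genome = GenomeAnnotation(species=sp)
        pos = 0
        for i, fam in enumerate(fams):
            if i in deletions.get(sp, []):
                continue
            copies = 2 if i in duplicates.get(sp, []) else 1
            for c in range(copies):
                gid = f"{sp}_{fam}" + (f"_t{c}" if copies > 1 else "")
                genome.add_gene(
                    GeneModel(id=gid, species=sp, scaffold=scaffold, start=pos,
                              end=pos + length, family=fam)
                )
                family_map[gid] = fam
                pos += spacing
        for g in extra.get(sp, []):
            genome.add_gene(g)
        genome.sort()
        genome.validate()
        genomes[sp] = genome
    return genomes, family_map
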