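"""Core domain types for annotated post-WGD yeast genomes.

The genus is fixed: five *Saccharomyces sensu stricto* species descended
from a whole-genome-duplicated ancestor.  All per-species tables and
pattern strings use the canonical display order
``Scer : Spar : Smik : Skud : Sbay``.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and
from the 1-based inclusive convention of the format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

#: Canonical species codes in fixed display order (used by every
#: presence/retention pattern string).
SPECIES: tuple[str, ...] = ("Scer", "Spar", "Smik", "Skud", "Sbay")

#: Tie-break priority when several species could found an orthogroup.
SPECIES_PRIORITY: dict[str, int] = {s: i for i, s in enumerate(SPECIES)}

GENE_STATUSES = ("intact", "pseudogene", "dubious")


class IntegrityError(ValueError):
    """Raised when an annotation violates a structural invariant."""


@dataclass
class GeneModel:
    """A single annotated gene model (or pseudogene) on a scaffold.

    ``n_disruptions`` counts the reading-frame disruptions (frameshifts
    and premature stops) required to reconstitute a full-length gene; a
    model with one or more disruptions is a pseudogene.
    """

    id: str
    species: str
    scaffold: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"
    status: str = "intact"
    family: Optional[str] = None
    n_disruptions: int = 0
    cds_length: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise IntegrityError(
                f"gene {self.id}: start {self.start} must precede end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise IntegrityError(f"gene {self.id}: bad strand {self.strand!r}")
        if self.status not in GENE_STATUSES:
            raise IntegrityError(f"gene {self.id}: bad status {self.status!r}")
        if self.n_disruptions < 0:
            raise IntegrityError(f"gene {self.id}: negative disruption count")
        if self.cds_length > self.end - self.start:
            raise IntegrityError(
                f"gene {self.id}: cds_length {self.cds_length} exceeds span"
            )
        if self.n_disruptions > 0 and self.status == "intact":
            # disrupted reading frame implies pseudogene
            self.status = "pseudogene"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_pseudogene(self) -> bool:
        return self.status == "pseudogene"


@dataclass
class ScaffoldAnnotation:
    """Ordered gene models plus assembly-gap (N-run) intervals on one scaffold."""

    id: str
    genes: list[GeneModel] = field(default_factory=list)
    gaps: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open

    def sort(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end, g.id))
        self.gaps.sort()

    def validate(self) -> None:
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise IntegrityError(f"scaffold {self.id}: genes not sorted by start")
        prev_end = -1
        for a, b in sorted(self.gaps):
            if a >= b:
                raise IntegrityError(f"scaffold {self.id}: empty gap interval")
            if a < prev_end:
                raise IntegrityError(f"scaffold {self.id}: overlapping gaps")
            prev_end = b

    def gap_in(self, start: int, end: int) -> bool:
        """True if any assembly gap overlaps [start, end)."""
        return any(a < end and start < b for a, b in self.gaps)


@dataclass
class GenomeAnnotation:
    """One species' full annotation: scaffolds, genes, optional codon tables."""

    species: str
    scaffolds: dict[str, ScaffoldAnnotation] = field(default_factory=dict)
    codon_usage: Optional[dict[str, float]] = None

    def add_gene(self, gene: GeneModel) -> None:
        sc = self.scaffolds.setdefault(gene.scaffold, ScaffoldAnnotation(gene.scaffold))
        sc.genes.append(gene)

    def genes(self) -> Iterator[GeneModel]:
        for sid in sorted(self.scaffolds):
            yield from self.scaffolds[sid].genes

    def gene_index(self) -> dict[str, GeneModel]:
        idx: dict[str, GeneModel] = {}
        for g in self.genes():
            if g.id in idx:
                raise IntegrityError(f"duplicate gene id {g.id} in {self.species}")
            idx[g.id] = g
        return idx

    def sort(self) -> None:
        for sc in self.scaffolds.values():
            sc.sort()

    def validate(self) -> None:
        self.gene_index()  # raises on duplicate ids
        for sc in self.scaffolds.values():
            sc.validate()

    def n_genes(self) -> int:
        return sum(len(sc.genes) for sc in self.scaffolds.values())


@dataclass
class AncestralOrder:
    """The ancestral (pre-duplication) gene order with post-WGD track labels.

    ``families`` lists ancestral loci (YGOB-style ``Anc_N.M`` ids) in
    chromosomal order; ``track`` maps each family to the duplicated track
    ({'A', 'B'}) on which its surviving copy resides after the genome
    duplication was resolved.  ``chromosome`` groups loci into ancestral
    chromosomes so neighbourhoods never span a chromosome boundary.
    """

    families: list[str]
    track: dict[str, str]
    chromosome: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.families)) != len(self.families):
            raise IntegrityError("ancestral order: duplicate family ids")
        bad = {t for t in self.track.values() if t not in ("A", "B")}
        if bad:
            raise IntegrityError(f"ancestral order: bad track labels {bad}")
        self._pos = {f: i for i, f in enumerate(self.families)}

    def position(self, family: str) -> int:
        return self._pos[family]

    def track_neighborhood(self, family: str, track: str, radius: int = 5) -> set[str]:
        """Up to ``radius`` same-track families on each side of ``family``.

        The focal family itself is excluded; the walk never crosses an
        ancestral-chromosome boundary.
        """
        pos = self._pos[family]
        chrom = self.chromosome.get(family, 0)
        out: set[str] = set()
        for step in (-1, 1):
            found = 0
            i = pos + step
            while 0 <= i < len(self.families) and found < radius:
                f = self.families[i]
                if self.chromosome.get(f, 0) != chrom:
                    break
                if self.track[f] == track:
                    out.add(f)
                    found += 1
                i += step
        return out


@dataclass
class RateRecord:
    """Per-gene substitution rates: dN, dS and their ratio ω = dN/dS."""

    id: str
    dN: float
    dS: float

    def __post_init__(self) -> None:
        if self.dN < 0 or self.dS < 0:
            raise IntegrityError(f"rates for {self.id}: dN and dS must be >= 0")

    @property
    def omega(self) -> Optional[float]:
        """dN/dS, defined only when dS > 0."""
        if self.dS > 0:
            return self.dN / self.dS
        return None


def window_families(
    scaffold: ScaffoldAnnotation,
    gene_pos: int,
    radius: int = 5,
    exclude_family: Optional[str] = None,
) -> set[str]:
    """Distinct family ids in a window of ``radius`` genes on each side.

    ``gene_pos`` is the index of the focal gene in the scaffold's ordered
    gene list.  The focal gene is excluded, as is ``exclude_family``
    wherever it appears in the window (the shared family of a query and
    its candidate orthogroup carries no synteny information).  Pseudogenes
    contribute their family: a disabled reading frame still occupies its
    ancestral slot.  Strand is ignored throughout.
    """
    lo = max(0, gene_pos - radius)
    hi = min(len(scaffold.genes), gene_pos + radius + 1)
    fams = {
        g.family
        for i, g in enumerate(scaffold.genes[lo:hi], start=lo)
        if i != gene_pos and g.family is not None
    }
    fams.discard(exclude_family)
    return fams
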