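"""Candidate gene gains and losses, WGD duplicate pairs and rate filters.

The loss walk follows the reference genome (S. cerevisiae by default)
between consecutive complete orthogroups, comparing the intervening gene
content of all five species.  Intervals are excluded when any species
has an assembly gap inside them or more than three intervening features
- restrictive rules that trade recall for a clean candidate list.
Presence and retention patterns are strings in the canonical species
order ``Scer:Spar:Smik:Skud:Sbay``; a species carrying a pseudogenized
copy is marked ``/ψ``, and the leading count is of intact copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .model import (
    SPECIES,
    AncestralOrder,
    GeneModel,
    GenomeAnnotation,
    RateRecord,
    window_families,
)
from .orthology import AssignmentConfig, Orthogroup, _GenePos, _interval_genes, synteny_statistic

MAX_INTERVENING = 3


@dataclass
class PresencePattern:
    """Per-species intact copy counts with pseudogene marks."""

    counts: tuple[int, ...]
    psi: tuple[bool, ...]

    def __str__(self) -> str:
        return ":".join(
            f"{c}/ψ" if p else str(c) for c, p in zip(self.counts, self.psi)
        )

    @property
    def absent_species(self) -> tuple[str, ...]:
        """Species with no intact copy (deleted or pseudogenized only)."""
        return tuple(sp for sp, c in zip(SPECIES, self.counts) if c == 0)


@dataclass
class LossCandidate:
    family: str
    interval: tuple[str, str]  # flanking orthogroup ids
    pattern: PresencePattern
    evidence: str  # absent | pseudogene
    klass: str = "unclassified"  # lineage_restricted | widespread | duplicate_loss


@dataclass
class WgdPair:
    """A family's surviving WGD duplicates across the genus."""

    family: str
    track_members: dict[str, dict[str, str]]  # species -> {track: gene id}
    pattern: "PresencePattern"
    pair_species: tuple[str, ...]  # species where both tracks are occupied

    def retention_string(self) -> str:
        return str(self.pattern)


def walk_losses(
    orthogroups: list[Orthogroup],
    genomes: dict[str, GenomeAnnotation],
    family_map: Optional[dict[str, str]] = None,
    reference: str = "Scer",
    max_intervening: int = MAX_INTERVENING,
) -> list[LossCandidate]:
    """Walk reference intervals between complete orthogroups for losses.

    For each adjacent pair of complete orthogroups on a reference
    scaffold, collect the genes between the flanking members in every
    species.  The interval is skipped when the flanks land on different
    scaffolds in some species (translocation breakpoints), when any
    species shows an assembly gap inside it, or when any species has
    more than ``max_intervening`` intervening features.  Each family
    present in the surviving intervals but lacking an intact copy in at
    least one species yields one candidate with its presence pattern.
    """
    family_map = family_map or {}
    pos = _GenePos(genomes)
    pairs = _adjacent_complete(orthogroups, reference, pos)
    out: list[LossCandidate] = []
    for left, right in pairs:
        spans: dict[str, list[GeneModel]] = {}
        excluded = False
        for sp in SPECIES:
            span = _interval_genes(left, right, sp, pos)
            if span is None:
                excluded = True
                break
            if len(span) > max_intervening:
                excluded = True
                break
            if _interval_has_gap(left, right, sp, pos):
                excluded = True
                break
            spans[sp] = span
        if excluded:
            continue
        families: set[str] = set()
        for sp, span in spans.items():
            for g in span:
                fam = family_map.get(g.id, g.family)
                if fam is not None:
                    families.add(fam)
        for fam in sorted(families):
            counts, psi = [], []
            for sp in SPECIES:
                members = [
                    g for g in spans[sp] if family_map.get(g.id, g.family) == fam
                ]
                counts.append(sum(1 for g in members if not g.is_pseudogene))
                psi.append(any(g.is_pseudogene for g in members))
            pattern = PresencePattern(tuple(counts), tuple(psi))
            absent = pattern.absent_species
            if not absent or len(absent) == len(SPECIES):
                continue  # present everywhere, or nowhere visible
            evidence = (
                "pseudogene"
                if any(psi[SPECIES.index(sp)] for sp in absent)
                else "absent"
            )
            out.append(
                LossCandidate(
                    family=fam,
                    interval=(left.id, right.id),
                    pattern=pattern,
                    evidence=evidence,
                )
            )
    return out


def _adjacent_complete(orthogroups, reference, pos):
    members = []
    for og in orthogroups:
        if og.status == "complete" and reference in og.members:
            sc, i, _ = pos.by_id[og.members[reference]]
            members.append((sc.id, i, og))
    members.sort(key=lambda t: (t[0], t[1]))
    return [
        (og1, og2)
        for (s1, _, og1), (s2, _, og2) in zip(members, members[1:])
        if s1 == s2
    ]


def _interval_has_gap(left, right, species, pos) -> bool:
    sc1, i1, g1 = pos.by_id[left.members[species]]
    sc2, i2, g2 = pos.by_id[right.members[species]]
    if sc1.id != sc2.id:
        return True
    lo = min(g1.end, g2.end)
    hi = max(g1.start, g2.start)
    return lo < hi and sc1.gap_in(lo, hi)


def classify_losses(
    candidates: list[LossCandidate],
    wgd_pairs: Iterable[WgdPair] = (),
) -> list[LossCandidate]:
    """Assign loss classes; duplicate-loss takes precedence.

    A candidate whose family retains a WGD duplicate pair in some
    species is a ``duplicate_loss``; otherwise 1-2 affected species make
    it ``lineage_restricted`` and more make it ``widespread``.
    """
    paired_families = {p.family for p in wgd_pairs if p.pair_species}
    for c in candidates:
        n_absent = len(c.pattern.absent_species)
        if c.family in paired_families:
            c.klass = "duplicate_loss"
        elif n_absent <= 2:
            c.klass = "lineage_restricted"
        else:
            c.klass = "widespread"
    return candidates


def detect_wgd_pairs(
    genomes: dict[str, GenomeAnnotation],
    family_map: dict[str, str],
    ancestral_order: AncestralOrder,
    config: Optional[AssignmentConfig] = None,
) -> tuple[list[WgdPair], list[str]]:
    """Detect surviving whole-genome-duplication duplicate pairs.

    For every family with two intact copies in a genome, each copy's
    gene-order window is scored against the ancestral track-A and
    track-B neighbourhoods of the family's locus.  A pair is called in
    that species iff the two copies map to *different* tracks, each with
    synteny support >= ``s_min``; ties (both copies best on one track)
    yield no call.  Families with more than two copies in a genome are
    returned separately for manual review, never auto-paired.

    Returns ``(pairs, flagged_families)`` where ``pairs`` has one entry
    per family observed in >= 1 species with both tracks occupied or a
    ψ-marked remnant, carrying the genus-wide retention pattern.
    """
    config = config or AssignmentConfig()
    pos = _GenePos(genomes)
    by_sp_family: dict[str, dict[str, list[GeneModel]]] = {sp: {} for sp in SPECIES}
    psi_by_sp_family: dict[str, dict[str, int]] = {sp: {} for sp in SPECIES}
    for sp, genome in genomes.items():
        for g in genome.genes():
            fam = family_map.get(g.id, g.family)
            if fam is None:
                continue
            if g.is_pseudogene:
                psi_by_sp_family[sp][fam] = psi_by_sp_family[sp].get(fam, 0) + 1
            else:
                by_sp_family[sp].setdefault(fam, []).append(g)

    flagged: set[str] = set()
    track_members: dict[str, dict[str, dict[str, str]]] = {}
    for sp in SPECIES:
        for fam, genes in sorted(by_sp_family[sp].items()):
            if len(genes) > 2:
                flagged.add(fam)
                continue
            if fam not in ancestral_order.track:
                continue
            if len(genes) < 2 and fam not in track_members:
                continue  # track mapping only needed once a pair exists somewhere
            assignments = {}
            for g in sorted(genes, key=lambda g: g.id):
                best = _best_track(g, fam, ancestral_order, pos, config)
                if best is not None:
                    assignments[g.id] = best
            if len(genes) == 2:
                tracks = [assignments.get(g.id) for g in sorted(genes, key=lambda g: g.id)]
                if None in tracks or tracks[0] == tracks[1]:
                    continue  # unsupported or same-track: no call
            for gid, (track, _score) in assignments.items():
                track_members.setdefault(fam, {}).setdefault(sp, {})[track] = gid

    # second pass so single-copy species of paired families get track labels
    for fam in sorted(track_members):
        for sp in SPECIES:
            if sp in track_members[fam]:
                continue
            genes = by_sp_family[sp].get(fam, [])
            if len(genes) == 1:
                best = _best_track(genes[0], fam, ancestral_order, pos, config)
                if best is not None:
                    track_members[fam][sp] = {best[0]: genes[0].id}

    pairs: list[WgdPair] = []
    for fam in sorted(track_members):
        per_sp = track_members[fam]
        pair_species = tuple(
            sp for sp in SPECIES if len(per_sp.get(sp, {})) == 2
        )
        if not pair_species:
            continue
        counts = tuple(len(by_sp_family[sp].get(fam, [])) for sp in SPECIES)
        psi = tuple(psi_by_sp_family[sp].get(fam, 0) > 0 for sp in SPECIES)
        pairs.append(
            WgdPair(
                family=fam,
                track_members=per_sp,
                pattern=PresencePattern(counts, psi),
                pair_species=pair_species,
            )
        )
    return pairs, sorted(flagged)


def _best_track(gene, family, order, pos, config) -> Optional[tuple[str, float]]:
    sc, i, _ = pos.by_id[gene.id]
    qwin = window_families(sc, i, radius=config.window_radius, exclude_family=family)
    best: Optional[tuple[str, float]] = None
    scores = {}
    for track in "AB":
        twin = order.track_neighborhood(family, track, radius=config.window_radius)
        if not twin:
            continue
        s = synteny_statistic(qwin, twin, config.n_universe).s
        scores[track] = s
    if not scores:
        return None
    track = max(sorted(scores), key=lambda t: scores[t])
    if scores[track] < config.s_min:
        return None
    if len(scores) > 1 and scores["A"] == scores["B"]:
        return None  # exact tie: ambiguous
    return track, scores[track]


def length_outliers(
    orthogroups: list[Orthogroup],
    genomes: dict[str, GenomeAnnotation],
    top_k: int = 200,
) -> list[tuple[str, float]]:
    """Orthogroups ranked by coefficient of variation of member length.

    CV = sample standard deviation (n-1) of member CDS lengths divided
    by the mean; severe truncations in one species surface at the top.
    Only non-rejected groups with >= 2 members are ranked.
    """
    idx = {}
    for genome in genomes.values():
        for g in genome.genes():
            idx[g.id] = g
    ranked = []
    for og in orthogroups:
        if og.status == "rejected" or len(og.members) < 2:
            continue
        lengths = []
        for gid in og.members.values():
            g = idx[gid]
            lengths.append(g.cds_length if g.cds_length else g.length)
        n = len(lengths)
        mean = sum(lengths) / n
        if mean == 0:
            continue
        var = sum((x - mean) ** 2 for x in lengths) / (n - 1)
        ranked.append((og.id, math.sqrt(var) / mean))
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked[:top_k]


def filter_rate_records(
    records: Iterable[RateRecord], mode: str = "strict"
) -> list[RateRecord]:
    """Drop unreliable rate records before selection screens.

    ``strict`` removes genes with dS = 0 (ω undefined and likelihood
    surfaces degenerate).  ``low_dS`` additionally removes genes whose
    dS falls more than two standard deviations below the mean of the
    remaining set - cases where a high ω is driven by an abnormally
    small denominator.  The mean and SD are computed after the dS = 0
    removal, with the sample (n-1) standard deviation.
    """
    if mode not in ("strict", "low_dS"):
        raise ValueError(f"unknown filter mode {mode!r}")
    kept = [r for r in records if r.dS > 0]
    if mode == "strict" or len(kept) < 2:
        return kept
    n = len(kept)
    mean = sum(r.dS for r in kept) / n
    sd = math.sqrt(sum((r.dS - mean) ** 2 for r in kept) / (n - 1))
    floor = mean - 2 * sd
    return [r for r in kept if r.dS >= floor]


def flag_disrupted_genes(
    genomes: dict[str, GenomeAnnotation], threshold: int = 3
) -> list[GeneModel]:
    """Genes with >= threshold reading-frame disruptions, most first."""
    hits = [
        g
        for genome in genomes.values()
        for g in genome.genes()
        if g.n_disruptions >= threshold
    ]
    hits.sort(key=lambda g: (-g.n_disruptions, g.id))
    return hits
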