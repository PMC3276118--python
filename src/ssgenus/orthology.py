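"""Two-step homology + synteny ortholog detection.

Genes are first grouped into ancestral families (the supplied family
table stands in for profile-HMM best matches).  Within each family the
species with most representatives founds one orthogroup per copy; genes
from the other species are then assigned to orthogroups when their
window-synteny support exceeds a floor and clearly beats the runner-up
orthogroup, iterating until steady state.  Completed five-member groups
are removed from the pool between passes.

The synteny statistic for a query gene against an orthogroup compares a
ten-gene window (radius 5 on each side, truncated at scaffold ends)
around the query with one around the orthogroup's founder member: with
``a`` and ``b`` distinct families in the two windows, ``k`` of them
shared, and a family universe of ``N`` genes, the score is

    S = -log10( P_hyper ),   P_hyper = sum_{i=k}^{min(a,b)} C(a,i) C(N-a, b-i) / C(N,b)

the upper-tail hypergeometric probability of sharing at least ``k``
families by chance.  ``N`` defaults to 4704, the number of
distinguishable ancestral-family models.  The probability is evaluated
in exact integer arithmetic (log10 of big-integer ratios), so the score
is accurate even when P underflows double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional

from .model import (
    SPECIES,
    SPECIES_PRIORITY,
    GeneModel,
    GenomeAnnotation,
    window_families,
)

DEFAULT_N = 4704


class SyntenyParameterError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class AssignmentConfig:
    """Tunable knobs of the assignment procedure.

    ``s_min`` is the minimum synteny support (3.0 ~ P <= 1e-3) and
    ``margin_min`` the required lead over the second-best orthogroup
    (2.0 ~ a hundred-fold probability ratio); both are exposed because
    the procedure only fixes that such floors exist, not their values.
    """

    window_radius: int = 5
    s_min: float = 3.0
    margin_min: float = 2.0
    n_universe: int = DEFAULT_N
    max_iterations: int = 25
    # homology floor for rescue and rejection
    min_identity: float = 0.30
    min_coverage: float = 0.50
    assign_pseudogenes: bool = False

    def __post_init__(self) -> None:
        if min(self.window_radius, self.s_min, self.margin_min, self.n_universe,
               self.max_iterations) <= 0:
            raise SyntenyParameterError("all assignment parameters must be positive")


@dataclass
class SyntenyScore:
    """S = -log10(P_hyper) with its (a, b, k, N) provenance."""

    a: int
    b: int
    k: int
    n_universe: int
    p_hyper: float
    s: float


def hypergeom_tail(a: int, b: int, k: int, n_universe: int) -> Fraction:
    """Exact upper-tail hypergeometric probability as a Fraction.

    Probability that two random subsets of sizes ``a`` and ``b`` drawn
    from ``n_universe`` families share at least ``k`` members.
    """
    if n_universe < a or n_universe < b:
        raise SyntenyParameterError(
            f"universe N={n_universe} smaller than window ({a}, {b})"
        )
    if k < 0 or k > min(a, b):
        raise SyntenyParameterError(f"shared count k={k} outside [0, min(a, b)]")
    num = sum(
        math.comb(a, i) * math.comb(n_universe - a, b - i)
        for i in range(k, min(a, b) + 1)
    )
    return Fraction(num, math.comb(n_universe, b))


def synteny_statistic(
    query_families: Iterable[str],
    target_families: Iterable[str],
    n_universe: int = DEFAULT_N,
) -> SyntenyScore:
    """Window-overlap synteny score between two family sets.

    The inputs are de-duplicated family-id sets (the focal gene's own
    family is expected to be excluded by the caller).  S is computed from
    the exact integer tail via big-int log10, so it stays finite and
    accurate for vanishingly small P.
    """
    qset, tset = set(query_families), set(target_families)
    a, b, k = len(qset), len(tset), len(qset & tset)
    p = hypergeom_tail(a, b, k, n_universe)
    if p == 0:  # only possible when k > 0 is impossible; defensive
        raise SyntenyParameterError("degenerate zero-probability tail")
    s = math.log10(p.denominator) - math.log10(p.numerator)
    s = max(0.0, s)
    return SyntenyScore(a=a, b=b, k=k, n_universe=n_universe, p_hyper=float(p), s=s)


@dataclass
class Orthogroup:
    """A candidate set of orthologs, at most one member per species."""

    id: str
    family: Optional[str]
    founder_species: str
    founder_gene: str
    members: dict[str, str] = field(default_factory=dict)  # species -> gene id
    scores: dict[str, SyntenyScore] = field(default_factory=dict)
    status: str = "incomplete"  # incomplete | complete | rejected

    @property
    def is_complete(self) -> bool:
        return len(self.members) == len(SPECIES)

    def mean_s(self) -> float:
        """Mean synteny support over non-founder members (founder S undefined)."""
        vals = [sc.s for sp, sc in self.scores.items() if sp != self.founder_species]
        return sum(vals) / len(vals) if vals else 0.0


class _GenePos:
    """Index: gene id -> (scaffold annotation, position in order)."""

    def __init__(self, genomes: dict[str, GenomeAnnotation]):
        self.by_id: dict[str, tuple] = {}
        for genome in genomes.values():
            for sid, sc in genome.scaffolds.items():
                for i, g in enumerate(sc.genes):
                    self.by_id[g.id] = (sc, i, g)

    def window(self, gene_id: str, radius: int, exclude_family: Optional[str]) -> set[str]:
        sc, i, _ = self.by_id[gene_id]
        return window_families(sc, i, radius=radius, exclude_family=exclude_family)

    def gene(self, gene_id: str) -> GeneModel:
        return self.by_id[gene_id][2]


def found_orthogroups(
    family_map: dict[str, str],
    genomes: dict[str, GenomeAnnotation],
    config: Optional[AssignmentConfig] = None,
) -> list[Orthogroup]:
    """Found one orthogroup per copy in the best-represented species.

    For each family, the species with the most (assignable) copies
    contributes each of its copies as a founder; ties go to the earlier
    species in canonical order.
    """
    config = config or AssignmentConfig()
    by_family: dict[str, dict[str, list[GeneModel]]] = {}
    for genome in genomes.values():
        for g in genome.genes():
            fam = family_map.get(g.id, g.family)
            if fam is None:
                continue
            if g.is_pseudogene and not config.assign_pseudogenes:
                continue
            by_family.setdefault(fam, {}).setdefault(g.species, []).append(g)
    groups: list[Orthogroup] = []
    for fam in sorted(by_family):
        per_sp = by_family[fam]
        best_sp = max(
            per_sp, key=lambda sp: (len(per_sp[sp]), -SPECIES_PRIORITY[sp])
        )
        copies = sorted(per_sp[best_sp], key=lambda g: g.id)
        for j, g in enumerate(copies):
            og = Orthogroup(
                id=f"OG_{fam}_{j}",
                family=fam,
                founder_species=best_sp,
                founder_gene=g.id,
            )
            og.members[best_sp] = g.id
            groups.append(og)
    return groups


def assign_to_orthogroups(
    founders: list[Orthogroup],
    genomes: dict[str, GenomeAnnotation],
    family_map: dict[str, str],
    config: Optional[AssignmentConfig] = None,
) -> list[Orthogroup]:
    """Iteratively assign family members to founder orthogroups.

    Each unassigned gene scores its window against every orthogroup of
    its family still in the pool; it is assigned to the best orthogroup
    iff best S >= s_min and best - second_best >= margin_min (second
    best taken as 0 when there is a single candidate group).  The margin
    rule is symmetric: when two genes of one species contend for the same
    orthogroup slot within margin_min of each other (tandem duplicates),
    neither is assigned; a clear winner takes the slot and the loser
    retries next pass.  Completed groups leave the pool; iteration stops
    at steady state.
    """
    config = config or AssignmentConfig()
    pos = _GenePos(genomes)
    by_family: dict[str, list[Orthogroup]] = {}
    for og in founders:
        by_family.setdefault(og.family, []).append(og)
    assigned: set[str] = {og.founder_gene for og in founders}

    candidates: list[GeneModel] = []
    for genome in genomes.values():
        for g in genome.genes():
            fam = family_map.get(g.id, g.family)
            if fam is None or fam not in by_family or g.id in assigned:
                continue
            if g.is_pseudogene and not config.assign_pseudogenes:
                continue
            candidates.append(g)
    candidates.sort(key=lambda g: g.id)

    unassigned = list(candidates)
    for _ in range(config.max_iterations):
        # open slots this pass: incomplete groups only
        proposals: dict[tuple[str, str], list[tuple[float, GeneModel, SyntenyScore, Orthogroup]]] = {}
        for g in unassigned:
            fam = family_map.get(g.id, g.family)
            pool = [
                og
                for og in by_family[fam]
                if og.status == "incomplete" and g.species not in og.members
            ]
            if not pool:
                continue
            qwin = pos.window(g.id, config.window_radius, exclude_family=fam)
            scored = []
            for og in pool:
                twin = pos.window(og.founder_gene, config.window_radius, exclude_family=fam)
                scored.append((synteny_statistic(qwin, twin, config.n_universe), og))
            scored.sort(key=lambda t: (-t[0].s, t[1].id))
            best_sc, best_og = scored[0]
            second = scored[1][0].s if len(scored) > 1 else 0.0
            if best_sc.s >= config.s_min and best_sc.s - second >= config.margin_min:
                proposals.setdefault((best_og.id, g.species), []).append(
                    (best_sc.s, g, best_sc, best_og)
                )
        if not proposals:
            break
        newly: set[str] = set()
        deferred: set[str] = set()
        for key in sorted(proposals):
            props = sorted(proposals[key], key=lambda t: (-t[0], t[1].id))
            s, g, sc, og = props[0]
            if len(props) > 1 and s - props[1][0] < config.margin_min:
                # ambiguous slot (e.g. tandem duplicates): defer all contenders
                deferred.update(p[1].id for p in props)
                continue
            og.members[g.species] = g.id
            og.scores[g.species] = sc
            newly.add(g.id)
        for og in founders:
            if og.is_complete and og.status == "incomplete":
                og.status = "complete"
        unassigned = [g for g in unassigned if g.id not in newly]
        if not newly:
            break
    else:
        still = sum(
            1
            for g in unassigned
            if any(
                og.status == "incomplete" and g.species not in og.members
                for og in by_family[family_map.get(g.id, g.family)]
            )
        )
        if still:
            raise ConvergenceError(
                f"assignment did not reach steady state in "
                f"{config.max_iterations} iterations ({still} genes pending)"
            )
    for og in founders:
        if og.is_complete and og.status == "incomplete":
            og.status = "complete"
    return founders


def detect_orthogroups(
    genomes: dict[str, GenomeAnnotation],
    family_map: dict[str, str],
    config: Optional[AssignmentConfig] = None,
) -> list[Orthogroup]:
    """Found + assign in one call (the common entry point)."""
    config = config or AssignmentConfig()
    founders = found_orthogroups(family_map, genomes, config)
    return assign_to_orthogroups(founders, genomes, family_map, config)


# --- intergenic rescue ----------------------------------------------------

def _ungapped_identity(p1: str, p2: str, seed_len: int = 8) -> tuple[float, float]:
    """(identity, coverage) of the best ungapped seed-extended alignment.

    Exact ``seed_len``-residue matches are extended without gaps in both
    directions; identity is matches over aligned length, coverage is
    aligned length over the shorter protein.
    """
    if not p1 or not p2:
        return 0.0, 0.0
    seeds: dict[str, list[int]] = {}
    for i in range(0, max(1, len(p1) - seed_len + 1)):
        seeds.setdefault(p1[i : i + seed_len], []).append(i)
    best = (0.0, 0.0)
    tried: set[int] = set()
    for j in range(0, max(1, len(p2) - seed_len + 1)):
        for i in seeds.get(p2[j : j + seed_len], ()):  # diagonal d = i - j
            d = i - j
            if d in tried:
                continue
            tried.add(d)
            lo = max(0, -d)
            hi = min(len(p2), len(p1) - d)
            matches = sum(1 for q in range(lo, hi) if p1[q + d] == p2[q])
            aln = hi - lo
            if aln <= 0:
                continue
            ident = matches / aln
            cov = aln / min(len(p1), len(p2))
            if ident * cov > best[0] * best[1]:
                best = (ident, cov)
    return best


def rescue_intergenic_orthogroups(
    orthogroups: list[Orthogroup],
    genomes: dict[str, GenomeAnnotation],
    family_map: dict[str, str],
    proteins: Optional[dict[str, str]] = None,
    config: Optional[AssignmentConfig] = None,
    reference: str = "Scer",
) -> list[Orthogroup]:
    """Recover conserved family-less genes between complete orthogroups.

    Walks adjacent complete orthogroups along the reference genome; genes
    without a family assignment occupying the corresponding interval in
    two or more species are matched by rank within the interval.  When
    protein sequences are supplied, matched genes must also pass the
    homology floor (>= ``min_identity`` over >= ``min_coverage`` of the
    shorter protein) against the reference-most member.
    """
    config = config or AssignmentConfig()
    pos = _GenePos(genomes)
    assigned = {
        gid for og in orthogroups if og.status != "rejected" for gid in og.members.values()
    }
    intervals = _reference_intervals(orthogroups, genomes, reference, pos)
    rescued: list[Orthogroup] = []
    counter = 0
    for left_og, right_og in intervals:
        per_species: dict[str, list[GeneModel]] = {}
        for sp in SPECIES:
            span = _interval_genes(left_og, right_og, sp, pos)
            if span is None:
                continue
            free = [
                g
                for g in span
                if g.id not in assigned
                and family_map.get(g.id, g.family) is None
                and not g.is_pseudogene
            ]
            if free:
                per_species[sp] = free
        if len(per_species) < 2:
            continue
        depth = max(len(v) for v in per_species.values())
        for rank in range(depth):
            members = {
                sp: genes[rank].id
                for sp, genes in per_species.items()
                if rank < len(genes)
            }
            if len(members) < 2:
                continue
            if proteins is not None:
                ref_sp = min(members, key=lambda s: SPECIES_PRIORITY[s])
                ref_prot = proteins.get(members[ref_sp], "")
                ok = {}
                for sp, gid in members.items():
                    if sp == ref_sp:
                        ok[sp] = gid
                        continue
                    ident, cov = _ungapped_identity(ref_prot, proteins.get(gid, ""))
                    if ident >= config.min_identity and cov >= config.min_coverage:
                        ok[sp] = gid
                members = ok
            if len(members) < 2:
                continue
            og = Orthogroup(
                id=f"OG_rescue_{counter}",
                family=None,
                founder_species=min(members, key=lambda s: SPECIES_PRIORITY[s]),
                founder_gene=members[min(members, key=lambda s: SPECIES_PRIORITY[s])],
                members=dict(members),
            )
            og.status = "complete" if og.is_complete else "incomplete"
            counter += 1
            rescued.append(og)
            assigned.update(members.values())
    return rescued


def _reference_intervals(orthogroups, genomes, reference, pos):
    """Adjacent pairs of complete orthogroups along each reference scaffold."""
    ref_members = []
    for og in orthogroups:
        if og.status == "complete" and reference in og.members:
            sc, i, g = pos.by_id[og.members[reference]]
            ref_members.append((sc.id, i, og))
    ref_members.sort(key=lambda t: (t[0], t[1]))
    pairs = []
    for (sc1, _, og1), (sc2, _, og2) in zip(ref_members, ref_members[1:]):
        if sc1 == sc2:
            pairs.append((og1, og2))
    return pairs


def _interval_genes(left_og, right_og, species, pos) -> Optional[list[GeneModel]]:
    """Genes strictly between a species' two flanking members, or None."""
    if species not in left_og.members or species not in right_og.members:
        return None
    sc1, i1, _ = pos.by_id[left_og.members[species]]
    sc2, i2, _ = pos.by_id[right_og.members[species]]
    if sc1.id != sc2.id:
        return None
    lo, hi = min(i1, i2), max(i1, i2)
    return sc1.genes[lo + 1 : hi]


def reject_weak_orthogroups(
    orthogroups: list[Orthogroup],
    genomes: Optional[dict[str, GenomeAnnotation]] = None,
    proteins: Optional[dict[str, str]] = None,
    config: Optional[AssignmentConfig] = None,
) -> list[Orthogroup]:
    """Flag orthogroups with weak synteny or weak homology support.

    A group is rejected when the mean member synteny score falls below
    ``s_min``, or (when proteins are supplied) when fewer than half of
    its non-founder members pass the homology floor against the founder.
    Members of rejected groups are released.
    """
    config = config or AssignmentConfig()
    for og in orthogroups:
        if og.status == "rejected":
            continue
        non_founder = [sp for sp in og.members if sp != og.founder_species]
        weak_synteny = bool(non_founder) and og.mean_s() < config.s_min
        weak_homology = False
        if proteins is not None and non_founder:
            ref = proteins.get(og.founder_gene, "")
            passing = 0
            for sp in non_founder:
                ident, cov = _ungapped_identity(ref, proteins.get(og.members[sp], ""))
                if ident >= config.min_identity and cov >= config.min_coverage:
                    passing += 1
            weak_homology = passing < len(non_founder) / 2
        if weak_synteny or weak_homology:
            og.status = "rejected"
    return orthogroups


def score_orthogroup_members(
    orthogroups: list[Orthogroup],
    genomes: dict[str, GenomeAnnotation],
    config: Optional[AssignmentConfig] = None,
) -> None:
    """(Re)compute each non-founder member's S against the founder window."""
    config = config or AssignmentConfig()
    pos = _GenePos(genomes)
    for og in orthogroups:
        twin = pos.window(og.founder_gene, config.window_radius, exclude_family=og.family)
        for sp, gid in og.members.items():
            if sp == og.founder_species:
                continue
            qwin = pos.window(gid, config.window_radius, exclude_family=og.family)
            og.scores[sp] = synteny_statistic(qwin, twin, config.n_universe)


def orthogroup_table(orthogroups: list[Orthogroup]):
    """Flat table: one row per orthogroup (member per species or '-')."""
    import pandas as pd

    rows = []
    for og in orthogroups:
        row = {"id": og.id, "family": og.family or "-", "status": og.status,
               "mean_S": round(og.mean_s(), 3)}
        for sp in SPECIES:
            row[sp] = og.members.get(sp, "-")
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_precision_recall(
    predicted: list[Orthogroup],
    truth_groups: Iterable[dict[str, str]],
) -> tuple[float, float]:
    """Precision/recall over co-orthologous cross-species gene pairs.

    Every unordered pair of genes placed in one orthogroup is a predicted
    link; truth links come from the planted membership maps.
    """
    def links(groups) -> set[frozenset]:
        out = set()
        for members in groups:
            ids = sorted(members.values())
            out.update(
                frozenset((x, y)) for idx, x in enumerate(ids) for y in ids[idx + 1:]
            )
        return out

    pred = links(
        og.members for og in predicted if og.status != "rejected" and len(og.members) > 1
    )
    true = links(m for m in truth_groups if len(m) > 1)
    if not pred or not true:
        return 0.0, 0.0
    tp = len(pred & true)
    return tp / len(pred), tp / len(true)
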