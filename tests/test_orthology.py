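"""Synteny statistic exactness and orthogroup assignment correctness."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import hypergeom

from ssgenus.model import SPECIES, GeneModel
from ssgenus.orthology import (
    AssignmentConfig,
    SyntenyParameterError,
    _GenePos,
    assign_to_orthogroups,
    detect_orthogroups,
    found_orthogroups,
    hypergeom_tail,
    pairwise_precision_recall,
    reject_weak_orthogroups,
    rescue_intergenic_orthogroups,
    score_orthogroup_members,
    synteny_statistic,
)

from conftest import make_collinear_genomes


def oracle_tail(a, b, k, N):
    """Exact rational upper-tail hypergeometric via factorial Fractions."""
    def comb(n, r):
        num = den = 1
        for i in range(r):
            num *= n - i
            den *= i + 1
        return Fraction(num, den)

    return sum(
        comb(a, i) * comb(N - a, b - i) for i in range(k, min(a, b) + 1)
    ) / comb(N, b)


class TestSyntenyStatistic:
    def test_zero_overlap_gives_zero_score(self):
        sc = synteny_statistic({"f1", "f2"}, {"g1", "g2"})
        assert sc.k == 0 and sc.p_hyper == 1.0 and sc.s == 0.0

    def test_full_ten_gene_overlap_equals_log_binomial(self):
        fams = {f"f{i}" for i in range(10)}
        sc = synteny_statistic(fams, fams, 4704)
        assert sc.s == pytest.approx(math.log10(math.comb(4704, 10)), abs=1e-9)

    def test_partial_overlap_matches_rational_oracle(self):
        q = {f"f{i}" for i in range(10)}
        t = {f"f{i}" for i in range(7, 17)}  # k = 3
        sc = synteny_statistic(q, t, 4704)
        exact = oracle_tail(10, 10, 3, 4704)
        assert sc.s == pytest.approx(
            math.log10(exact.denominator) - math.log10(exact.numerator), abs=1e-9
        )

    def test_agrees_with_scipy_upper_tail(self):
        for a, b, k in [(5, 8, 2), (10, 10, 5), (3, 9, 1), (7, 7, 7)]:
            p = float(hypergeom_tail(a, b, k, 4704))
            ref = hypergeom.sf(k - 1, 4704, a, b)
            assert p == pytest.approx(ref, rel=1e-8)

    def test_monotone_nondecreasing_in_shared_count(self):
        prev = -1.0
        for k in range(11):
            p = hypergeom_tail(10, 10, k, 4704)
            s = math.log10(p.denominator) - math.log10(p.numerator)
            assert s >= prev
            prev = s

    def test_window_larger_than_universe_rejected(self):
        with pytest.raises(SyntenyParameterError):
            hypergeom_tail(11, 5, 2, 10)

    def test_impossible_overlap_rejected(self):
        with pytest.raises(SyntenyParameterError):
            hypergeom_tail(5, 5, 6, 4704)

    def test_windows_are_deduplicated_sets(self):
        a = synteny_statistic(["f1", "f1", "f2"], ["f1", "f2", "f2"])
        b = synteny_statistic({"f1", "f2"}, {"f1", "f2"})
        assert a.s == b.s and a.a == 2


class TestFounding:
    def test_single_copy_family_founds_once_from_priority_species(self):
        genomes, fmap = make_collinear_genomes(n_families=5)
        groups = found_orthogroups(fmap, genomes)
        assert len(groups) == 5
        assert all(og.founder_species == "Scer" for og in groups)

    def test_species_with_most_copies_founds(self):
        genomes, fmap = make_collinear_genomes(n_families=5, duplicates={"Sbay": [2]})
        groups = [og for og in found_orthogroups(fmap, genomes) if og.family == "F02"]
        assert len(groups) == 2
        assert all(og.founder_species == "Sbay" for og in groups)

    def test_family_absent_everywhere_founds_nothing(self):
        genomes, fmap = make_collinear_genomes(n_families=3)
        fmap["phantom"] = "F99"  # maps an id that exists in no genome
        groups = found_orthogroups(
            {k: v for k, v in fmap.items() if k != "phantom"}, genomes
        )
        assert {og.family for og in groups} == {"F00", "F01", "F02"}


class TestAssignment:
    def test_perfect_collinearity_yields_complete_groups_with_full_windows(self):
        genomes, fmap = make_collinear_genomes(n_families=15)
        groups = detect_orthogroups(genomes, fmap)
        assert all(og.status == "complete" for og in groups)
        mid = next(og for og in groups if og.family == "F07")
        for sp in SPECIES:
            if sp == mid.founder_species:
                continue
            sc = mid.scores[sp]
            assert (sc.a, sc.b, sc.k) == (10, 10, 10)

    def test_ambiguous_duplicate_groups_defer_single_copy_candidates(self):
        # Spar founds two groups from its tandem F07 copies whose windows
        # are nearly identical; a single-copy species scores both groups
        # equally, fails the margin, and stays unassigned
        genomes, fmap = make_collinear_genomes(
            n_families=15, duplicates={"Spar": [7], "Sbay": [7]}
        )
        groups = detect_orthogroups(genomes, fmap)
        f07 = [og for og in groups if og.family == "F07"]
        assert len(f07) == 2
        assert all(og.founder_species == "Spar" for og in f07)
        for og in f07:
            for sp in ("Scer", "Smik", "Skud"):
                assert sp not in og.members

    def test_tandem_duplicates_contending_for_one_slot_stay_unassigned(self):
        # one founder group per family (founded from Scer); Smik's two
        # tandem F07 copies tie for the same slot within the margin, so
        # neither is assigned while every other species completes
        from ssgenus.orthology import Orthogroup

        genomes, fmap = make_collinear_genomes(
            n_families=15, duplicates={"Smik": [7]}
        )
        founders = []
        for i in range(15):
            fam = f"F{i:02d}"
            founders.append(
                Orthogroup(id=f"OG_{fam}", family=fam, founder_species="Scer",
                           founder_gene=f"Scer_{fam}", members={"Scer": f"Scer_{fam}"})
            )
        assign_to_orthogroups(founders, genomes, fmap)
        og = next(o for o in founders if o.family == "F07")
        assert "Smik" not in og.members
        assert {"Scer", "Spar", "Skud", "Sbay"} <= set(og.members)

    def test_partition_no_gene_in_two_live_groups(self, default_orthogroups):
        seen = {}
        for og in default_orthogroups:
            if og.status == "rejected":
                continue
            for gid in og.members.values():
                assert gid not in seen, f"{gid} in {seen.get(gid)} and {og.id}"
                seen[gid] = og.id

    def test_precision_and_recall_on_default_scenario(
        self, default_genus, default_orthogroups
    ):
        p, r = pairwise_precision_recall(
            default_orthogroups, default_genus.truth.orthogroups.values()
        )
        assert p >= 0.95 and r >= 0.95


def matching_oracle(genomes, family_map, config):
    """Exhaustive per-family matching under the same score/margin rules.

    Independent of the iterative implementation: enumerates, for every
    family and species, each gene's score against every founder window
    (all windows static), applies the gene-side margin rule, then the
    slot-side margin rule, exhaustively rather than iteratively.  Valid
    only on instances built so that scores do not change as groups
    complete (single scaffold, static windows).
    """
    pos = _GenePos(genomes)
    founders = found_orthogroups(family_map, genomes, config)
    by_family = {}
    for og in founders:
        by_family.setdefault(og.family, []).append(og)
    result = {og.id: dict(og.members) for og in founders}
    for fam, ogs in by_family.items():
        twins = {
            og.id: pos.window(og.founder_gene, config.window_radius, fam)
            for og in ogs
        }
        for sp in SPECIES:
            cands = [
                g
                for genome in genomes.values()
                for g in genome.genes()
                if g.species == sp
                and family_map.get(g.id, g.family) == fam
                and g.id not in {og.founder_gene for og in ogs}
            ]
            # gene -> chosen og under the margin rule
            chosen = {}
            for g in sorted(cands, key=lambda g: g.id):
                scores = []
                for og in ogs:
                    if sp in result[og.id]:
                        continue
                    qwin = pos.window(g.id, config.window_radius, fam)
                    scores.append(
                        (synteny_statistic(qwin, twins[og.id], config.n_universe).s,
                         og.id)
                    )
                scores.sort(key=lambda t: (-t[0], t[1]))
                if not scores:
                    continue
                best_s, best_og = scores[0]
                second = scores[1][0] if len(scores) > 1 else 0.0
                if best_s >= config.s_min and best_s - second >= config.margin_min:
                    chosen[g.id] = (best_og, best_s)
            by_slot = {}
            for gid, (ogid, s) in chosen.items():
                by_slot.setdefault(ogid, []).append((s, gid))
            for ogid, entries in by_slot.items():
                entries.sort(key=lambda t: (-t[0], t[1]))
                if len(entries) > 1 and entries[0][0] - entries[1][0] < config.margin_min:
                    continue  # ambiguous slot
                result[ogid][sp] = entries[0][1]
    return result


class TestMatchingOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_assignment_equals_exhaustive_matching(self, seed):
        rng = np.random.default_rng(seed)
        deletions = {
            sp: sorted(
                rng.choice(30, size=int(rng.integers(0, 4)), replace=False).tolist()
            )
            for sp in SPECIES
        }
        dup_sp = SPECIES[int(rng.integers(0, 5))]
        duplicates = {dup_sp: [15]}
        genomes, fmap = make_collinear_genomes(
            n_families=30, deletions=deletions, duplicates=duplicates
        )
        config = AssignmentConfig()
        groups = detect_orthogroups(genomes, fmap, config)
        got = {og.id: dict(og.members) for og in groups}
        expected = matching_oracle(genomes, fmap, config)
        assert got == expected


class TestRescue:
    def _genus_with_novel(self):
        novel = {}
        for sp in SPECIES:
            novel[sp] = [
                GeneModel(id=f"{sp}_novelA", species=sp, scaffold="chr1",
                          start=7500, end=7800, family=None)
            ]
        return make_collinear_genomes(n_families=15, extra=novel)

    def test_planted_family_less_gene_rescued_across_all_species(self):
        genomes, fmap = self._genus_with_novel()
        groups = detect_orthogroups(genomes, fmap)
        rescued = rescue_intergenic_orthogroups(groups, genomes, fmap)
        assert len(rescued) == 1
        assert rescued[0].family is None
        assert set(rescued[0].members) == set(SPECIES)
        assert rescued[0].status == "complete"

    def test_single_species_orf_not_rescued(self):
        extra = {"Smik": [
            GeneModel(id="Smik_orphan", species="Smik", scaffold="chr1",
                      start=7500, end=7800, family=None)
        ]}
        genomes, fmap = make_collinear_genomes(n_families=15, extra=extra)
        groups = detect_orthogroups(genomes, fmap)
        assert rescue_intergenic_orthogroups(groups, genomes, fmap) == []

    def test_empty_intervals_rescue_nothing(self):
        genomes, fmap = make_collinear_genomes(n_families=15)
        groups = detect_orthogroups(genomes, fmap)
        assert rescue_intergenic_orthogroups(groups, genomes, fmap) == []

    def test_homology_floor_blocks_unrelated_sequences(self):
        genomes, fmap = self._genus_with_novel()
        groups = detect_orthogroups(genomes, fmap)
        proteins = {f"{sp}_novelA": p for sp, p in zip(
            SPECIES,
            ["MKLVNTWEDQRAHGFYSPIC" * 3,
             "MKLVNTWEDQRAHGFYSPIC" * 3,
             "MKLVNTWEDQRAHGFYSPIC" * 3,
             "MWYRAGDEQQLKHINVSTFP" * 3,  # unrelated
             "MKLVNTWEDQRAHGFYSPIC" * 3],
        )}
        rescued = rescue_intergenic_orthogroups(
            groups, genomes, fmap, proteins=proteins
        )
        assert len(rescued) == 1
        assert "Skud" not in rescued[0].members

    def test_recovers_generator_planted_novel_genes(self, default_genus, default_orthogroups):
        rescued = rescue_intergenic_orthogroups(
            default_orthogroups, default_genus.genomes, default_genus.family_map
        )
        got = {frozenset(og.members.values()) for og in rescued}
        want = {frozenset(g.values()) for g in default_genus.truth.novel_groups}
        assert got == want


class TestRejection:
    def test_zero_synteny_groups_rejected_and_members_released(self):
        genomes, fmap = make_collinear_genomes(n_families=15)
        groups = detect_orthogroups(genomes, fmap)
        target = groups[7]
        for sp in list(target.scores):
            sc = target.scores[sp]
            sc.s = 0.0
        reject_weak_orthogroups([target])
        assert target.status == "rejected"

    def test_supported_complete_groups_retained(self, default_orthogroups):
        complete = [og for og in default_orthogroups if og.status == "complete"]
        reject_weak_orthogroups(complete)
        assert all(og.status == "complete" for og in complete)

    def test_shuffled_decoy_groups_rejected(self, default_genus, default_orthogroups):
        """False joins built by shuffling members across groups are caught."""
        import copy

        rng = np.random.default_rng(0)
        complete = [og for og in default_orthogroups if og.status == "complete"]
        decoys = copy.deepcopy(rng.choice(complete, size=40, replace=False).tolist())
        pool = copy.deepcopy(rng.choice(complete, size=160, replace=False).tolist())
        for i, og in enumerate(decoys):
            og.id = f"decoy_{i}"
            for j, sp in enumerate(s for s in SPECIES if s != og.founder_species):
                donor = pool[(i * 4 + j) % len(pool)]
                if sp in donor.members and donor.family != og.family:
                    og.members[sp] = donor.members[sp]
        score_orthogroup_members(decoys, default_genus.genomes)
        reject_weak_orthogroups(decoys)
        rejected = sum(og.status == "rejected" for og in decoys)
        assert rejected / len(decoys) >= 0.90
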