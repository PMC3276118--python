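"""Loss walking, WGD pair detection, outlier ranking and rate filters."""

import math

import numpy as np
import pytest

from ssgenus.gain_loss import (
    PresencePattern,
    classify_losses,
    detect_wgd_pairs,
    filter_rate_records,
    flag_disrupted_genes,
    length_outliers,
    walk_losses,
)
from ssgenus.model import SPECIES, GeneModel, RateRecord
from ssgenus.orthology import AssignmentConfig, detect_orthogroups

from conftest import make_collinear_genomes


class TestPresencePattern:
    def test_string_format_with_psi_marks(self):
        p = PresencePattern((1, 1, 0, 0, 1), (False, False, True, False, False))
        assert str(p) == "1:1:0/ψ:0:1"
        assert p.absent_species == ("Smik", "Skud")


class TestWalkLosses:
    def test_deletion_in_one_species_detected_with_exact_pattern(self):
        genomes, fmap = make_collinear_genomes(n_families=15, deletions={"Smik": [7]})
        groups = detect_orthogroups(genomes, fmap)
        losses = walk_losses(groups, genomes, fmap)
        assert len(losses) == 1
        c = losses[0]
        assert c.family == "F07"
        assert str(c.pattern) == "1:1:0:1:1"
        assert c.evidence == "absent"

    def test_interval_with_more_than_three_intervening_features_excluded(self):
        # four consecutive families absent in Smik: the other species show
        # four intervening features in the surviving interval
        genomes, fmap = make_collinear_genomes(
            n_families=15, deletions={"Smik": [6, 7, 8, 9]}
        )
        groups = detect_orthogroups(genomes, fmap)
        assert walk_losses(groups, genomes, fmap) == []
        # exactly at the three-feature budget the interval is kept
        genomes2, fmap2 = make_collinear_genomes(
            n_families=15, deletions={"Smik": [6, 7, 8]}
        )
        groups2 = detect_orthogroups(genomes2, fmap2)
        assert len(walk_losses(groups2, genomes2, fmap2)) == 3

    def test_interval_overlapping_gap_excluded(self):
        genomes, fmap = make_collinear_genomes(n_families=15, deletions={"Smik": [7]})
        # plant an assembly gap inside the Sbay interval around locus 7
        sbay = genomes["Sbay"].scaffolds["chr1"]
        g_left = next(g for g in sbay.genes if g.family == "F06")
        g_right = next(g for g in sbay.genes if g.family == "F08")
        sbay.gaps.append((g_left.end + 10, g_right.start - 10))
        groups = detect_orthogroups(genomes, fmap)
        assert walk_losses(groups, genomes, fmap) == []

    def test_pseudogene_counts_as_loss_evidence(self):
        genomes, fmap = make_collinear_genomes(n_families=15)
        skud = genomes["Skud"].scaffolds["chr1"]
        victim = next(g for g in skud.genes if g.family == "F07")
        victim.status = "pseudogene"
        victim.n_disruptions = 2
        groups = detect_orthogroups(genomes, fmap)
        losses = walk_losses(groups, genomes, fmap)
        assert len(losses) == 1
        assert str(losses[0].pattern) == "1:1:1:0/ψ:1"
        assert losses[0].evidence == "pseudogene"

    def test_losses_in_reference_itself_are_seen(self):
        genomes, fmap = make_collinear_genomes(n_families=15, deletions={"Scer": [7]})
        groups = detect_orthogroups(genomes, fmap)
        losses = walk_losses(groups, genomes, fmap)
        assert len(losses) == 1
        assert str(losses[0].pattern) == "0:1:1:1:1"


class TestClassification:
    def _cand(self, counts, psi=(False,) * 5, family="F01"):
        from ssgenus.gain_loss import LossCandidate

        return LossCandidate(
            family=family, interval=("a", "b"),
            pattern=PresencePattern(tuple(counts), tuple(psi)), evidence="absent",
        )

    def test_one_or_two_absent_is_lineage_restricted(self):
        c1 = self._cand((1, 1, 0, 1, 1))
        c2 = self._cand((1, 1, 0, 0, 1))
        classify_losses([c1, c2])
        assert c1.klass == c2.klass == "lineage_restricted"

    def test_more_than_two_absent_is_widespread(self):
        c = self._cand((0, 0, 0, 0, 1))
        classify_losses([c])
        assert c.klass == "widespread"

    def test_duplicate_loss_takes_precedence(self):
        from ssgenus.gain_loss import WgdPair

        pair = WgdPair(
            family="F01",
            track_members={"Sbay": {"A": "x", "B": "y"}},
            pattern=PresencePattern((1, 1, 1, 1, 2), (False,) * 5),
            pair_species=("Sbay",),
        )
        c = self._cand((1, 1, 0, 1, 1), family="F01")
        classify_losses([c], [pair])
        assert c.klass == "duplicate_loss"


class TestWgdPairs:
    def test_single_copy_families_yield_no_pairs(self, default_genus):
        pairs, _ = detect_wgd_pairs(
            default_genus.genomes, default_genus.family_map,
            default_genus.ancestral_order,
        )
        retained = set(default_genus.truth.retained_families)
        assert all(p.family in retained for p in pairs)

    def test_precision_and_recall_on_planted_pairs(self, default_genus):
        truth = default_genus.truth
        pairs, _ = detect_wgd_pairs(
            default_genus.genomes, default_genus.family_map,
            default_genus.ancestral_order,
        )
        truth_pairs = {
            (fam, sp)
            for fam in truth.retained_families
            for sp in SPECIES
            if all(truth.statuses[(sp, fam, t)] == "intact" for t in "AB")
        }
        pred = {(p.family, sp) for p in pairs for sp in p.pair_species}
        tp = len(pred & truth_pairs)
        assert tp / len(pred) >= 0.90
        assert tp / len(truth_pairs) >= 0.90

    def test_pair_members_map_to_distinct_tracks(self, default_genus):
        pairs, _ = detect_wgd_pairs(
            default_genus.genomes, default_genus.family_map,
            default_genus.ancestral_order,
        )
        for p in pairs:
            for sp in p.pair_species:
                assert set(p.track_members[sp]) == {"A", "B"}

    def test_single_track_retention_reports_expected_pattern(self, default_genus):
        fam = default_genus.truth.single_track_retention_family
        pairs, _ = detect_wgd_pairs(
            default_genus.genomes, default_genus.family_map,
            default_genus.ancestral_order,
        )
        match = [p for p in pairs if p.family == fam]
        assert match and match[0].retention_string() == "1:1:1:1:2"
        assert match[0].pair_species == ("Sbay",)

    def test_families_with_more_than_two_copies_flagged_not_paired(self):
        genomes, fmap = make_collinear_genomes(n_families=15)
        # give Sbay a third F07 copy
        extra = GeneModel(id="Sbay_F07_x", species="Sbay", scaffold="chr9",
                          start=0, end=600, family="F07")
        genomes["Sbay"].add_gene(extra)
        genomes["Sbay"].sort()
        fmap["Sbay_F07_x"] = "F07"
        genomes["Sbay"].scaffolds["chr1"].genes.append(
            GeneModel(id="Sbay_F07_y", species="Sbay", scaffold="chr1",
                      start=99000, end=99600, family="F07")
        )
        fmap["Sbay_F07_y"] = "F07"
        genomes["Sbay"].sort()
        from ssgenus.model import AncestralOrder

        order = AncestralOrder(
            families=[f"F{i:02d}" for i in range(15)],
            track={f"F{i:02d}": "A" for i in range(15)},
        )
        pairs, flagged = detect_wgd_pairs(genomes, fmap, order)
        assert "F07" in flagged
        assert all(p.family != "F07" for p in pairs)


class TestLengthOutliers:
    def test_hand_computed_coefficient_of_variation(self):
        lengths = [300, 300, 300, 300, 150]
        mean = sum(lengths) / 5
        sd = math.sqrt(sum((x - mean) ** 2 for x in lengths) / 4)
        expected_cv = sd / mean
        genomes, fmap = make_collinear_genomes(n_families=15)
        smik = genomes["Smik"].scaffolds["chr1"]
        victim = next(g for g in smik.genes if g.family == "F07")
        for genome in genomes.values():
            for g in genome.genes():
                g.cds_length = 300
        victim.cds_length = 150
        groups = detect_orthogroups(genomes, fmap)
        ranked = length_outliers(groups, genomes)
        top_id, top_cv = ranked[0]
        assert top_cv == pytest.approx(expected_cv)
        assert "F07" in top_id

    def test_planted_truncations_rank_in_top_five(self, default_genus, default_orthogroups):
        ranked = length_outliers(default_orthogroups, default_genus.genomes, top_k=200)
        top5 = {og_id for og_id, _ in ranked[:5]}
        for tr in default_genus.truth.truncations:
            assert any(tr["family"] in og_id for og_id in top5)

    def test_equal_lengths_never_outrank_variation(self, default_genus, default_orthogroups):
        ranked = length_outliers(default_orthogroups, default_genus.genomes, top_k=10**6)
        zero_cv = [og_id for og_id, cv in ranked if cv == 0.0]
        positive = [og_id for og_id, cv in ranked if cv > 0]
        if zero_cv and positive:
            worst_positive_rank = max(
                i for i, (og_id, _) in enumerate(ranked) if og_id in positive
            )
            best_zero_rank = min(
                i for i, (og_id, _) in enumerate(ranked) if og_id in zero_cv
            )
            assert worst_positive_rank < best_zero_rank


class TestRateFilters:
    def test_zero_ds_dropped_in_both_modes(self):
        recs = [RateRecord("a", 0.1, 0.0), RateRecord("b", 0.1, 0.5)]
        assert [r.id for r in filter_rate_records(recs, "strict")] == ["b"]
        assert [r.id for r in filter_rate_records(recs, "low_dS")] == ["b"]

    def test_low_ds_drops_two_sd_below_mean(self):
        rng = np.random.default_rng(0)
        ds = rng.normal(1.0, 0.3, size=200).clip(0.05)
        recs = [RateRecord(f"g{i}", 0.1, float(d)) for i, d in enumerate(ds)]
        recs.append(RateRecord("low", 0.1, 0.01))
        out = filter_rate_records(recs, "low_dS")
        assert "low" not in {r.id for r in out}
        mean = np.mean([r.dS for r in recs])
        sd = np.std([r.dS for r in recs], ddof=1)
        kept_expected = [r.id for r in recs if r.dS >= mean - 2 * sd]
        assert {r.id for r in out} == set(kept_expected)

    def test_identical_ds_values_survive_low_ds(self):
        recs = [RateRecord(f"g{i}", 0.1, 0.5) for i in range(5)]
        assert len(filter_rate_records(recs, "low_dS")) == 5

    def test_low_ds_removals_superset_of_strict(self):
        rng = np.random.default_rng(1)
        recs = [
            RateRecord(f"g{i}", 0.1, float(max(0.0, d)))
            for i, d in enumerate(rng.normal(0.8, 0.5, size=100))
        ]
        strict = {r.id for r in filter_rate_records(recs, "strict")}
        low = {r.id for r in filter_rate_records(recs, "low_dS")}
        assert low <= strict

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            filter_rate_records([], "bogus")


class TestDisruptionFlags:
    def test_no_pseudogenes_no_flags(self):
        genomes, _ = make_collinear_genomes(n_families=5)
        assert flag_disrupted_genes(genomes) == []

    def test_threshold_behaviour_on_planted_pseudogenes(self, default_genus):
        truth = default_genus.truth
        flagged = {g.id for g in flag_disrupted_genes(default_genus.genomes)}
        for gid, k in truth.disruptions.items():
            if k >= 3:
                assert gid in flagged
            else:
                assert gid not in flagged

    def test_sorted_by_disruption_count_descending(self, default_genus):
        flagged = flag_disrupted_genes(default_genus.genomes)
        counts = [g.n_disruptions for g in flagged]
        assert counts == sorted(counts, reverse=True)


class TestGenusWalk:
    def test_recall_and_pattern_exactness_without_gaps(
        self, nogap_genus, nogap_orthogroups
    ):
        truth = nogap_genus.truth
        losses = walk_losses(nogap_orthogroups, nogap_genus.genomes, nogap_genus.family_map)
        # patterns must match the planted per-(family, track) truth exactly
        for c in losses:
            gene_tracks = set()
            for sp in SPECIES:
                for t in "AB":
                    if truth.statuses[(sp, c.family, t)] in ("intact", "pseudogene"):
                        gene_tracks.add(t)
            assert str(c.pattern) in {
                truth.presence_pattern(c.family, t) for t in gene_tracks
            }
        cand_fams = {c.family for c in losses}
        ev_fams = {e["family"] for e in truth.events}
        recall = sum(1 for f in ev_fams if f in cand_fams) / len(ev_fams)
        assert recall >= 0.90
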