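"""Synthetic five-species genus generator with full ground truth.

The generator emulates the evolution of a *Saccharomyces sensu stricto*-like
genus from a whole-genome-duplicated ancestor:

* an ancestral gene order of ``n_families`` loci (YGOB-style ``Anc_c.i``
  names) on ``n_chromosomes`` chromosomes is duplicated into parallel
  tracks A and B;
* most duplicate pairs resolve to a single track before speciation, a
  ``wgd_retention_rate`` fraction remain duplicated (ohnolog pairs);
* the five species then diverge on the fixed topology
  ``((((Scer,Spar),Smik),Skud),Sbay)``, each branch losing gene copies by
  deletion or pseudogenization (1-4 recorded frameshift indels) at rates
  scaled by relative branch length;
* reciprocal translocations swap scaffold arms in selected species;
* assembly gaps (N-runs), annotation dropout, conserved family-less
  ("novel") genes, intergenic ORF decoys and spliceosomal introns are
  layered on, each recorded in the truth tables;
* coding sequence is drawn per species from species-specific biased codon
  usage so the codon-usage coding classifier has signal.

Every random draw flows through a single seeded generator, so identical
parameters produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    SPECIES,
    AncestralOrder,
    GeneModel,
    GenomeAnnotation,
    ScaffoldAnnotation,
)
from .seqs import AMINO_ACIDS, CODONS_BY_AA, SENSE_CODONS, revcomp
from . import io as ssio

# Relative branch lengths: depth of the Sbay split is 1.0, the Skud,
# Smik and Scer/Spar splits at 0.78, 0.53 and 0.33 of that depth.
BRANCHES: tuple[tuple[str, float, tuple[str, ...]], ...] = (
    ("Sbay", 1.0, ("Sbay",)),
    ("anc_ScSk", 0.22, ("Scer", "Spar", "Smik", "Skud")),
    ("Skud", 0.78, ("Skud",)),
    ("anc_ScSm", 0.25, ("Scer", "Spar", "Smik")),
    ("Smik", 0.53, ("Smik",)),
    ("anc_ScSp", 0.20, ("Scer", "Spar")),
    ("Scer", 0.33, ("Scer",)),
    ("Spar", 0.33, ("Spar",)),
)

DONOR = "GTATGT"
BRANCH_MOTIF = "TACTAAC"
ACCEPTOR = "CAG"


class ParameterError(ValueError):
    """Raised when evolution parameters would produce a degenerate genus."""


@dataclass
class EvolutionParams:
    """Rates and sizes governing the synthetic genus.

    Defaults define the standard study scenario: 500 ancestral loci,
    10% ohnolog retention, 5% deletion and 2% pseudogenization per unit
    branch length, 2 translocations in Smik and 4 in Sbay.
    """

    n_families: int = 500
    # scaled with n_families so the fraction of scaffold-terminal loci —
    # where interval methods are blind — stays near the real genomes'
    n_chromosomes: int = 2
    wgd_retention_rate: float = 0.10
    # the standard scenario loses copies at 0.05 per unit branch length in
    # total: 0.04 outright deletion + 0.01 pseudogenization
    lineage_loss_rate: float = 0.04
    pseudogenization_rate: float = 0.01
    translocations: dict[str, int] = field(
        default_factory=lambda: {"Smik": 2, "Sbay": 4}
    )
    gap_rate: float = 0.01
    gap_length: int = 100
    annotation_dropout_rate: float = 0.01
    codon_divergence: float = 0.10
    codon_bias_concentration: float = 0.4
    intron_rate: float = 0.05
    n_truncations: int = 2
    truncation_fraction: float = 0.4
    n_novel_genes: int = 6
    n_decoys_per_species: int = 40
    protein_length_range: tuple[int, int] = (100, 400)
    spacer_length_range: tuple[int, int] = (200, 500)
    gaps_avoid_loss_intervals: bool = True
    plant_single_track_retention: bool = True
    seed: int = 42

    def validate(self) -> None:
        for name in (
            "wgd_retention_rate",
            "lineage_loss_rate",
            "pseudogenization_rate",
            "gap_rate",
            "annotation_dropout_rate",
            "intron_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.n_families < 50:
            raise ParameterError("n_families must be >= 50")
        if self.n_families // self.n_chromosomes < 12:
            raise ParameterError("too few loci per chromosome")
        # a genus where every copy is expected lost is degenerate
        total_loss = (self.lineage_loss_rate + self.pseudogenization_rate) * sum(
            b[1] for b in BRANCHES
        )
        if total_loss >= 1.0:
            raise ParameterError("loss rates imply empty genomes")


@dataclass
class TruthTables:
    """The generator's complete record of planted history.

    ``statuses[(species, family, track)]`` is one of ``intact``,
    ``pseudogene``, ``deleted`` (including pre-speciation track
    resolution) or ``dropped`` (intact in the sequence but absent from
    the annotation).  ``orthogroups`` maps each surviving (family, track)
    lineage to its annotated intact members.
    """

    statuses: dict[tuple[str, str, str], str]
    orthogroups: dict[tuple[str, str], dict[str, str]]
    events: list[dict]
    retained_families: list[str]
    single_track_retention_family: Optional[str]
    disruptions: dict[str, int]
    novel_groups: list[dict[str, str]]
    truncations: list[dict]
    decoys: dict[str, list[tuple[str, int, int, str]]]
    introns: dict[str, list[tuple[str, int]]]
    translocation_log: list[dict]
    dropped_genes: list[str]
    gene_lineage: dict[str, tuple[str, str]]

    def presence_pattern(self, family: str, track: str) -> str:
        """Annotated-state pattern for one (family, track) lineage.

        Counts intact annotated copies per species in canonical order,
        marking species that instead carry a pseudogenized copy with
        ``/psi`` (rendered with the Greek letter).
        """
        parts = []
        for sp in SPECIES:
            st = self.statuses[(sp, family, track)]
            if st == "intact":
                parts.append("1")
            elif st == "pseudogene":
                parts.append("0/ψ")
            else:
                parts.append("0")
        return ":".join(parts)

    def retention_pattern(self, family: str) -> str:
        """Ohnolog retention string for a retained family (intact counts, ψ marks)."""
        parts = []
        for sp in SPECIES:
            intact = sum(
                self.statuses[(sp, family, t)] == "intact" for t in "AB"
            )
            psi = any(
                self.statuses[(sp, family, t)] == "pseudogene" for t in "AB"
            )
            parts.append(f"{intact}/ψ" if psi else str(intact))
        return ":".join(parts)

    def intact_copy_counts(self, family: str) -> dict[str, int]:
        return {
            sp: sum(self.statuses[(sp, family, t)] == "intact" for t in "AB")
            for sp in SPECIES
        }


@dataclass
class GenusData:
    """Everything `simulate_genus` produces, in memory."""

    params: EvolutionParams
    genomes: dict[str, GenomeAnnotation]
    genome_seqs: dict[str, dict[str, str]]
    cds_seqs: dict[str, dict[str, str]]
    family_map: dict[str, str]
    ancestral_order: AncestralOrder
    truth: TruthTables
    codon_tables: dict[str, dict[str, np.ndarray]]

    def write_outputs(self, out_dir) -> None:
        """Emit GFF3 + FASTA per species plus the TSV tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sp in SPECIES:
            ssio.write_gff3(self.genomes[sp], out / f"{sp}.gff3")
            ssio.write_fasta(self.genome_seqs[sp], out / f"{sp}.genome.fasta")
            ssio.write_fasta(self.cds_seqs[sp], out / f"{sp}.cds.fasta")
        ssio.write_family_table(self.family_map, out / "families.tsv")
        ssio.write_ancestral_order(self.ancestral_order, out / "ancestral_order.tsv")
        tdir = out / "truth"
        tdir.mkdir(exist_ok=True)
        summarize_truth(self.truth).to_csv(tdir / "summary.tsv", sep="\t", index=False)
        pd.DataFrame(self.truth.events).to_csv(tdir / "events.tsv", sep="\t", index=False)
        rows = [
            {"species": sp, "family": f, "track": t, "status": st}
            for (sp, f, t), st in sorted(self.truth.statuses.items())
        ]
        pd.DataFrame(rows).to_csv(tdir / "statuses.tsv", sep="\t", index=False)


def _gene_id(species: str, family: str, track: str) -> str:
    return f"{species}_{family}_{track}"


def simulate_genus(params: Optional[EvolutionParams] = None) -> GenusData:
    """Simulate the five-species genus; see the module docstring."""
    params = params or EvolutionParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    # --- ancestral order -------------------------------------------------
    per_chrom = params.n_families // params.n_chromosomes
    families: list[str] = []
    chromosome: dict[str, int] = {}
    for c in range(params.n_chromosomes):
        n = per_chrom + (1 if c < params.n_families % params.n_chromosomes else 0)
        for i in range(n):
            f = f"Anc_{c + 1}.{i + 1}"
            families.append(f)
            chromosome[f] = c + 1

    n_retained = int(round(params.wgd_retention_rate * params.n_families))
    retained = sorted(
        rng.choice(params.n_families, size=n_retained, replace=False).tolist()
    )
    retained_families = [families[i] for i in retained]
    retained_set = set(retained_families)

    track_label = {
        f: ("A" if f in retained_set else ("A" if rng.random() < 0.5 else "B"))
        for f in families
    }
    order = AncestralOrder(
        families=families, track=dict(track_label), chromosome=chromosome
    )

    # a designated ohnolog pair retained in duplicate only in Sbay: one
    # track is deleted on the branch ancestral to the other four species
    gal_family: Optional[str] = None
    if params.plant_single_track_retention and retained_families:
        gal_family = retained_families[len(retained_families) // 2]

    # --- copies present at speciation -----------------------------------
    root_content: dict[tuple[str, str], str] = {}
    for f in families:
        if f in retained_set:
            root_content[(f, "A")] = "intact"
            root_content[(f, "B")] = "intact"
        else:
            root_content[(f, track_label[f])] = "intact"

    # --- branch events ---------------------------------------------------
    events: list[dict] = []
    species_content: dict[str, dict[tuple[str, str], str]] = {}

    def n_intact_tracks(content: dict, f: str) -> int:
        return sum(content.get((f, t)) == "intact" for t in "AB")

    # walk the fixed branch list; each branch copies its ancestor's content
    lineage_content = {"root": root_content}
    branch_parent = {
        "Sbay": "root",
        "anc_ScSk": "root",
        "Skud": "anc_ScSk",
        "anc_ScSm": "anc_ScSk",
        "Smik": "anc_ScSm",
        "anc_ScSp": "anc_ScSm",
        "Scer": "anc_ScSp",
        "Spar": "anc_ScSp",
    }
    for name, blen, affected in BRANCHES:
        content = dict(lineage_content[branch_parent[name]])
        p_del = params.lineage_loss_rate * blen
        p_psi = params.pseudogenization_rate * blen
        for key in sorted(content):
            f, t = key
            if content[key] != "intact":
                continue
            if f == gal_family:
                continue  # the planted case sees no random events
            u = rng.random()
            event_type = None
            if u < p_del:
                event_type = "deletion"
            elif u < p_del + p_psi:
                event_type = "pseudogenization"
            if event_type is None:
                continue
            # never remove the last intact copy of a retained pair
            if f in retained_set and n_intact_tracks(content, f) <= 1:
                continue
            if event_type == "deletion":
                content[key] = "deleted"
                events.append(
                    {"family": f, "track": t, "branch": name, "type": "deletion",
                     "species": ",".join(affected)}
                )
            else:
                n_indels = int(rng.integers(1, 5))
                content[key] = f"pseudogene:{n_indels}"
                events.append(
                    {"family": f, "track": t, "branch": name,
                     "type": "pseudogenization", "n_disruptions": n_indels,
                     "species": ",".join(affected)}
                )
        lineage_content[name] = content

    if gal_family is not None:
        content = lineage_content["anc_ScSk"]
        content[(gal_family, "B")] = "deleted"
        events.append(
            {"family": gal_family, "track": "B", "branch": "anc_ScSk",
             "type": "deletion", "species": "Scer,Spar,Smik,Skud"}
        )
        for name in ("Skud", "anc_ScSm", "Smik", "anc_ScSp", "Scer", "Spar"):
            lineage_content[name][(gal_family, "B")] = "deleted"

    for sp in SPECIES:
        species_content[sp] = lineage_content[sp]

    # --- per-(family, track) structural choices --------------------------
    strands = {}
    for f in families:
        for t in "AB":
            strands[(f, t)] = "+" if rng.random() < 0.5 else "-"
    prot_lengths = {
        f: int(rng.integers(*params.protein_length_range)) for f in families
    }
    aa_seqs = {
        f: "".join(rng.choice(AMINO_ACIDS, size=prot_lengths[f]))
        for f in families
    }
    # which surviving lineages carry an intron (forward-strand only, and
    # never in the designated retained pair, to keep that case clean)
    intron_lineages = {
        key
        for key in sorted(root_content)
        if strands[key] == "+"
        and key[0] != gal_family
        and rng.random() < params.intron_rate
    }

    # indel realizations are drawn once per pseudogenization event so that
    # descendants of an internal-branch event share positions
    for ev in events:
        if ev["type"] != "pseudogenization":
            continue
        cds_len = 3 * (prot_lengths[ev["family"]] + 1)
        k = ev["n_disruptions"]
        positions = _spaced_positions(rng, cds_len, k, margin=45, min_gap=45)
        ev["indels"] = [
            (int(p), "ins" if rng.random() < 0.5 else "del") for p in positions
        ]

    # --- codon usage ------------------------------------------------------
    base_tables = {
        aa: rng.dirichlet([params.codon_bias_concentration] * len(CODONS_BY_AA[aa]))
        if len(CODONS_BY_AA[aa]) > 1
        else np.array([1.0])
        for aa in AMINO_ACIDS
    }
    codon_tables: dict[str, dict[str, np.ndarray]] = {}
    for sp in SPECIES:
        sp_table = {}
        for aa in AMINO_ACIDS:
            base = base_tables[aa]
            if len(base) == 1:
                sp_table[aa] = base
            else:
                conc = np.maximum(base, 1e-3) / max(params.codon_divergence, 1e-6)
                sp_table[aa] = rng.dirichlet(conc)
        codon_tables[sp] = sp_table

    # --- novel family-less genes -----------------------------------------
    eventful = {ev["family"] for ev in events}
    quiet = [
        f
        for f in families
        if f not in eventful and f not in retained_set
        and order.position(f) + 1 < len(families)
        and families[order.position(f) + 1] not in eventful
        and chromosome[families[order.position(f) + 1]] == chromosome[f]
        and track_label[families[order.position(f) + 1]] == track_label[f]
    ]
    # anchor after a quiet family whose successor on the same track is quiet:
    # the novel gene then sits between two complete orthogroups everywhere
    anchors: list[str] = []
    for f in quiet:
        pos = order.position(f)
        nxt = next(
            (
                g
                for g in families[pos + 1:]
                if chromosome[g] == chromosome[f] and track_label[g] == track_label[f]
                and g not in retained_set
            ),
            None,
        )
        if nxt is not None and nxt not in eventful:
            anchors.append(f)
    sel = rng.choice(len(anchors), size=min(params.n_novel_genes, len(anchors)), replace=False)
    novel_anchors = [anchors[i] for i in sorted(sel.tolist())]
    novel_aa = {
        a: "".join(rng.choice(AMINO_ACIDS, size=int(rng.integers(90, 200))))
        for a in novel_anchors
    }

    # planted severe truncations: one species' copy of a quiet single-copy
    # family is cut to a fraction of its length (intact frame, short CDS)
    trunc_pool = [
        f for f in quiet if f not in set(novel_anchors) and f != gal_family
    ]
    truncations: list[dict] = []
    if params.n_truncations and trunc_pool:
        t_sel = rng.choice(
            len(trunc_pool), size=min(params.n_truncations, len(trunc_pool)),
            replace=False,
        )
        for i in sorted(t_sel.tolist()):
            f = trunc_pool[i]
            sp = SPECIES[int(rng.integers(0, len(SPECIES)))]
            truncations.append(
                {"family": f, "track": track_label[f], "species": sp}
            )
    trunc_lookup = {
        (tr["species"], tr["family"], tr["track"]): tr for tr in truncations
    }
    trunc_families = {tr["family"] for tr in truncations}
    intron_lineages -= {(f, t) for (f, t) in intron_lineages if f in trunc_families}

    # --- scaffold gene lists ---------------------------------------------
    # item: ("copy", family, track) or ("novel", anchor_family, index)
    scaffold_lists: dict[str, dict[str, list[tuple]]] = {}
    for sp in SPECIES:
        content = species_content[sp]
        scs: dict[str, list[tuple]] = {}
        for c in range(1, params.n_chromosomes + 1):
            for t in "AB":
                items: list[tuple] = []
                for f in families:
                    if chromosome[f] != c:
                        continue
                    st = content.get((f, t))
                    if st is None or st == "deleted":
                        continue
                    items.append(("copy", f, t))
                    if f in novel_anchors and track_label[f] == t:
                        items.append(("novel", f, novel_anchors.index(f)))
                scs[f"chr{c}{t}"] = items
        scaffold_lists[sp] = scs

    # --- translocations ---------------------------------------------------
    translocation_log: list[dict] = []
    for sp in SPECIES:
        for _ in range(params.translocations.get(sp, 0)):
            scs = scaffold_lists[sp]
            names = sorted(n for n in scs if len(scs[n]) >= 10)
            if len(names) < 2:
                break
            i, j = rng.choice(len(names), size=2, replace=False)
            a, b = names[int(i)], names[int(j)]
            cut_a = int(rng.integers(5, len(scs[a]) - 4))
            cut_b = int(rng.integers(5, len(scs[b]) - 4))
            scs[a], scs[b] = (
                scs[a][:cut_a] + scs[b][cut_b:],
                scs[b][:cut_b] + scs[a][cut_a:],
            )
            translocation_log.append(
                {"species": sp, "scaffold_a": a, "cut_a": cut_a,
                 "scaffold_b": b, "cut_b": cut_b}
            )

    # --- annotation dropout ----------------------------------------------
    dropped: set[tuple[str, str, str]] = set()
    for sp in SPECIES:
        content = species_content[sp]
        for key in sorted(content):
            if content[key] != "intact" or key[0] == gal_family:
                continue
            if key[0] in trunc_families:
                continue  # keep planted truncations observable
            if rng.random() < params.annotation_dropout_rate:
                dropped.add((sp, key[0], key[1]))

    # --- sequence layout ---------------------------------------------------
    loss_families = {ev["family"] for ev in events}
    genomes: dict[str, GenomeAnnotation] = {}
    genome_seqs: dict[str, dict[str, str]] = {}
    cds_seqs: dict[str, dict[str, str]] = {}
    family_map: dict[str, str] = {}
    disruptions: dict[str, int] = {}
    statuses: dict[tuple[str, str, str], str] = {}
    novel_groups: list[dict[str, str]] = [dict() for _ in novel_anchors]
    decoys: dict[str, list[tuple[str, int, int, str]]] = {sp: [] for sp in SPECIES}
    introns: dict[str, list[tuple[str, int]]] = {sp: [] for sp in SPECIES}
    orthogroups: dict[tuple[str, str], dict[str, str]] = {}
    gene_lineage: dict[str, tuple[str, str]] = {}
    dropped_genes: list[str] = []

    psi_events = {
        (ev["family"], ev["track"]): ev
        for ev in events
        if ev["type"] == "pseudogenization"
    }

    for sp in SPECIES:
        genome = GenomeAnnotation(species=sp)
        seqs: dict[str, str] = {}
        cds_out: dict[str, str] = {}
        content = species_content[sp]

        # decoy assignment: (scaffold, slot index) -> planted decoy ORF
        all_slots = [
            (scaffold, k)
            for scaffold in sorted(scaffold_lists[sp])
            for k in range(len(scaffold_lists[sp][scaffold]) + 1)
        ]
        decoy_idx = rng.choice(
            len(all_slots),
            size=min(params.n_decoys_per_species, len(all_slots)),
            replace=False,
        )
        decoy_slots = {all_slots[int(i)] for i in decoy_idx}

        for scaffold in sorted(scaffold_lists[sp]):
            items = scaffold_lists[sp][scaffold]
            # which spacers must stay gap-free so losses stay identifiable
            protected: set[int] = set()
            if params.gaps_avoid_loss_intervals:
                for k, item in enumerate(items):
                    if item[0] == "copy" and item[1] in loss_families:
                        protected.update(range(k - 3, k + 5))
            parts: list[str] = []
            pos = 0
            gaps: list[tuple[int, int]] = []

            def add_spacer(slot: int) -> None:
                nonlocal pos
                length = int(rng.integers(*params.spacer_length_range))
                spacer = _random_dna(rng, length)
                if (scaffold, slot) in decoy_slots:
                    d_len = int(rng.integers(100, 300)) * 3
                    d_seq = _decoy_orf(rng, d_len)
                    mid = length // 2
                    start = pos + mid
                    decoys[sp].append((scaffold, start, start + len(d_seq), d_seq))
                    spacer = spacer[:mid] + d_seq + spacer[mid:]
                elif (
                    params.gap_rate > 0
                    and slot not in protected
                    and rng.random() < params.gap_rate
                ):
                    mid = length // 2
                    gaps.append((pos + mid, pos + mid + params.gap_length))
                    spacer = spacer[:mid] + "N" * params.gap_length + spacer[mid:]
                parts.append(spacer)
                pos += len(spacer)

            for k, item in enumerate(items):
                add_spacer(k)
                if item[0] == "copy":
                    _, f, t = item
                    st = content[(f, t)]
                    strand = strands[(f, t)]
                    cds = _draw_cds(rng, aa_seqs[f], codon_tables[sp])
                    n_dis = 0
                    status = "intact"
                    tr = trunc_lookup.get((sp, f, t))
                    if tr is not None and st == "intact":
                        n_keep = max(30, int(len(aa_seqs[f]) * params.truncation_fraction))
                        cds = cds[: 3 * (n_keep + 1)] + "TAA"
                        tr["gene_id"] = _gene_id(sp, f, t)
                    if st.startswith("pseudogene"):
                        ev = psi_events[(f, t)]
                        cds = _apply_indels(rng, cds, ev["indels"])
                        n_dis = len(ev["indels"])
                        status = "pseudogene"
                    genomic = cds
                    intron_here = (
                        (f, t) in intron_lineages and status == "intact"
                    )
                    if intron_here:
                        intron = _intron_seq(rng)
                        ins_at = 30
                        genomic = cds[:ins_at] + intron + cds[ins_at:]
                    if strand == "-":
                        genomic_fwd = revcomp(genomic)
                    else:
                        genomic_fwd = genomic
                    gid = _gene_id(sp, f, t)
                    start, end = pos, pos + len(genomic_fwd)
                    if intron_here and strand == "+":
                        introns[sp].append((scaffold, start + 30))
                    is_dropped = (sp, f, t) in dropped
                    statuses[(sp, f, t)] = (
                        "dropped" if is_dropped else status
                    )
                    gene_lineage[gid] = (f, t)
                    if not is_dropped:
                        genome.add_gene(
                            GeneModel(
                                id=gid, species=sp, scaffold=scaffold,
                                start=start, end=end, strand=strand,
                                status=status, family=f,
                                n_disruptions=n_dis, cds_length=len(cds),
                            )
                        )
                        family_map[gid] = f
                        cds_out[gid] = cds
                        if status == "pseudogene":
                            disruptions[gid] = n_dis
                        else:
                            orthogroups.setdefault((f, t), {})[sp] = gid
                    else:
                        dropped_genes.append(gid)
                    parts.append(genomic_fwd)
                    pos = end
                else:
                    _, anchor, idx = item
                    aa = novel_aa[anchor]
                    cds = _draw_cds(rng, aa, codon_tables[sp])
                    gid = f"{sp}_nov{idx}"
                    start, end = pos, pos + len(cds)
                    genome.add_gene(
                        GeneModel(
                            id=gid, species=sp, scaffold=scaffold,
                            start=start, end=end, strand="+",
                            status="intact", family=None,
                            n_disruptions=0, cds_length=len(cds),
                        )
                    )
                    novel_groups[idx][sp] = gid
                    cds_out[gid] = cds
                    parts.append(cds)
                    pos = end
            add_spacer(len(items))
            seqs[scaffold] = "".join(parts)
            genome.scaffolds.setdefault(
                scaffold, ScaffoldAnnotation(scaffold)
            ).gaps = gaps
        genome.sort()
        genome.validate()
        genomes[sp] = genome
        genome_seqs[sp] = seqs
        cds_seqs[sp] = cds_out

    # statuses for lineages with no surviving copy anywhere in a species
    for sp in SPECIES:
        content = species_content[sp]
        for f in families:
            for t in "AB":
                key = (sp, f, t)
                if key in statuses:
                    continue
                st = content.get((f, t))
                statuses[key] = "deleted" if st in (None, "deleted") else st

    truth = TruthTables(
        statuses=statuses,
        orthogroups=orthogroups,
        events=events,
        retained_families=retained_families,
        single_track_retention_family=gal_family,
        disruptions=disruptions,
        novel_groups=[g for g in novel_groups if g],
        truncations=truncations,
        decoys=decoys,
        introns=introns,
        translocation_log=translocation_log,
        dropped_genes=dropped_genes,
        gene_lineage=gene_lineage,
    )
    return GenusData(
        params=params,
        genomes=genomes,
        genome_seqs=genome_seqs,
        cds_seqs=cds_seqs,
        family_map=family_map,
        ancestral_order=order,
        truth=truth,
        codon_tables=codon_tables,
    )


def summarize_truth(truth: TruthTables) -> pd.DataFrame:
    """One-row summary of planted event counts, deterministic column order."""
    ev = pd.DataFrame(truth.events)
    n_del = int((ev["type"] == "deletion").sum()) if len(ev) else 0
    n_psi = int((ev["type"] == "pseudogenization").sum()) if len(ev) else 0
    return pd.DataFrame(
        [
            {
                "deletions": n_del,
                "pseudogenizations": n_psi,
                "retained_pairs": len(truth.retained_families),
                "translocations": len(truth.translocation_log),
                "novel_genes": len(truth.novel_groups),
                "truncations": len(truth.truncations),
                "dropped_annotations": len(truth.dropped_genes),
                "decoy_orfs": sum(len(v) for v in truth.decoys.values()),
                "introns": sum(len(v) for v in truth.introns.values()),
            }
        ]
    )


# --- low-level draws -----------------------------------------------------

_DNA = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_DNA[rng.integers(0, 4, size=length)])


def _draw_cds(rng, aa_seq: str, table: dict[str, np.ndarray]) -> str:
    """ATG + species-biased synonymous codons + TAA stop."""
    codons = ["ATG"]
    for aa in aa_seq:
        opts = CODONS_BY_AA[aa]
        if len(opts) == 1:
            codons.append(opts[0])
        else:
            codons.append(opts[int(rng.choice(len(opts), p=table[aa]))])
    codons.append("TAA")
    return "".join(codons)


def _decoy_orf(rng, length: int) -> str:
    """An ORF with uniform sense-codon usage: no coding codon bias."""
    n = length // 3 - 2
    body = "".join(
        SENSE_CODONS[int(i)] for i in rng.integers(0, len(SENSE_CODONS), size=n)
    )
    return "ATG" + body + "TAA"


def _intron_seq(rng) -> str:
    mid1 = _random_dna(rng, int(rng.integers(20, 60)))
    mid2 = _random_dna(rng, int(rng.integers(6, 16)))
    # scrub accidental donor/acceptor-like signal from filler
    mid1 = mid1.replace("GT", "CT")
    return DONOR + mid1 + BRANCH_MOTIF + mid2 + ACCEPTOR


def _spaced_positions(rng, length: int, k: int, margin: int, min_gap: int) -> list[int]:
    """k positions in [margin, length-margin) pairwise >= min_gap apart."""
    for _ in range(200):
        pos = sorted(
            int(p) for p in rng.integers(margin, max(margin + 1, length - margin), size=k)
        )
        if all(b - a >= min_gap for a, b in zip(pos, pos[1:])):
            return pos
    # fall back to an even grid
    step = max(min_gap, (length - 2 * margin) // max(k, 1))
    return [margin + i * step for i in range(k)]


def _apply_indels(rng, cds: str, indels: list[tuple[int, str]]) -> str:
    out = cds
    shift = 0
    for pos, kind in sorted(indels):
        p = pos + shift
        if kind == "ins":
            base = "ACGT"[int(rng.integers(0, 4))]
            out = out[:p] + base + out[p:]
            shift += 1
        else:
            out = out[:p] + out[p + 1:]
            shift -= 1
    return out
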