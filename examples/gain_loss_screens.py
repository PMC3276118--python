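"""Gene loss walking, WGD duplicate pairs and the length-CV screen.

Walks the reference genome between complete orthogroups to find
lineage-specific absences, calls surviving whole-genome-duplication
pairs by mapping duplicate copies to the two ancestral tracks, and
ranks orthogroups by length heterogeneity to surface truncations.
"""

from collections import Counter

from ssgenus import (
    EvolutionParams,
    classify_losses,
    detect_orthogroups,
    detect_wgd_pairs,
    flag_disrupted_genes,
    length_outliers,
    simulate_genus,
    walk_losses,
)

genus = simulate_genus(EvolutionParams(n_families=120, gap_rate=0.0, seed=11))
groups = detect_orthogroups(genus.genomes, genus.family_map)

pairs, flagged = detect_wgd_pairs(
    genus.genomes, genus.family_map, genus.ancestral_order
)
losses = classify_losses(walk_losses(groups, genus.genomes, genus.family_map), pairs)

print(f"{len(losses)} loss candidates; classes:",
      dict(Counter(c.klass for c in losses)))
for c in losses[:5]:
    print(f"  {c.family}: {c.pattern}  [{c.klass}, {c.evidence}]")
print("Pattern = intact copies per species (Scer:Spar:Smik:Skud:Sbay); 0 "
      "marks an absence, /ψ a pseudogenized remnant.\n")

print(f"{len(pairs)} families with a surviving WGD duplicate pair somewhere:")
for p in pairs[:5]:
    print(f"  {p.family}: retention {p.retention_string()} "
          f"(pair in {', '.join(p.pair_species)})")

ranked = length_outliers(groups, genus.genomes, top_k=5)
print("\ntop length-CV outliers (likely truncations):")
for og_id, cv in ranked:
    print(f"  {og_id}: CV = {cv:.3f}")

disrupted = flag_disrupted_genes(genus.genomes)
print(f"\n{len(disrupted)} genes carry >= 3 reading-frame disruptions "
      "(the pseudogene review list)")
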