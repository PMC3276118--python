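"""Simulate a small synthetic post-WGD genus and summarize its history.

The generator plants every event class the downstream analyses look
for - duplicate losses, pseudogenizations, translocations, novel genes,
assembly gaps - and records them in truth tables.
"""

from ssgenus import EvolutionParams, simulate_genus, summarize_truth

params = EvolutionParams(n_families=120, seed=11)
genus = simulate_genus(params)

print("planted history (counts per event class):")
print(summarize_truth(genus.truth).to_string(index=False))

print("\ngenes per species:")
for sp, genome in genus.genomes.items():
    print(f"  {sp}: {genome.n_genes()} annotated gene models")

fam = genus.truth.single_track_retention_family
print(f"\ndesignated ohnolog pair retained only in Sbay: {fam} "
      f"(retention pattern {genus.truth.retention_pattern(fam)})")
print("Pattern format is Scer:Spar:Smik:Skud:Sbay counts of intact copies,")
print("with /ψ marking a species whose extra copy survives only as a pseudogene.")
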