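"""Codon-usage coding probability for ORFs without homology support.

Trains the two-class LDA on confirmed coding sequence versus intergenic
decoy ORFs from a simulated genus, then scores held-out examples.
"""

import numpy as np

from ssgenus import EvolutionParams, simulate_genus
from ssgenus.annotation import codon_frequencies, coding_probability, train_coding_lda

genus = simulate_genus(EvolutionParams(n_families=120, seed=11))

coding = [
    codon_frequencies(cds)
    for sp in genus.cds_seqs
    for cds in genus.cds_seqs[sp].values()
]
noncoding = [
    codon_frequencies(seq)
    for sp in genus.truth.decoys
    for _, _, _, seq in genus.truth.decoys[sp]
]
rng = np.random.default_rng(0)
ci, ni = rng.permutation(len(coding)), rng.permutation(len(noncoding))
hc, hn = len(ci) // 2, len(ni) // 2
model = train_coding_lda(
    [coding[i] for i in ci[:hc]], [noncoding[i] for i in ni[:hn]], priors=(0.5, 0.5)
)

hits = sum(coding_probability(coding[i], model).probability >= 0.5 for i in ci[hc:])
hits += sum(coding_probability(noncoding[i], model).probability < 0.5 for i in ni[hn:])
total = (len(ci) - hc) + (len(ni) - hn)
print(f"holdout accuracy: {hits}/{total} = {hits/total:.3f}")

example = coding_probability(genus.cds_seqs["Scer"][sorted(genus.cds_seqs['Scer'])[0]], model)
print(f"example gene coding probability: {example.probability:.4f}")
print("A probability near 1 means the ORF's synonymous-codon preferences "
      "match confirmed genes rather than intergenic sequence.")
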