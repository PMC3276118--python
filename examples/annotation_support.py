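"""ORF extraction, splice-site scoring and frameshift counting.

Shows the three annotation-support primitives on small explicit inputs:
context-dependent ORF minima, PWM recovery of a planted intron, and the
disruption count of a two-indel pseudogene.
"""

import numpy as np

from ssgenus.annotation import (
    SpliceSiteModel,
    count_frame_disruptions,
    extract_orfs,
    score_splice_sites,
)
from ssgenus.seqs import CODONS_BY_AA, translate

# --- ORFs: a 90 bp ORF passes only in a relaxed (splice-adjacent) context
flank = "TTAA" * 10
seq = flank + "ATG" + "GCT" * 30 + "TGA" + flank
print("internal 96 bp ORF calls:", len(extract_orfs(seq)))
print("same ORF next to a splice hit:",
      len(extract_orfs(seq, splice_hits=[len(flank)])))
print("(internal ORFs need 300 bp; contig-end and splice-adjacent only 60 bp)\n")

# --- splice sites: plant a consensus yeast intron and recover its donor
rng = np.random.default_rng(0)
bg = "".join(rng.choice(list("AC"), size=300))
intron = "GTATGT" + "A" * 40 + "TACTAAC" + "A" * 10 + "CAG"
planted = bg[:120] + intron + bg[120:]
hits = score_splice_sites(planted, SpliceSiteModel())
print(f"splice-site hits: {[(p, round(s,1)) for p, s in hits]} (donor planted at 120)\n")

# --- disruptions: two spaced single-base indels in a 40-codon gene
protein = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=39))
cds = "".join(CODONS_BY_AA[aa][0] for aa in protein)
broken = cds[:40] + "G" + cds[40:80] + cds[81:]  # one insertion, one deletion
print("reference protein:", protein[:25] + "...")
print("disruptions needed to reconstitute it:",
      count_frame_disruptions(broken, protein))
print("(genes needing >= 3 such disruptions are flagged as pseudogene candidates)")
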