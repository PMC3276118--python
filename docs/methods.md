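# Methods

This note documents the models behind `ssgenus`, the defaults and why
they were chosen, the simulator's scope, and the numerical decisions a
maintainer would otherwise have to reverse-engineer from the code.

## The synteny statistic

Orthology assignment rests on a window-overlap statistic. For a query
gene, take the set of distinct ancestral-family ids among the ten genes
around it (radius 5 per side, truncated at scaffold ends, the query's
own family excluded); do the same around the candidate orthogroup's
founder gene. With `a` and `b` distinct families in the two windows,
`k` shared, and a universe of `N` distinguishable families, the
upper-tail hypergeometric probability of sharing at least `k` families
by chance is

    P_hyper = Σ_{i=k}^{min(a,b)} C(a,i) · C(N−a, b−i) / C(N,b)

and the synteny score is `S = −log10(P_hyper)`. `N` defaults to 4704,
the number of curated ancestral-family models distinguishable in
post-WGD yeasts. Windows are de-duplicated **sets** — a family present
twice in a window counts once — and strand is ignored: gene order, not
orientation, carries the signal here.

Numerics: the tail is computed in exact integer arithmetic
(`math.comb`), and `S` as `log10` of big-integer numerator and
denominator, so the score is exact to double precision even when
`P_hyper` (down to ~10⁻³³ for a perfect ten-gene window) approaches the
underflow threshold of intermediate floating-point schemes. The test
suite checks every `(a, b, k)` with `a, b ≤ 10` against an independent
`Fraction`-based summation at 1e-9 and cross-checks `scipy.stats.hypergeom`.

## Orthogroup construction

1. **Founding.** Per family, the species with the most assignable copies
   contributes each copy as a founder (ties break in the fixed order
   Scer > Spar > Smik > Skud > Sbay). Pseudogenes contribute their
   family to windows — a disabled gene still occupies its syntenic
   slot — but are not assignable members by default
   (`AssignmentConfig.assign_pseudogenes`).
2. **Assignment.** Each unassigned family member scores `S` against
   every same-family orthogroup still in the pool and is assigned iff
   best `S ≥ s_min` **and** the lead over the second-best group is
   `≥ margin_min`. The margin is applied symmetrically: two genes of one
   species contending for the same slot within the margin (tandem
   duplicates) are both deferred. Complete five-species groups leave the
   pool after each pass; iteration stops when a pass changes nothing
   (steady state), with a hard cap (`max_iterations`, default 25) whose
   breach raises a diagnostic error rather than silently truncating.
   Groups are never re-founded from a different species.
3. **Rescue.** Intervals between adjacent complete orthogroups along the
   reference are searched for unassigned family-less genes occupying the
   same interval in ≥ 2 species, matched by rank within the interval,
   optionally gated by a homology floor.
4. **Rejection.** Groups whose mean member score falls below `s_min`, or
   with fewer than half their members passing the homology floor against
   the founder, are rejected and their members released.

Defaults: `s_min = 3.0` (P ≤ 10⁻³ — three decades of support is a
conservative floor given that a single shared neighbor pair already
scores ≈ 1.7) and `margin_min = 2.0` (a hundred-fold probability lead
over the runner-up). Both are judgment calls on a quantity the method
itself only requires to exist, and both are config-exposed.

The homology floor — ≥ 30% identity over ≥ 50% of the shorter protein —
is evaluated by an exact 8-residue seed, ungapped-extension aligner.
That deliberately minimal aligner is sufficient for the floor's job
(separating conserved orthologs from shuffled joins); it is not a
general-purpose aligner and will underestimate identity for highly
diverged or indel-riddled pairs.

## Gain/loss screens

The loss walk follows the reference genome (S. cerevisiae) between each
pair of consecutive complete orthogroups and collects every species'
intervening features. An interval is discarded if, in any species, the
flanking members land on different scaffolds (translocation
breakpoints), an assembly gap intersects the interval, or more than
**three** intervening features occur — "features" counts everything
annotated, pseudogenes included. Surviving intervals yield one candidate
per family lacking an intact copy in at least one species, with a
presence pattern in fixed species order.

Pattern notation: the count is of **intact** copies; `/ψ` marks a
species that additionally carries a pseudogenized copy (so `1/ψ` means
one intact copy plus a pseudogene remnant, `0/ψ` a pseudogene only).
Classification: families retaining a WGD duplicate pair anywhere are
`duplicate_loss` (precedence), otherwise 1–2 affected species is
`lineage_restricted` and more is `widespread`.

WGD pairs: for a family with exactly two intact copies in a genome, each
copy's window is scored against the ancestral track-A and track-B
neighbourhoods of the family's locus (up to five same-track loci per
side from the ancestral order, never crossing an ancestral chromosome).
A pair is called iff the copies map to different tracks with `S ≥ s_min`
each; exact ties yield no call, and families with more than two copies
are set aside for manual review rather than auto-paired.

The length screen ranks orthogroups by the coefficient of variation of
member CDS length using the sample (n−1) standard deviation — small
orthogroups make the n−1 correction material. The dS filters drop
records with dS = 0 always, and in `low_dS` mode additionally drop
dS more than two sample standard deviations below the mean of the
surviving set (high ω driven by a tiny denominator).

## Annotation support

* **ORFs.** Both strands, three frames; an ORF runs from the most
  upstream in-frame ATG to the first in-frame stop (stop included in its
  length). Codons containing N terminate frames, so assembly gaps behave
  like contig ends. Minima: 300 bp for fully internal ORFs, 60 bp when a
  terminus is truncated by a contig end or gap, or lies within 3 bp of a
  splice-site hit — each spliced fragment is judged on its own length.
  A frame truncated on its 5′ side (contig start or gap) needs no ATG.
* **Splice sites.** Donor (GTATGT), branch (TACTAAC) and acceptor (YAG)
  position-weight matrices with a uniform-background log₂-odds score; a
  donor position's composite score adds the best branch hit 10–220 bp
  and best acceptor hit 18–260 bp downstream, windows sized for compact
  yeast introns. The acceptor window is anchored to the donor, not the
  chosen branch point — a simplification that keeps scoring a pure
  sliding-window computation and costs little at yeast intron lengths.
  Default threshold 18 bits (consensus scores ≈ 28; random GT positions
  rarely exceed ~10). An N anywhere in a motif window contributes a −10
  penalty, effectively vetoing the position.
* **Coding probability.** Two-class Gaussian LDA on 61-dimensional
  sense-codon frequency vectors: class means, pooled within-class
  covariance, class priors. Frequency vectors are compositional, so the
  pooled covariance is singular by construction; a ridge of
  `1e-6 × trace/d` is added before inversion. Posteriors come from the
  linear discriminants via softmax, so the two class posteriors sum to 1
  exactly. The acceptance threshold for calling an unknown ORF coding is
  a parameter (default 0.5); nothing in the method fixes it.
* **Curation.** Adjacent same-family, same-strand models separated by
  ≤ 5000 bp — or by an assembly gap of any size — merge into one model
  with summed disruption counts (fragmentation is itself evidence of
  disruption); 5000 bp is a generous bound on yeast intergenic distances
  chosen because the merge contract needs *some* distance. A model
  flagged dubious that overlaps a supported model is dropped.
  Start-codon harmonization picks the alignment column with an ATG in
  the most species, ties toward the most upstream column (maximizing
  gene length); species lacking the chosen column fall back to their
  nearest candidate.
* **Disruption counting.** Match blocks between the reference protein
  and the three forward-frame translations (exact 8-residue seeds,
  ungapped extension) are chained by a dynamic program; each frame
  change costs 1, as does a same-frame junction spanning a premature
  stop. Junction slack: blocks may overlap by 2 residues or leave 3
  uncovered, with nucleotide drift in [−9, +12] — enough for the codons
  an indel corrupts, tight enough to forbid skipping real disruptions.
  The count is 0 iff one frame encodes the full protein stop-free;
  "no significant match" (< 50% coverage) returns null, distinct from 0.
  Limits follow from the seed length: indels closer than 8 residues to
  each other or to the protein ends merge or vanish, and repetitive
  proteins can be tiled more cheaply than they were disrupted — the
  brute-force re-editing oracle in the tests is therefore run on
  non-repetitive proteins with spaced indels, which is also how the
  generator plants them.

## Completeness arithmetic

With `k` genomes each complete-and-correct for a random gene with
probability `p`, and errors uncorrelated across genomes, a gene falls in
a complete k-species ortholog set with probability `p^k`; the inverse
question solves `p = f^(1/k)`. Both are exact to double precision;
display rounding is to the nearest percent. The independence assumption
is the model — correlated assembly biases (e.g. all assemblers failing
at the same subtelomeric repeats) would make `p^k` an underestimate of
the loss.

## The synthetic genus

`simulate_genus` emulates what the analyses need to see, not yeast
biochemistry. An ancestral order of `n_families` loci (default 500, on
2 chromosomes so the fraction of scaffold-terminal loci — where interval
methods are blind — stays near that of real 16-chromosome genomes) is
duplicated into tracks A and B. A `wgd_retention_rate` fraction
(default 0.10) stays duplicated at speciation; the rest resolve to one
track, which defines the ancestral track labels. The five species then
diverge on the fixed topology `((((Scer,Spar),Smik),Skud),Sbay)` with
relative branch lengths 0.33 / 0.53 / 0.78 / 1.0 of the genus depth.
Per unit branch length each surviving copy is deleted with probability
0.04 or pseudogenized with probability 0.01 — a total loss intensity of
0.05 — except that a retained pair never loses its last intact copy, and
one designated pair deterministically loses track B on the branch
ancestral to the four non-Sbay species, yielding the textbook
`1:1:1:1:2` retention pattern. Pseudogenization plants 1–4 single-base
indels at positions ≥ 45 bp from CDS ends and from each other (so each
flanking block carries a full seed), realized once per event and shared
by descendant species. Reciprocal translocations (2 in Smik, 4 in Sbay)
swap scaffold tails; conserved family-less genes (6), uniform-codon
decoy ORFs (40/species), consensus introns (5% of forward-strand
genes), 100 bp N-run gaps (1% of intergenic junctions, kept away from
planted-loss neighbourhoods so losses stay identifiable — a flag
disables the avoidance), annotation dropout (1%) and two severe
truncations complete the picture. Coding sequence encodes a shared
per-family protein through species-specific codon tables (Dirichlet
perturbations of a biased base table), which is what gives the LDA its
signal.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: nucleotide-level substitution (the
proteins of orthologs are identical up to synonymous choice, so
homology floors are never stressed by real divergence), subtelomeric
repeat families and transposons (the classic assembly confounders),
intron evolution, overlapping genes, and correlated assembly biases.
Precision/recall figures on the synthetic genus are ceilings, not
forecasts, for real genomes.

All randomness flows through one seeded `numpy` generator in fixed
order: identical parameters give byte-identical outputs.

## Validation scales

The standard validation scenario is 500 families (~2700 genes per
genome, ~550 orthogroups), where the full pipeline — simulation,
assignment, rescue, rejection, walking, WGD calling — runs in well under
a minute. Oracle-equivalence checks (exhaustive matching, brute-force
ORF scans, rational-arithmetic tails, brute-force re-editing) run on
instances small enough for their oracles: ≤ 30 families, ≤ 2 kb
sequences, ≤ 2 indels. These sizes exercise every code path the
full-scale runs use.

## Known limitations

* The walk inherits the interval method's blind spots: scaffold-terminal
  loci have no flanking orthogroup pair, clustered events overflow the
  three-feature budget, and translocation breakpoints void their
  intervals. On the standard scenario this leaves planted-loss recall
  at ~0.92, and the misses are structural, not statistical.
* Orthogroup windows anchor on the founder member; a founder in a
  locally rearranged region weakens scores for all candidates of that
  family.
* The disruption counter assumes the annotated strand and forward frames
  only; it will not recover inversions within a gene.
* `N = 4704` is a property of the family universe, not of the synthetic
  genus; using the statistic on other clades means re-stating `N`.
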