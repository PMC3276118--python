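"""Gene-model curation: fragment merging, overlap cleanup and
cross-species start-codon harmonization."""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Optional, Sequence

from ..model import GeneModel, ScaffoldAnnotation

MAX_MERGE_GAP = 5000  # bp; fragments further apart are distinct loci


def merge_fragmented_models(
    scaffold: ScaffoldAnnotation,
    family_map: Optional[Mapping[str, str]] = None,
    max_merge_gap: int = MAX_MERGE_GAP,
) -> ScaffoldAnnotation:
    """Merge same-family fragments and drop overlapped dubious models.

    Adjacent models of the same family on the same strand separated by
    at most ``max_merge_gap`` bp - or by an assembly gap, however wide -
    are collapsed into one model spanning both, with summed disruption
    counts and CDS lengths (fragmentation is itself evidence of a
    disrupted locus, so the merged model keeps its pseudogene mark if
    either part had one).  A model flagged ``dubious`` that overlaps a
    non-dubious model is removed.
    """
    family_of = lambda g: family_map.get(g.id, g.family) if family_map else g.family

    genes = sorted(scaffold.genes, key=lambda g: (g.start, g.end, g.id))
    # pass 1: drop dubious models nested in / overlapping supported ones
    kept: list[GeneModel] = []
    for g in genes:
        if g.status == "dubious" and any(
            o.status != "dubious" and o.start < g.end and g.start < o.end
            for o in genes
            if o.id != g.id
        ):
            continue
        kept.append(g)

    # pass 2: merge collinear same-family, same-strand fragments
    merged: list[GeneModel] = []
    for g in kept:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and family_of(prev) is not None
            and family_of(prev) == family_of(g)
            and prev.strand == g.strand
            and (
                g.start - prev.end <= max_merge_gap
                or scaffold.gap_in(prev.end, g.start)
            )
        ):
            status = (
                "pseudogene"
                if (prev.n_disruptions + g.n_disruptions) > 0
                or "pseudogene" in (prev.status, g.status)
                else prev.status
            )
            merged[-1] = replace(
                prev,
                end=g.end,
                status=status,
                n_disruptions=prev.n_disruptions + g.n_disruptions,
                cds_length=prev.cds_length + g.cds_length,
            )
        else:
            merged.append(g)
    out = ScaffoldAnnotation(id=scaffold.id, genes=merged, gaps=list(scaffold.gaps))
    out.sort()
    return out


def harmonize_start_codons(
    candidates: Mapping[str, Sequence[int]],
) -> dict[str, int]:
    """Choose one start-codon alignment column across species.

    ``candidates`` maps species to the alignment columns of their
    candidate ATGs (a common coordinate system from a 5' alignment).
    The column carrying an ATG in the most species wins; ties break
    toward the most upstream column, which maximizes overall gene
    length.  Species lacking an ATG at the chosen column fall back to
    their own candidate nearest to it (upstream preferred on a tie).
    """
    columns: dict[int, int] = {}
    for cols in candidates.values():
        for c in set(cols):
            columns[c] = columns.get(c, 0) + 1
    if not columns:
        return {}
    chosen = min(columns, key=lambda c: (-columns[c], c))
    out: dict[str, int] = {}
    for sp, cols in candidates.items():
        if not cols:
            continue
        if chosen in cols:
            out[sp] = chosen
        else:
            out[sp] = min(cols, key=lambda c: (abs(c - chosen), c))
    return out
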