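"""Counting the reading-frame disruptions of a candidate pseudogene.

Given a genomic region and the reference protein it should encode, the
counter asks: what is the minimal number of frame transitions plus
premature stops needed to tile the reference across the three forward
frames of the region?  An intact gene needs zero; each non-compensating
frameshift indel adds one; a nonsense mutation inside an otherwise
collinear frame adds one.

The region is examined in the three forward frames of the annotated
strand only (callers reverse-complement minus-strand regions first).
Match blocks are found with exact 8-residue seeds extended without gaps,
then chained by a small dynamic program; this is deterministic and
exactly checkable against brute-force re-editing on small cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ..seqs import translate

SEED_LEN = 8
# slack at junctions: an indel can corrupt the codons flanking it
REF_OVERLAP = 2  # blocks may overlap by up to 2 residues
REF_GAP = 3  # ... or leave up to 3 residues uncovered
END_SLACK = 3  # residues of the reference allowed to dangle at either end


@dataclass(frozen=True)
class _Block:
    ref_start: int
    ref_end: int
    frame: int
    t_start: int  # start in the frame's translation (residues)

    @property
    def t_end(self) -> int:
        return self.t_start + (self.ref_end - self.ref_start)


def _match_blocks(ref: str, trans: str, frame: int) -> list[_Block]:
    """Maximal ungapped exact matches between ref and one frame's translation."""
    if len(ref) < SEED_LEN or len(trans) < SEED_LEN:
        return []
    seeds: dict[str, list[int]] = {}
    for i in range(len(ref) - SEED_LEN + 1):
        seeds.setdefault(ref[i : i + SEED_LEN], []).append(i)
    blocks: set[_Block] = set()
    seen_diags: dict[int, int] = {}  # diagonal -> rightmost extent handled
    for j in range(len(trans) - SEED_LEN + 1):
        for i in seeds.get(trans[j : j + SEED_LEN], ()):
            d = i - j
            if seen_diags.get(d, -1) >= j:
                continue
            lo_i, lo_j = i, j
            while lo_i > 0 and lo_j > 0 and ref[lo_i - 1] == trans[lo_j - 1]:
                lo_i -= 1
                lo_j -= 1
            hi_i, hi_j = i + SEED_LEN, j + SEED_LEN
            while hi_i < len(ref) and hi_j < len(trans) and ref[hi_i] == trans[hi_j]:
                hi_i += 1
                hi_j += 1
            seen_diags[d] = hi_j
            blocks.add(_Block(ref_start=lo_i, ref_end=hi_i, frame=frame, t_start=lo_j))
    return sorted(blocks, key=lambda b: (b.ref_start, b.frame, b.t_start))


def count_frame_disruptions(region: str, ref_protein: str) -> Optional[int]:
    """Minimal disruptions to reconstitute ``ref_protein`` from ``region``.

    Returns 0 iff the region encodes the full protein in a single frame
    with no internal stop; returns None (distinct from 0) when no
    significant match exists in any frame.
    """
    region = region.upper()
    ref = ref_protein.upper().rstrip("*")
    translations = [translate(region[f:]) for f in range(3)]
    blocks: list[_Block] = []
    for f in range(3):
        blocks.extend(_match_blocks(ref, translations[f], f))
    if not blocks:
        return None
    blocks.sort(key=lambda b: (b.ref_start, b.ref_end, b.frame, b.t_start))
    covered = max(b.ref_end for b in blocks) - min(b.ref_start for b in blocks)
    if covered < len(ref) / 2:
        return None

    INF = float("inf")
    best: dict[int, float] = {}
    for idx, b in enumerate(blocks):
        cost = 0.0 if b.ref_start <= END_SLACK else INF
        for jdx in range(idx):
            a = blocks[jdx]
            prev_cost = best.get(jdx, INF)
            if prev_cost == INF:
                continue
            if not (a.ref_end - REF_OVERLAP <= b.ref_start <= a.ref_end + REF_GAP):
                continue
            # region coordinate must advance roughly in step with the reference
            a_end_nt = a.frame + 3 * a.t_end
            b_start_nt = b.frame + 3 * b.t_start
            ref_step_nt = 3 * (b.ref_start - a.ref_end)
            drift = (b_start_nt - a_end_nt) - ref_step_nt
            if not (-9 <= drift <= 12):
                continue
            if a.frame != b.frame:
                step_cost = 1.0  # frameshift
            else:
                between = translations[a.frame][a.t_end : b.t_start]
                step_cost = 1.0 if "*" in between else 0.0
            cost = min(cost, prev_cost + step_cost)
        best[idx] = cost

    answer = INF
    for idx, b in enumerate(blocks):
        if b.ref_end >= len(ref) - END_SLACK:
            answer = min(answer, best.get(idx, INF))
    if answer == INF:
        return None
    return int(answer)
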