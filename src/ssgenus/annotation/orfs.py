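"""Open-reading-frame extraction with context-dependent length minima.

ORFs run from the most upstream in-frame ATG to the first in-frame stop.
Both strands and all three frames are scanned.  Assembly gaps (N-runs)
terminate reading frames just like contig ends, and ORFs truncated by a
contig end or gap keep a relaxed 60 bp minimum, as do ORFs adjacent to a
splice-site hit; fully internal ORFs must reach 300 bp (stop codon
included).  These are the thresholds appropriate for compact yeast
genomes, where shorter internal ORFs are overwhelmingly spurious.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from ..seqs import is_stop, revcomp

MIN_INTERNAL_BP = 300
MIN_END_BP = 60


@dataclass(frozen=True)
class OrfCall:
    """One extracted ORF, in forward-strand coordinates (0-based half-open)."""

    start: int
    end: int
    strand: str
    frame: int  # frame on its own strand
    context: str  # contig_end | splice_adjacent | internal
    scaffold: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_orfs(
    sequence: str,
    splice_hits: Iterable[int] = (),
    scaffold: Optional[str] = None,
    min_internal: int = MIN_INTERNAL_BP,
    min_end: int = MIN_END_BP,
    splice_margin: int = 3,
) -> list[OrfCall]:
    """All ORFs above the context-dependent minimum, on both strands.

    ``splice_hits`` are forward-strand positions of splice-site matches;
    an ORF terminus within ``splice_margin`` of a hit takes the relaxed
    end minimum.  Returns calls sorted by (start, end, strand).
    """
    seq = sequence.upper()
    hits = sorted(set(splice_hits))
    calls: list[OrfCall] = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        n = len(s)
        for frame in range(3):
            codon_starts = range(frame, n - 2, 3)
            seg_first: Optional[int] = None  # codon start of current segment
            truncated_start = True  # frame opens at a boundary
            for p in codon_starts:
                codon = s[p : p + 3]
                if is_stop(codon):
                    if seg_first is not None:
                        _close_segment(
                            calls, s, n, strand, frame, seg_first, p,
                            stop_is_gap="N" in codon, truncated_start=truncated_start,
                            hits=hits, min_internal=min_internal, min_end=min_end,
                            splice_margin=splice_margin, scaffold=scaffold,
                        )
                    seg_first = None
                    truncated_start = "N" in codon  # gap opens a truncated frame
                else:
                    if seg_first is None:
                        seg_first = p
            if seg_first is not None:  # segment runs off the contig end
                _close_segment(
                    calls, s, n, strand, frame, seg_first, None,
                    stop_is_gap=False, truncated_start=truncated_start,
                    hits=hits, min_internal=min_internal, min_end=min_end,
                    splice_margin=splice_margin, scaffold=scaffold,
                )
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls


def _close_segment(
    calls, s, n, strand, frame, seg_first, stop_at, *, stop_is_gap,
    truncated_start, hits, min_internal, min_end, splice_margin, scaffold,
):
    # end of the ORF on this strand's coordinates
    if stop_at is None:  # ran into the contig end
        orf_end = n - (n - frame) % 3
        end_truncated = True
    elif stop_is_gap:
        orf_end = stop_at
        end_truncated = True
    else:
        orf_end = stop_at + 3  # include the stop codon
        end_truncated = False

    # most upstream in-frame ATG; a frame truncated on its 5' side may
    # continue off the contig/gap and needs no ATG
    orf_start = None
    p = seg_first
    while p < (stop_at if stop_at is not None else orf_end):
        if s[p : p + 3] == "ATG":
            orf_start = p
            break
        p += 3
    start_truncated = False
    if orf_start is None:
        if truncated_start:
            orf_start = seg_first
            start_truncated = True
        else:
            return

    length = orf_end - orf_start
    if length < 3:
        return

    # forward-strand coordinates
    if strand == "+":
        f_start, f_end = orf_start, orf_end
    else:
        f_start, f_end = n - orf_end, n - orf_start

    if end_truncated or start_truncated:
        context = "contig_end"
    elif hits and _near_hit(f_start, f_end, hits, splice_margin):
        context = "splice_adjacent"
    else:
        context = "internal"
    minimum = min_internal if context == "internal" else min_end
    if length >= minimum:
        calls.append(
            OrfCall(start=f_start, end=f_end, strand=strand, frame=frame,
                    context=context, scaffold=scaffold)
        )


def _near_hit(start: int, end: int, hits: list[int], margin: int) -> bool:
    return any(
        abs(h - start) <= margin or abs(h - end) <= margin for h in hits
    )
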