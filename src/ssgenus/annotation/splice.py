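"""Position-weight-matrix scoring of yeast spliceosomal intron signals.

An intron is recognized by three short motifs: the 5' donor (consensus
GTATGT), the branch point (TACTAAC) and the 3' acceptor (YAG).  Each is
modelled as a position-weight matrix (columns sum to 1 before the
log-odds transform against a uniform background); a candidate donor
position is scored as its donor log-odds plus the best branch and
acceptor log-odds in downstream windows typical of compact yeast introns.
The acceptor window is anchored to the donor rather than the chosen
branch point - a deliberate simplification that keeps scoring a pure
sliding-window computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

# canonical yeast motif instances used to build the default matrices
_DONOR_TRAINING = ["GTATGT"] * 8 + ["GTAAGT", "GTACGT"]
_BRANCH_TRAINING = ["TACTAAC"] * 9 + ["GACTAAC"]
_ACCEPTOR_TRAINING = ["CAG"] * 6 + ["TAG"] * 3 + ["AAG"]


def _pwm(instances: list[str], pseudocount: float = 0.5) -> np.ndarray:
    """4 x L probability matrix from aligned motif instances."""
    length = len(instances[0])
    counts = np.full((4, length), pseudocount)
    for inst in instances:
        for j, b in enumerate(inst):
            counts[_BASE_IDX[b], j] += 1
    return counts / counts.sum(axis=0, keepdims=True)


@dataclass
class SpliceSiteModel:
    """Donor/branch/acceptor PWMs with a composite log-odds threshold."""

    donor: np.ndarray = field(default_factory=lambda: _pwm(_DONOR_TRAINING))
    branch: np.ndarray = field(default_factory=lambda: _pwm(_BRANCH_TRAINING))
    acceptor: np.ndarray = field(default_factory=lambda: _pwm(_ACCEPTOR_TRAINING))
    threshold: float = 18.0  # bits; consensus hits score ~28
    branch_window: tuple[int, int] = (10, 220)  # offsets from the donor G
    acceptor_window: tuple[int, int] = (18, 260)

    def __post_init__(self) -> None:
        for m in (self.donor, self.branch, self.acceptor):
            if not np.allclose(m.sum(axis=0), 1.0):
                raise ValueError("PWM columns must sum to 1")

    @classmethod
    def from_training(cls, donors, branches, acceptors, **kw) -> "SpliceSiteModel":
        return cls(donor=_pwm(list(donors)), branch=_pwm(list(branches)),
                   acceptor=_pwm(list(acceptors)), **kw)

    def to_dict(self) -> dict:
        return {
            "donor": self.donor.tolist(),
            "branch": self.branch.tolist(),
            "acceptor": self.acceptor.tolist(),
            "threshold": self.threshold,
            "branch_window": list(self.branch_window),
            "acceptor_window": list(self.acceptor_window),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpliceSiteModel":
        return cls(
            donor=np.asarray(d["donor"]), branch=np.asarray(d["branch"]),
            acceptor=np.asarray(d["acceptor"]), threshold=float(d["threshold"]),
            branch_window=tuple(d["branch_window"]),
            acceptor_window=tuple(d["acceptor_window"]),
        )


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)  # 4 = N/other
    for b, i in _BASE_IDX.items():
        out[arr == ord(b)] = i
    return out


def _scan(code: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Per-position log2-odds of the motif starting there (-inf-ish for N)."""
    n, length = code.size, pwm.shape[1]
    if n < length:
        return np.full(0, -np.inf)
    logodds = np.log2(pwm / 0.25)
    padded = np.vstack([logodds, np.full(length, -10.0)])  # row 4: N penalty
    scores = np.zeros(n - length + 1)
    for j in range(length):
        scores += padded[code[j : n - length + 1 + j], j]
    return scores


def _window_max(x: np.ndarray, lo: int, hi: int, n: int) -> np.ndarray:
    """out[p] = max(x[p+lo : p+hi]) with -inf outside, for p in range(n)."""
    win = hi - lo
    padded = np.concatenate([x, np.full(win, -np.inf)])
    sw = np.lib.stride_tricks.sliding_window_view(padded, win)
    out = np.full(n, -np.inf)
    starts = np.arange(n) + lo
    valid = (starts >= 0) & (starts < sw.shape[0])
    out[valid] = sw[starts[valid]].max(axis=1)
    return out


def score_splice_sites(sequence: str, model: SpliceSiteModel | None = None) -> list[tuple[int, float]]:
    """Positions (0-based, at the donor G of GT) scoring above threshold.

    Scans the given strand only; callers scan the reverse complement
    separately for minus-strand introns.
    """
    model = model or SpliceSiteModel()
    code = _encode(sequence)
    n = code.size
    if n < model.donor.shape[1]:
        return []
    donor_sc = _scan(code, model.donor)
    branch_sc = _scan(code, model.branch)
    acceptor_sc = _scan(code, model.acceptor)
    nd = donor_sc.size
    b_best = _window_max(branch_sc, *model.branch_window, nd)
    a_best = _window_max(acceptor_sc, *model.acceptor_window, nd)
    total = donor_sc + b_best + a_best
    # require an actual GT dinucleotide at the donor
    gt = (code[:nd] == _BASE_IDX["G"]) & (code[1 : nd + 1] == _BASE_IDX["T"])
    hits = np.nonzero(gt & (total >= model.threshold))[0]
    return [(int(p), float(total[p])) for p in hits]
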