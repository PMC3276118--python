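"""Ortholog-set completeness combinatorics.

With ``k`` genomes each independently complete-and-correct for a random
gene with probability ``p``, the chance that a gene lands in a complete
k-species ortholog set is ``p**k`` (annotation and assembly biases
assumed uncorrelated across genomes).  The arithmetic is elementary but
its consequence is not: comparative analyses degrade exponentially in
the number of genomes, so per-genome quality requirements tighten
sharply as a genus grows.
"""

from __future__ import annotations

from dataclasses import dataclass


class CompletenessParameterError(ValueError):
    pass


@dataclass
class CompletenessParams:
    p: float  # per-genome completeness-and-accuracy probability
    k: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise CompletenessParameterError(f"p={self.p} outside [0, 1]")
        if self.k < 1:
            raise CompletenessParameterError(f"k={self.k} must be >= 1")


def expected_complete_fraction(p: float, k: int = 5) -> float:
    """Fraction of genes expected in complete k-species ortholog sets."""
    CompletenessParams(p=p, k=k)
    return p**k


def required_per_genome_completeness(target_fraction: float, k: int = 5) -> float:
    """Per-genome quality needed so a ``target_fraction`` of genes complete."""
    if not 0.0 < target_fraction <= 1.0:
        raise CompletenessParameterError(
            f"target fraction {target_fraction} outside (0, 1]"
        )
    if k < 1:
        raise CompletenessParameterError(f"k={k} must be >= 1")
    return target_fraction ** (1.0 / k)


def as_percent(fraction: float) -> int:
    """Round a fraction to the nearest whole percent for display."""
    return round(fraction * 100)
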