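"""Codon-usage coding potential via two-class linear discriminant analysis.

Each ORF is summarized as its normalized frequency vector over the 61
sense codons.  A Gaussian LDA with class means, a pooled within-class
covariance (ridge-regularized, since compositional frequency vectors are
rank-deficient) and class priors yields a posterior "coding probability":
how much more the ORF's codon usage resembles confirmed coding sequence
than confirmed intergenic sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from ..seqs import SENSE_CODONS, SENSE_INDEX

log = logging.getLogger(__name__)

RIDGE_SCALE = 1e-6  # ridge = RIDGE_SCALE * trace(cov) / dim


def codon_frequencies(cds: str) -> np.ndarray:
    """Normalized 61-dim sense-codon frequency vector of a CDS/ORF."""
    counts = np.zeros(len(SENSE_CODONS))
    s = cds.upper()
    for i in range(0, len(s) - 2, 3):
        idx = SENSE_INDEX.get(s[i : i + 3])
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    return counts / total if total else counts


@dataclass
class LdaModel:
    """Two-class Gaussian LDA in codon-frequency space."""

    means: np.ndarray  # (2, d): row 0 coding, row 1 noncoding
    cov_inv: np.ndarray  # pooled, regularized, inverted
    log_priors: np.ndarray  # (2,)
    classes: tuple[str, str] = ("coding", "noncoding")

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        """P(class | x) for both classes; rows sum to 1 exactly."""
        x = np.atleast_2d(x)
        # linear discriminants: x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c
        proj = self.cov_inv @ self.means.T  # (d, 2)
        disc = x @ proj - 0.5 * np.einsum("cd,dc->c", self.means, proj) + self.log_priors
        disc -= disc.max(axis=1, keepdims=True)
        p = np.exp(disc)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class CodingCall:
    id: str
    frequencies: np.ndarray
    probability: float  # posterior of the coding class

    @property
    def klass(self) -> str:
        return "coding" if self.probability >= 0.5 else "noncoding"


def train_coding_lda(
    coding: Sequence[np.ndarray],
    noncoding: Sequence[np.ndarray],
    priors: tuple[float, float] | None = None,
) -> LdaModel:
    """Fit the two-class LDA from example frequency vectors.

    The pooled within-class covariance receives a ridge term of
    ``1e-6 * trace / d`` on the diagonal before inversion; frequency
    vectors are compositional (they sum to 1) so the raw pooled
    covariance is always singular.  Deterministic given its inputs.
    """
    X1 = np.asarray(list(coding), dtype=float)
    X0 = np.asarray(list(noncoding), dtype=float)
    if len(X1) < 2 or len(X0) < 2:
        raise ValueError("need at least 2 examples per class")
    d = X1.shape[1]
    mu = np.vstack([X1.mean(axis=0), X0.mean(axis=0)])
    dev1 = X1 - mu[0]
    dev0 = X0 - mu[1]
    pooled = (dev1.T @ dev1 + dev0.T @ dev0) / (len(X1) + len(X0) - 2)
    ridge = RIDGE_SCALE * np.trace(pooled) / d
    if ridge == 0.0:
        ridge = RIDGE_SCALE
        log.warning("degenerate training set: zero pooled covariance, using bare ridge")
    pooled = pooled + ridge * np.eye(d)
    if priors is None:
        n = len(X1) + len(X0)
        priors = (len(X1) / n, len(X0) / n)
    return LdaModel(
        means=mu,
        cov_inv=np.linalg.inv(pooled),
        log_priors=np.log(np.asarray(priors)),
    )


def coding_probability(
    orf: Union[str, np.ndarray], model: LdaModel, orf_id: str = ""
) -> CodingCall:
    """Posterior probability that an ORF's codon usage is coding-like."""
    freqs = codon_frequencies(orf) if isinstance(orf, str) else np.asarray(orf, float)
    p = float(model.posteriors(freqs)[0, 0])
    return CodingCall(id=orf_id, frequencies=freqs, probability=p)
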