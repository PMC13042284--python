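"""Shared domain primitives: parental allele frequencies and the genomic-cline function."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ParentalFreqs", "phi"]


@dataclass
class ParentalFreqs:
    """Per-locus allele frequencies in the two pure parental pools.

    ``p_a``/``p_b`` are frequencies of the counted (ALT) allele in pool A
    and pool B.  The ``differential`` |p_a - p_b| measures how
    ancestry-informative a locus is; genomic-cline analysis restricts to
    loci with a large differential.
    """

    p_a: np.ndarray
    p_b: np.ndarray
    ancestral: np.ndarray | None = None

    def __post_init__(self):
        self.p_a = np.asarray(self.p_a, dtype=float)
        self.p_b = np.asarray(self.p_b, dtype=float)
        if self.p_a.shape != self.p_b.shape:
            raise ValueError("p_a and p_b must have the same length")
        for arr in (self.p_a, self.p_b):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.p_a.shape[0]

    @property
    def differential(self) -> np.ndarray:
        return np.abs(self.p_a - self.p_b)

    def swapped(self) -> "ParentalFreqs":
        """Relabel the pools (A <-> B)."""
        return ParentalFreqs(self.p_b.copy(), self.p_a.copy(), self.ancestral)


def phi(h, alpha=0.0, beta=0.0):
    """Genomic-cline function: probability an allele descends from parent A.

    phi(h) = clamp(h + 2 h (1 - h) (alpha + beta (2 h - 1)), 0, 1)

    ``alpha`` shifts the cline (directional introgression: positive means
    excess parent-A ancestry relative to the genome-wide hybrid index h);
    ``beta`` changes its steepness around h = 0.5.  The boundary fixed
    points phi(0) = 0 and phi(1) = 1 hold for all alpha, beta: pure
    individuals carry pure ancestry regardless of locus-specific
    distortion.  Broadcasts over array-valued arguments.
    """
    h = np.asarray(h, dtype=float)
    raw = h + 2.0 * h * (1.0 - h) * (np.asarray(alpha) + np.asarray(beta) * (2.0 * h - 1.0))
    return np.clip(raw, 0.0, 1.0)
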