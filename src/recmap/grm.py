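"""Genomic relationship matrix (VanRaden method 1).

G = Z Z' / (2 * sum_j p_j (1 - p_j)) with Z_ij = g_ij - 2 p_j, where p_j is
the in-sample frequency of the counted (alternate) allele.  Only autosomal
markers contribute; missing genotypes are mean-imputed per marker.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix
from .qc import mean_impute

__all__ = ["Grm", "compute_grm"]


@dataclass
class Grm:
    matrix: np.ndarray
    n_markers_used: int
    allele_freqs: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(m, m.T, atol=1e-8 * max(1.0, np.abs(m).max())):
            raise ValueError("GRM must be symmetric")
        if self.n_markers_used <= 0:
            raise ValueError("n_markers_used must be > 0")
        self.matrix = m

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def with_ridge(self, ridge: float = 1e-6) -> "Grm":
        """Copy with ``ridge`` added to the diagonal (eigen-stability)."""
        return Grm(
            matrix=self.matrix + ridge * np.eye(self.n_samples),
            n_markers_used=self.n_markers_used,
            allele_freqs=self.allele_freqs,
        )


def compute_grm(gm: GenotypeMatrix, autosomes_only: bool = True) -> Grm:
    """Build the relationship matrix from 0/1/2 genotype calls.

    Allele frequencies are estimated from the same sample (cases and
    controls pooled).  Raises if every contributing marker is monomorphic
    (zero scaling denominator).
    """
    if autosomes_only:
        keep = gm.chromosome_classes() == "autosome"
        if not keep.any():
            raise ValueError("no autosomal markers available for the GRM")
        gm = gm.take_markers(keep)
    g = mean_impute(gm)
    p = g.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError(
            "all markers monomorphic: VanRaden scaling denominator is zero"
        )
    z = g - 2.0 * p[None, :]
    matrix = (z @ z.T) / denom
    return Grm(matrix=matrix, n_markers_used=gm.n_markers, allele_freqs=p)
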