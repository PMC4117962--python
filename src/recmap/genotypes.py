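"""Shared genotype containers.

Genotypes are coded as copies of the counted (alternate) allele:
``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: canonical marker-metadata columns
MARKER_COLUMNS = ("id", "chrom", "pos")

_AUTOSOME_MAX = 99


def chromosome_class(chrom: object) -> str:
    """Classify a chromosome label as autosome / X / Y / MT / unknown.

    Labels are matched case-insensitively; numeric strings are autosomes.
    ``0``, ``.``, ``NA`` and empty labels mean the position is unknown.
    """
    s = str(chrom).strip().upper()
    if s.startswith("CHR"):
        s = s[3:]
    if s in ("X",):
        return "X"
    if s in ("Y",):
        return "Y"
    if s in ("MT", "M", "MITO"):
        return "MT"
    if s in ("", "0", ".", "NA", "NAN", "UN", "UNKNOWN"):
        return "unknown"
    try:
        v = int(s)
    except ValueError:
        return "unknown"
    if 1 <= v <= _AUTOSOME_MAX:
        return "autosome"
    return "unknown"


@dataclass
class GenotypeMatrix:
    """Samples x markers genotype calls plus marker metadata.

    Parameters
    ----------
    geno
        ``int8`` array of shape ``(n_samples, n_markers)`` with values in
        ``{0, 1, 2, -1}``.
    markers
        Data frame with at least columns ``id``, ``chrom``, ``pos``
        (1-based bp). Row order matches the columns of ``geno``.
    samples
        Sample identifiers, matching the rows of ``geno``.
    """

    geno: np.ndarray
    markers: pd.DataFrame
    samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2:
            raise ValueError("geno must be 2-D (samples x markers)")
        if len(self.markers) != self.geno.shape[1]:
            raise ValueError(
                f"marker table has {len(self.markers)} rows but geno has "
                f"{self.geno.shape[1]} columns"
            )
        if self.samples and len(self.samples) != self.geno.shape[0]:
            raise ValueError("sample list length does not match geno rows")
        if not self.samples:
            self.samples = [f"S{i:05d}" for i in range(self.geno.shape[0])]
        bad = ~np.isin(self.geno, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls outside {0,1,2,missing}")
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise ValueError(f"marker table lacks columns {missing_cols}")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]

    def chromosome_classes(self) -> np.ndarray:
        return self.markers["chrom"].map(chromosome_class).to_numpy()

    def take_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Subset markers by a boolean mask or index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            geno=self.geno[:, idx],
            markers=self.markers.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - trivial
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None


def allele_frequencies(geno: np.ndarray) -> np.ndarray:
    """Per-marker frequency of the counted allele, from non-missing calls.

    Markers with no non-missing calls get frequency ``nan``.
    """
    g = np.asarray(geno, dtype=float)
    obs = g != MISSING
    g = np.where(obs, g, 0.0)
    denom = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, g.sum(axis=0) / denom, np.nan)


def minor_allele_frequencies(geno: np.ndarray) -> np.ndarray:
    p = allele_frequencies(geno)
    return np.minimum(p, 1.0 - p)
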