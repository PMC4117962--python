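"""Region subsetting, recessive-compatibility filtering and stop-gain
annotation of sequencing variants."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genotypes import MISSING

__all__ = [
    "VariantTable",
    "CdsModel",
    "Consequence",
    "subset_region",
    "recessive_filter",
    "annotate_consequence",
]

log = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT = 0, 1, 2


@dataclass
class VariantTable:
    """Variant records plus a variants x samples genotype-class matrix.

    ``variants`` columns: ``chrom, pos, id, ref, alt, vclass``; genotype
    codes are 0 hom-ref, 1 het, 2 hom-alt, -1 missing.  ``vclass`` is
    ``indel`` iff the ref and alt allele lengths differ.
    """

    variants: pd.DataFrame
    geno: np.ndarray
    samples: list
    #: optional allele-level calls (n_variants, n_samples, 2) and per-call
    #: phase flags, populated by the VCF reader when phase is present
    alleles: np.ndarray | None = None
    phased: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.variants), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        expect = np.where(
            self.variants["ref"].str.len() != self.variants["alt"].str.len(),
            "indel",
            "snp",
        )
        if not (self.variants["vclass"].to_numpy() == expect).all():
            raise ValueError("vclass inconsistent with ref/alt lengths")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def take(self, idx) -> "VariantTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            geno=self.geno[idx],
            samples=list(self.samples),
            alleles=None if self.alleles is None else self.alleles[idx],
            phased=None if self.phased is None else self.phased[idx],
        )

    def class_counts(self) -> dict:
        vc = self.variants["vclass"]
        return {"snp": int((vc == "snp").sum()), "indel": int((vc == "indel").sum())}


def subset_region(vt: VariantTable, chrom: str, start: int, end: int):
    """Records with ``start <= pos <= end`` on ``chrom`` (1-based inclusive).

    Returns ``(subset, counts)`` where counts itemizes retained records by
    variant class.
    """
    if start > end:
        raise ValueError("empty interval: start > end")
    keep = (vt.variants["chrom"].astype(str) == str(chrom)) & vt.variants[
        "pos"
    ].between(start, end)
    sub = vt.take(keep.to_numpy())
    return sub, sub.class_counts()


def recessive_filter(
    vt: VariantTable,
    case_ids: list,
    haplo_hom_control_ids: list,
    control_ids: list,
    case_mode: str = "hom_alt",
    missing_policy: str = "strict",
) -> VariantTable:
    """Variants compatible with recessive inheritance of the defect.

    A record is kept iff every case is hom-alt (``case_mode="hom_alt"``) or
    carries the alternate allele (``case_mode="segregating"``: het or
    hom-alt), every haplotype-homozygous control is het or hom-ref, and
    every remaining control is hom-ref.  Under the default strict missing
    policy a missing call in any constrained sample makes the record
    incompatible; ``"permissive"`` lets missing calls satisfy any
    constraint.
    """
    if case_mode not in ("hom_alt", "segregating"):
        raise ValueError(f"unknown case_mode {case_mode!r}")
    if missing_policy not in ("strict", "permissive"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    groups = [set(case_ids), set(haplo_hom_control_ids), set(control_ids)]
    for i in range(3):
        for j in range(i + 1, 3):
            overlap = groups[i] & groups[j]
            if overlap:
                raise ValueError(f"sample groups overlap: {sorted(overlap)[:5]}")
    gcase = vt.geno[:, vt.sample_index(case_ids)]
    ghap = vt.geno[:, vt.sample_index(haplo_hom_control_ids)]
    gctl = vt.geno[:, vt.sample_index(control_ids)]

    def ok(g, allowed):
        match = np.isin(g, allowed)
        if missing_policy == "permissive":
            match |= g == MISSING
        return match.all(axis=1)

    case_allowed = (HOM_ALT,) if case_mode == "hom_alt" else (HET, HOM_ALT)
    keep = ok(gcase, case_allowed) & ok(ghap, (HOM_REF, HET)) & ok(gctl, (HOM_REF,))
    return vt.take(keep)


_STANDARD_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class CdsModel:
    """A coding sequence on the coding strand, start to (and including) the
    stop codon."""

    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if len(self.seq) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if not self.seq.startswith("ATG"):
            raise ValueError("CDS must begin with ATG")
        if self.seq[-3:] not in _STANDARD_STOPS:
            raise ValueError("CDS must end with a stop codon")
        if set(self.seq) - set("ACGT"):
            raise ValueError("CDS contains non-ACGT characters")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def protein_length(self) -> int:
        """Residue count of the wild-type protein (stop excluded)."""
        return len(self.seq) // 3 - 1

    def codon(self, index: int) -> str:
        """1-based codon lookup."""
        if not 1 <= index <= len(self.seq) // 3:
            raise IndexError(f"codon index {index} out of range")
        return self.seq[3 * (index - 1) : 3 * index]

    def translate(self) -> str:
        return str(Seq(self.seq).translate(to_stop=True))


@dataclass(frozen=True)
class Consequence:
    cds_pos: int
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str
    truncated_protein_length: int | None = None
    residues_lost: int | None = None


def annotate_consequence(cds: CdsModel, cds_pos: int, alt_base: str) -> Consequence:
    """Classify a single-nucleotide substitution within a CDS.

    ``cds_pos`` is 1-based on the coding strand.  For stop-gains the
    truncated protein length is ``codon_index - 1`` and ``residues_lost``
    the difference to the wild-type protein length.
    """
    alt_base = alt_base.upper().replace("U", "T")
    if alt_base not in "ACGT" or len(alt_base) != 1:
        raise ValueError(f"invalid alternate base {alt_base!r}")
    if not 1 <= cds_pos <= len(cds.seq):
        raise ValueError(f"cds_pos {cds_pos} outside CDS of length {len(cds.seq)}")
    if cds.seq[cds_pos - 1] == alt_base:
        raise ValueError("alternate base equals the reference base")
    codon_index = math.ceil(cds_pos / 3)
    offset = (cds_pos - 1) % 3
    ref_codon = cds.codon(codon_index)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    truncated = lost = None
    if ref_aa == "*" and alt_aa != "*":
        effect = "stop_lost"
    elif alt_aa == "*" and ref_aa != "*":
        effect = "stop_gain"
        truncated = codon_index - 1
        lost = cds.protein_length - truncated
    elif codon_index == 1 and alt_aa != "M":
        effect = "start_lost"
    elif ref_aa == alt_aa:
        effect = "synonymous"
    else:
        effect = "missense"
    return Consequence(
        cds_pos=cds_pos,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect=effect,
        truncated_protein_length=truncated,
        residues_lost=lost,
    )


def default_cds(protein_length: int = 487, stop_gain_codon: int = 215) -> CdsModel:
    """Deterministic CDS whose ``stop_gain_codon`` is TGG (tryptophan), so a
    G->A change at its third base creates a premature TGA stop."""
    codons = ["ATG"] + ["GCT"] * (protein_length - 1) + ["TAA"]
    codons[stop_gain_codon - 1] = "TGG"
    return CdsModel("".join(codons))
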