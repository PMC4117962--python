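"""Haplotype carrier statistics.

Frequency of the disease-associated haplotype from carrier counts, an exact
Hardy-Weinberg test, concordance between haplotype and mutation carriers,
the derived defect-allele frequency, exact risk-mating homozygote
probabilities, and expected affected births under random mating.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "CarrierCounts",
    "AlleleFrequencyEstimate",
    "haplotype_frequency",
    "hwe_exact_test",
    "carrier_concordance",
    "defect_allele_frequency",
    "risk_mating_homozygote_prob",
    "expected_affected_per_year",
    "call_haplotype_carriers",
]


@dataclass(frozen=True)
class CarrierCounts:
    n_total: int
    n_het: int
    n_hom: int

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_het, self.n_hom) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_het + self.n_hom > self.n_total:
            raise ValueError("carriers exceed total")


@dataclass(frozen=True)
class AlleleFrequencyEstimate:
    haplotype_freq: float
    concordance: float

    def __post_init__(self) -> None:
        for v in (self.haplotype_freq, self.concordance):
            if not 0.0 <= v <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")

    @property
    def defect_allele_freq(self) -> float:
        return self.haplotype_freq * self.concordance


def haplotype_frequency(c: CarrierCounts) -> float:
    """Allele-count frequency ``(n_het + 2 n_hom) / (2 n_total)``."""
    if c.n_total == 0:
        raise ValueError("n_total must be > 0")
    return (c.n_het + 2 * c.n_hom) / (2 * c.n_total)


def hwe_exact_test(c: CarrierCounts) -> float:
    """Exact conditional Hardy-Weinberg test (standard, not mid-p).

    Conditions on the total and minor-allele counts and sums the
    probabilities of all heterozygote counts no more probable than the
    observed one.  A monomorphic sample returns 1 by convention.
    """
    n = c.n_total
    rare = c.n_het + 2 * c.n_hom
    rare = min(rare, 2 * n - rare)
    obs_het = c.n_het
    if rare == 0:
        return 1.0
    # unnormalized probabilities over het counts with the parity of `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.zeros(hets.size)
    # log P(het) up to a constant, via the hypergeometric-style ratio
    # P(h+2)/P(h) = 4 * n_rare_hom * n_common_hom / ((h+2)(h+1))
    for k in range(1, hets.size):
        h = hets[k - 1]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        logp[k] = logp[k - 1] + np.log(4.0 * hom_r * hom_c) - np.log(
            (h + 2.0) * (h + 1.0)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == obs_het]
    if p_obs.size == 0:
        raise ValueError(
            f"heterozygote count {obs_het} impossible for minor-allele "
            f"count {rare}"
        )
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def hwe_chisq_test(c: CarrierCounts) -> float:
    """One-degree-of-freedom goodness-of-fit chi-square test of HWE.

    Companion to :func:`hwe_exact_test`; preferable only for large,
    common-allele samples.  Monomorphic input returns 1.
    """
    from scipy import stats

    n = c.n_total
    q = (c.n_het + 2 * c.n_hom) / (2 * n)
    if q in (0.0, 1.0):
        return 1.0
    obs = np.array([c.n_hom, c.n_het, n - c.n_het - c.n_hom])
    exp = n * np.array([q * q, 2 * q * (1 - q), (1 - q) ** 2])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def carrier_concordance(
    n_carriers_genotyped: int,
    n_mutation_carriers: int,
    n_hom_carriers: int = 0,
    n_mutation_copies_in_homs: int = 0,
    per_copy: bool = False,
) -> float:
    """Fraction of haplotype carriers (or carrier copies) with the mutation.

    Animal level (default): mutation carriers over genotyped heterozygous
    haplotype carriers.  ``per_copy``: mutant copies over haplotype copies,
    counting homozygous carriers twice.
    """
    if n_carriers_genotyped <= 0:
        raise ValueError("no genotyped haplotype carriers")
    if n_mutation_carriers > n_carriers_genotyped:
        raise ValueError("mutation carriers exceed genotyped carriers")
    if per_copy:
        return (n_mutation_carriers + n_mutation_copies_in_homs) / (
            n_carriers_genotyped + 2 * n_hom_carriers
        )
    return n_mutation_carriers / n_carriers_genotyped


def defect_allele_frequency(haplotype_freq: float, concordance: float) -> float:
    """Haplotype frequency discounted by the mutation concordance."""
    return AlleleFrequencyEstimate(haplotype_freq, concordance).defect_allele_freq


def risk_mating_homozygote_prob(
    sire_carrier: bool, mgs_carrier: bool, pop_freq: float = 0.0
) -> float:
    """P(calf homozygous for the defect) by exhaustive transmission walk.

    The sire is a known heterozygous carrier (or known non-carrier); the
    dam's paternal allele comes from the maternal grandsire, her maternal
    allele from an unrelated granddam with allele frequency ``pop_freq``.
    """
    if not 0.0 <= pop_freq < 1.0:
        raise ValueError("pop_freq outside [0, 1)")

    def allele_probs(carrier: bool):
        # one meiosis from a het carrier; non-carriers transmit the
        # population allele only through the granddam term
        return {1: 0.5, 0: 0.5} if carrier else {0: 1.0}

    total = 0.0
    granddam = {1: pop_freq, 0: 1.0 - pop_freq}
    for (a_mgs, p1), (a_gd, p2) in product(
        allele_probs(mgs_carrier).items(), granddam.items()
    ):
        # dam genotype (a_mgs, a_gd); she transmits each with prob 1/2
        for dam_allele, p3 in ((a_mgs, 0.5), (a_gd, 0.5)):
            for sire_allele, p4 in allele_probs(sire_carrier).items():
                if dam_allele == 1 and sire_allele == 1:
                    total += p1 * p2 * p3 * p4
    return total


def expected_affected_per_year(q: float, births: int) -> float:
    """Random-mating expectation ``q^2 * births``."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q outside [0, 1]")
    if births < 0:
        raise ValueError("births must be >= 0")
    return q * q * births


def call_haplotype_carriers(panel, reference_haplotype: np.ndarray):
    """Exact-match haplotype carrier calling on a phased panel.

    A haplotype copy carries the disease haplotype iff its alleles equal
    ``reference_haplotype`` at every segment marker.  Returns
    ``(CarrierCounts, DataFrame)`` with per-sample copy counts.
    """
    ref = np.asarray(reference_haplotype)
    a0 = panel.segment_alleles(0)
    a1 = panel.segment_alleles(1)
    if a0.shape[1] != ref.size:
        raise ValueError("reference haplotype length does not match segment")
    is0 = (a0 == ref[None, :]).all(axis=1)
    is1 = (a1 == ref[None, :]).all(axis=1)
    n_copies = is0.astype(int) + is1.astype(int)
    counts = CarrierCounts(
        n_total=panel.n_samples,
        n_het=int((n_copies == 1).sum()),
        n_hom=int((n_copies == 2).sum()),
    )
    status = pd.DataFrame(
        {"id": panel.samples, "n_carrier_copies": n_copies,
         "carrier": n_copies >= 1, "hom_carrier": n_copies == 2}
    )
    return counts, status
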