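"""Synthetic cohort generator.

Builds phased SNP-array panels in which a low-frequency founder haplotype
segregates, a nonsense allele is present on a configurable fraction of the
founder copies, and a fixed number of affected samples are homozygous for
the mutant copy over a target segment.  Also generates region sequencing
variants carrying one planted causal record, and survival records for
calves from risk and non-risk matings.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "PhasedPanel",
    "simulate_cohort",
    "simulate_region_variants",
    "simulate_survival",
    "simulate_mating_cohort",
    "calibrate_hazards",
]

# default target segment (1-based inclusive bp)
DEFAULT_SEGMENT = ("21", 70_550_045, 71_573_501)
DEFAULT_CAUSAL_POS = 71_001_232


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the forward simulation.

    Proportions live in ``[0, 1]``; a fixed ``seed`` makes every product of
    the simulation bit-identical across runs.
    """

    n_samples: int = 500
    n_markers_per_chrom: int = 400
    n_chroms: int = 3
    chrom_length_bp: int = 80_000_000
    segment_chrom: str = DEFAULT_SEGMENT[0]
    segment_start: int = DEFAULT_SEGMENT[1]
    segment_end: int = DEFAULT_SEGMENT[2]
    haplotype_freq: float = 0.0186
    mutation_on_haplotype: float = 0.595
    n_cases: int = 8
    array_missing_rate: float = 0.002
    maf_floor: float = 0.05
    maf_range: float = 0.45
    seq_region_n_snps: int = 7_086
    seq_region_n_indels: int = 574
    seq_region_n_outside: int = 500
    causal_pos: int = DEFAULT_CAUSAL_POS
    hazard_base: float = 3.39e-4
    hazard_hom_multiplier: float = 10.3
    censor_day: float = 300.0
    n_risk_matings: int = 1_213
    n_nonrisk_matings: int = 2_552
    edge_erosion_mean: float = 5.0
    flank_markers: int = 10
    seed: int = 0

    def validate(self) -> None:
        props = {
            "haplotype_freq": self.haplotype_freq,
            "mutation_on_haplotype": self.mutation_on_haplotype,
            "array_missing_rate": self.array_missing_rate,
            "maf_floor": self.maf_floor,
            "maf_range": self.maf_range,
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.maf_floor + self.maf_range > 1.0:
            raise ValueError("maf_floor + maf_range exceeds 1")
        if self.segment_start >= self.segment_end:
            raise ValueError("segment_start must be < segment_end")
        if self.segment_end > self.chrom_length_bp:
            raise ValueError("segment extends beyond chrom_length_bp")
        if self.n_cases > self.n_samples:
            raise ValueError(
                f"infeasible config: n_cases={self.n_cases} exceeds "
                f"n_samples={self.n_samples}"
            )
        if self.n_cases > 0 and self.haplotype_freq == 0.0:
            raise ValueError(
                "infeasible config: n_cases > 0 requires haplotype_freq > 0 "
                "(homozygotes for the founder haplotype cannot exist)"
            )
        if self.n_cases > 0 and self.mutation_on_haplotype == 0.0:
            raise ValueError(
                "infeasible config: n_cases > 0 requires "
                "mutation_on_haplotype > 0 (no mutant copies available)"
            )
        for name in ("hazard_base", "hazard_hom_multiplier", "censor_day"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_samples < 1 or self.n_markers_per_chrom < 2 or self.n_chroms < 1:
            raise ValueError("cohort dimensions must be positive")

    def segment_bounds(self) -> tuple:
        return (self.segment_chrom, self.segment_start, self.segment_end)


@dataclass
class PhasedPanel:
    """Phased haplotypes with per-copy founder / mutant provenance flags.

    ``haplotypes`` has shape ``(n_samples, 2, n_markers)`` with 0/1 alleles;
    copy 0 is paternal, copy 1 maternal.  ``mutant_copy`` implies
    ``founder_copy`` (the mutation arose on the founder haplotype).
    """

    haplotypes: np.ndarray
    founder_copy: np.ndarray
    mutant_copy: np.ndarray
    markers: pd.DataFrame
    samples: list
    segment: tuple
    founder_alleles: np.ndarray  # full-length allele vector of the founder haplotype
    segment_marker_idx: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if np.any(self.mutant_copy & ~self.founder_copy):
            raise ValueError("mutant_copy implies founder_copy")
        if self.segment_marker_idx is None:
            chrom, start, end = self.segment
            m = self.markers
            sel = (m["chrom"].astype(str) == str(chrom)) & (
                m["pos"].between(start, end)
            )
            self.segment_marker_idx = np.flatnonzero(sel.to_numpy())

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0]

    def genotypes(self) -> np.ndarray:
        """Unphased genotypes: allele sum over the two copies."""
        return self.haplotypes.sum(axis=1).astype(np.int8)

    def n_founder_copies(self) -> np.ndarray:
        return self.founder_copy.sum(axis=1)

    def n_mutant_copies(self) -> np.ndarray:
        return self.mutant_copy.sum(axis=1)

    def segment_alleles(self, copy: int) -> np.ndarray:
        return self.haplotypes[:, copy, :][:, self.segment_marker_idx]

    def founder_segment_alleles(self) -> np.ndarray:
        return self.founder_alleles[self.segment_marker_idx]


def _marker_table(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced markers; the segment chromosome gets anchor markers at
    the exact segment boundaries so printed coordinates are recoverable."""
    rows = []
    m = config.n_markers_per_chrom
    for c in range(1, config.n_chroms + 1):
        chrom = str(c) if str(c) != config.segment_chrom else config.segment_chrom
        pos = np.linspace(1, config.chrom_length_bp, m).round().astype(np.int64)
        if chrom == config.segment_chrom:
            lo = int(np.argmin(np.abs(pos - config.segment_start)))
            hi = int(np.argmin(np.abs(pos - config.segment_end)))
            if hi == lo:
                hi = lo + 1
            pos[lo] = config.segment_start
            pos[hi] = config.segment_end
            pos = np.sort(pos)
        rows.append(
            pd.DataFrame(
                {
                    "id": [f"snp_{chrom}_{i:05d}" for i in range(m)],
                    "chrom": chrom,
                    "pos": pos,
                }
            )
        )
    # place the target segment on the last chromosome label if not among 1..n
    table = pd.concat(rows, ignore_index=True)
    if config.segment_chrom not in set(table["chrom"]):
        # relabel the last simulated chromosome as the segment chromosome
        last = str(config.n_chroms)
        table.loc[table["chrom"] == last, "chrom"] = config.segment_chrom
        sel = table["chrom"] == config.segment_chrom
        pos = table.loc[sel, "pos"].to_numpy().copy()
        lo = int(np.argmin(np.abs(pos - config.segment_start)))
        hi = int(np.argmin(np.abs(pos - config.segment_end)))
        if hi == lo:
            hi = lo + 1
        pos[lo] = config.segment_start
        pos[hi] = config.segment_end
        table.loc[sel, "pos"] = np.sort(pos)
        table.loc[sel, "id"] = [
            f"snp_{config.segment_chrom}_{i:05d}" for i in range(int(sel.sum()))
        ]
    return table


def simulate_cohort(config: SimulationConfig):
    """Simulate a phased panel, array genotypes and cohort table.

    Returns
    -------
    (PhasedPanel, GenotypeMatrix, pandas.DataFrame)
        The cohort table has one row per sample with columns ``id``,
        ``affected``, ``sire_carrier``, ``mgs_carrier``, ``is_mutant_hom``,
        ``n_founder_copies``, ``n_mutant_copies``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    markers = _marker_table(config)
    n, m = config.n_samples, len(markers)
    freqs = config.maf_floor + rng.uniform(0.0, config.maf_range, size=m)

    haps = (rng.random((n, 2, m)) < freqs).astype(np.uint8)
    founder_alleles = (rng.random(m) < freqs).astype(np.uint8)

    founder = np.zeros((n, 2), dtype=bool)
    mutant = np.zeros((n, 2), dtype=bool)
    case_idx = np.arange(config.n_cases)
    founder[case_idx, :] = True
    mutant[case_idx, :] = True
    others = np.arange(config.n_cases, n)
    founder[others] = rng.random((len(others), 2)) < config.haplotype_freq
    mutant[others] = founder[others] & (
        rng.random((len(others), 2)) < config.mutation_on_haplotype
    )
    # the case count is exact by construction: demote accidental mutant
    # homozygotes among the remaining samples to single-copy carriers
    accidental = np.flatnonzero(mutant[others].all(axis=1)) + config.n_cases
    mutant[accidental, 1] = False

    # founder-identical region: segment core plus an erodible marker flank
    chrom, start, end = config.segment_bounds()
    on_chrom = (markers["chrom"].astype(str) == chrom).to_numpy()
    in_core = on_chrom & markers["pos"].between(start, end).to_numpy()
    core_idx = np.flatnonzero(in_core)
    chrom_idx = np.flatnonzero(on_chrom)
    lo_core, hi_core = core_idx[0], core_idx[-1]
    left_flank = chrom_idx[(chrom_idx < lo_core)][-config.flank_markers :]
    right_flank = chrom_idx[(chrom_idx > hi_core)][: config.flank_markers]

    p_geom = 1.0 / (config.edge_erosion_mean + 1.0)
    for s, c in zip(*np.nonzero(founder)):
        erode_l = min(rng.geometric(p_geom) - 1, len(left_flank))
        erode_r = min(rng.geometric(p_geom) - 1, len(right_flank))
        keep = list(core_idx)
        if erode_l < len(left_flank):
            keep = list(left_flank[erode_l:]) + keep
        if erode_r < len(right_flank):
            keep += list(right_flank[: len(right_flank) - erode_r])
        haps[s, c, keep] = founder_alleles[keep]

    geno = haps.sum(axis=1).astype(np.int8)
    if config.array_missing_rate > 0:
        miss = rng.random((n, m)) < config.array_missing_rate
        geno[miss] = MISSING

    samples = [f"S{i:05d}" for i in range(n)]
    panel = PhasedPanel(
        haplotypes=haps,
        founder_copy=founder,
        mutant_copy=mutant,
        markers=markers,
        samples=samples,
        segment=config.segment_bounds(),
        founder_alleles=founder_alleles,
    )
    gm = GenotypeMatrix(geno=geno, markers=markers.copy(), samples=samples)

    is_hom = mutant.all(axis=1)
    # pedigree carrier flags consistent with Mendelian transmission: a mutant
    # paternal copy came from a carrier sire; a mutant maternal copy came from
    # the maternal grandsire with probability 1/2; otherwise flags reflect the
    # background population carrier frequency.
    bg = 2.0 * config.haplotype_freq * config.mutation_on_haplotype
    sire_carrier = mutant[:, 0] | (rng.random(n) < bg)
    mgs_carrier = (mutant[:, 1] & (rng.random(n) < 0.5)) | (rng.random(n) < bg)
    mgs_carrier |= is_hom & sire_carrier  # affected calves arise in risk matings
    cohort = pd.DataFrame(
        {
            "id": samples,
            "affected": is_hom,
            "sire_carrier": sire_carrier,
            "mgs_carrier": mgs_carrier,
            "is_mutant_hom": is_hom,
            "n_founder_copies": founder.sum(axis=1),
            "n_mutant_copies": mutant.sum(axis=1),
        }
    )
    return panel, gm, cohort


_BASES = np.array(list("ACGT"))


def simulate_region_variants(
    config: SimulationConfig,
    panel: PhasedPanel,
    table1_decoys: bool = False,
    rng: np.random.Generator | None = None,
):
    """Simulate sequencing variants in and around the target segment.

    Emits ``seq_region_n_snps`` SNPs and ``seq_region_n_indels`` indels with
    positions inside the segment (one of the SNPs is the planted causal
    record at ``config.causal_pos``, whose genotype equals each sample's
    mutant-copy count), plus ``seq_region_n_outside`` decoy records outside.
    With ``table1_decoys`` three extra in-segment records mimic additional
    recessive-compatible rows.

    Returns a :class:`recmap.varfilter.VariantTable`.
    """
    from .varfilter import VariantTable

    chrom, start, end = config.segment_bounds()
    if (config.segment_chrom, start, end) != panel.segment:
        raise ValueError("panel was simulated with different segment bounds")
    n_snps, n_indels = config.seq_region_n_snps, config.seq_region_n_indels
    if table1_decoys:
        # the three decoys (two SNPs, one indel) count toward the totals
        if n_snps < 3 or n_indels < 1:
            raise ValueError("table1_decoys needs >= 3 SNPs and >= 1 indel")
        n_snps -= 2
        n_indels -= 1
    n_in = n_snps + n_indels
    span = end - start + 1
    if n_in + 3 * table1_decoys > span:
        raise ValueError(
            f"{n_in} in-segment variants requested but only {span} integer "
            f"positions available"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = panel.n_samples

    decoy_pos = np.array([70_679_787, 70_842_696, 71_315_111]) if table1_decoys else np.array([], dtype=int)
    reserved = set(decoy_pos.tolist()) | {config.causal_pos}
    if n_in > 0:
        avail = span - len(reserved)
        if n_in - 1 > avail:
            raise ValueError("not enough free positions inside the segment")
        pool = rng.choice(span, size=min(span, n_in + len(reserved) + 8), replace=False) + start
        pool = [int(p) for p in pool if p not in reserved][: n_in - 1]
        pos_in = np.sort(np.array(pool + [config.causal_pos], dtype=np.int64))
        is_indel = np.zeros(n_in, dtype=bool)
        idx_pool = np.flatnonzero(pos_in != config.causal_pos)
        is_indel[rng.choice(idx_pool, size=n_indels, replace=False)] = True
    else:
        pos_in = np.array([], dtype=np.int64)
        is_indel = np.zeros(0, dtype=bool)

    rows = []
    geno_rows = []
    mut_counts = panel.n_mutant_copies().astype(np.int8)

    def random_genotypes() -> np.ndarray:
        p = rng.uniform(0.05, 0.5)
        return rng.binomial(2, p, size=n).astype(np.int8)

    for pos, indel in zip(pos_in, is_indel):
        if pos == config.causal_pos:
            ref, alt = "G", "A"
            g = mut_counts.copy()
            vid = "causal"
        else:
            if indel:
                ref = "".join(rng.choice(_BASES, size=rng.integers(2, 5)))
                alt = ref[0]
            else:
                ref, alt = rng.choice(_BASES, size=2, replace=False)
            g = random_genotypes()
            vid = f"var_{chrom}_{pos}"
        rows.append((chrom, int(pos), vid, ref, alt, "indel" if indel else "snp"))
        geno_rows.append(g)

    # compatible decoys: hom-alt in mutant homozygotes, het in the other
    # founder-haplotype homozygotes, hom-ref elsewhere -- a pattern the
    # recessive filter cannot distinguish from the causal record
    is_mut_hom = panel.mutant_copy.all(axis=1)
    is_founder_hom = panel.founder_copy.all(axis=1)
    for pos in decoy_pos:
        g = np.where(is_mut_hom, 2, np.where(is_founder_hom, 1, 0)).astype(np.int8)
        ref, alt = ("AC", "A") if pos == decoy_pos[0] else tuple(rng.choice(_BASES, 2, replace=False))
        cls = "indel" if len(ref) != len(alt) else "snp"
        rows.append((chrom, int(pos), f"decoy_{pos}", ref, alt, cls))
        geno_rows.append(g)

    # records outside the segment, on the same chromosome where possible
    out_left = np.arange(max(1, start - config.seq_region_n_outside * 50), start, 50)
    out_pool = out_left[-config.seq_region_n_outside :]
    for pos in out_pool:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        rows.append((chrom, int(pos), f"out_{chrom}_{pos}", ref, alt, "snp"))
        geno_rows.append(random_genotypes())

    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt", "vclass"]
    ).astype({"pos": np.int64})
    order = np.argsort(variants["pos"].to_numpy(), kind="stable")
    variants = variants.iloc[order].reset_index(drop=True)
    geno = (
        np.vstack(geno_rows)[order]
        if geno_rows
        else np.zeros((0, n), dtype=np.int8)
    )
    return VariantTable(variants=variants, geno=geno, samples=list(panel.samples))


def simulate_mating_cohort(
    n_risk: int, n_nonrisk: int, rng: np.random.Generator | int | None = 0
) -> pd.DataFrame:
    """Calves from risk (carrier sire x carrier MGS) and non-risk matings.

    Genotypes follow Mendelian transmission: in a risk mating the calf is a
    mutant homozygote with probability 1/8; in a non-risk mating never.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = n_risk + n_nonrisk
    risk = np.zeros(n, dtype=bool)
    risk[:n_risk] = True
    sire_transmits = np.where(risk, rng.random(n) < 0.5, False)
    dam_is_carrier = rng.random(n) < 0.5  # from the carrier MGS
    dam_transmits = dam_is_carrier & (rng.random(n) < 0.5)
    hom = sire_transmits & dam_transmits
    return pd.DataFrame(
        {
            "id": [f"C{i:05d}" for i in range(n)],
            "sire_carrier": risk,
            "mgs_carrier": True,
            "is_mutant_hom": hom,
        }
    )


def simulate_survival(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival times with an elevated hazard for mutant homs.

    Records are administratively censored at ``config.censor_day``.  Group
    labels come from the pedigree carrier flags: ``risk`` = carrier sire x
    carrier MGS, ``nonrisk`` = non-carrier sire x carrier MGS; calves from
    other matings are excluded.
    """
    if config.hazard_base <= 0 or config.hazard_hom_multiplier <= 0:
        raise ValueError("hazard rates must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    keep = cohort["mgs_carrier"].to_numpy()
    sub = cohort.loc[keep]
    group = np.where(sub["sire_carrier"].to_numpy(), "risk", "nonrisk")
    hazard = config.hazard_base * np.where(
        sub["is_mutant_hom"].to_numpy(), config.hazard_hom_multiplier, 1.0
    )
    t = rng.exponential(1.0 / hazard)
    event = t <= config.censor_day
    t = np.minimum(t, config.censor_day)
    return pd.DataFrame(
        {
            "id": sub["id"].to_numpy(),
            "time": t,
            "event": event,
            "group": group,
        }
    ).reset_index(drop=True)


def calibrate_hazards(
    s_nonrisk: float, s_risk: float, day: float = 300.0, hom_prob: float = 0.125
) -> tuple:
    """Base hazard and homozygote multiplier hitting two target survivals.

    Solves ``exp(-day*h) = s_nonrisk`` and the two-component mixture
    ``(1-hom_prob)*s_nonrisk + hom_prob*exp(-day*h*mult) = s_risk``.
    """
    if not 0 < s_risk < s_nonrisk < 1:
        raise ValueError("need 0 < s_risk < s_nonrisk < 1")
    h = -np.log(s_nonrisk) / day
    s_hom = (s_risk - (1.0 - hom_prob) * s_nonrisk) / hom_prob
    if s_hom <= 0:
        raise ValueError("targets unreachable: homozygote survival would be <= 0")
    mult = -np.log(s_hom) / (day * h)
    return float(h), float(mult)
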