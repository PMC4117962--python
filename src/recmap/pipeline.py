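"""End-to-end orchestration: simulate -> qc -> grm -> gwas -> roh -> haplo
-> filter -> annotate -> survival, with plain-text checkpoints and a JSON
summary."""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grm as grm_mod
from . import io as rio
from . import lmm, qc, roh, survival as surv
from .haplo import call_haplotype_carriers, haplotype_frequency, hwe_exact_test
from .simulate import (
    SimulationConfig,
    calibrate_hazards,
    simulate_cohort,
    simulate_mating_cohort,
    simulate_region_variants,
    simulate_survival,
)
from .varfilter import annotate_consequence, default_cds, recessive_filter, subset_region

log = logging.getLogger("recmap.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "default_demo_config"]


@dataclass
class PipelineConfig:
    """Stage parameters and toggles for one pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    max_missing: float = 0.05
    min_maf: float = 0.005
    gwas_mode: str = "null-delta"
    roh_min_markers: int = 5
    roh_max_het: int = 0
    roh_max_missing: int = 2
    roh_min_length_bp: int = 200_000
    filter_case_mode: str = "hom_alt"
    cds_protein_length: int = 487
    cds_stop_codon: int = 215
    cds_pos: int = 645
    alt_base: str = "A"
    survival_days: tuple = surv.DEFAULT_DAYS
    out_dir: str = "recmap_run"

    def validate(self) -> None:
        self.sim.validate()
        if not 0 <= self.max_missing <= 1 or not 0 <= self.min_maf <= 1:
            raise ValueError("QC thresholds outside [0, 1]")
        if self.gwas_mode not in ("exact", "null-delta"):
            raise ValueError(f"unknown gwas_mode {self.gwas_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["survival_days"] = list(self.survival_days)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_demo_config(out_dir: str = "recmap_demo", seed: int = 0) -> PipelineConfig:
    """Small cohort that runs end-to-end in well under a minute."""
    h, mult = calibrate_hazards(0.903, 0.834, day=300.0)
    sim = SimulationConfig(
        n_samples=300,
        n_markers_per_chrom=300,
        n_chroms=3,
        haplotype_freq=0.05,
        mutation_on_haplotype=0.6,
        n_cases=8,
        seq_region_n_snps=120,
        seq_region_n_indels=15,
        seq_region_n_outside=40,
        hazard_base=h,
        hazard_hom_multiplier=mult,
        n_risk_matings=600,
        n_nonrisk_matings=1200,
        seed=seed,
    )
    return PipelineConfig(sim=sim, out_dir=out_dir)


def _stage(name, t0, **counts):
    log.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0,
             " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order, writing checkpoints under ``out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).  Any
    stage failure propagates with partial outputs left on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.sim.seed}

    t0 = time.time()
    panel, gm, cohort = simulate_cohort(config.sim)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    rio.write_plink_text(gm, out / "array.ped", out / "array.map")
    _stage("simulate", t0, samples=gm.n_samples, markers=gm.n_markers)

    t0 = time.time()
    gm_qc, report = qc.apply_qc(gm, config.max_missing, config.min_maf)
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    _stage("qc", t0, kept=gm_qc.n_markers, removed=report.n_removed)
    summary["qc"] = {"n_input": report.n_input, "n_output": report.n_output}

    t0 = time.time()
    g = grm_mod.compute_grm(gm_qc)
    np.savetxt(out / "grm.tsv", g.matrix, delimiter="\t", fmt="%.6g")
    _stage("grm", t0, markers_used=g.n_markers_used)

    t0 = time.time()
    y = np.where(cohort["affected"].to_numpy(), 1.0, 2.0)
    assoc = lmm.fit_lmm_gwas(y, gm_qc, g, mode=config.gwas_mode)
    assoc.to_csv(out / "gwas.tsv", sep="\t", index=False)
    threshold = lmm.significance_threshold(gm_qc.n_markers)
    top = assoc.loc[assoc["p"].idxmin()]
    summary["gwas"] = {
        "threshold": threshold,
        "n_significant": int((assoc["p"] < threshold).sum()),
        "top_snp": {"id": top["id"], "chrom": str(top["chrom"]),
                    "pos": int(top["pos"]), "p": float(top["p"])},
    }
    _stage("gwas", t0, n_significant=summary["gwas"]["n_significant"])

    t0 = time.time()
    case_ids = cohort.loc[cohort["affected"], "id"].tolist()
    case_rows = gm_qc.sample_index(case_ids)
    case_segments = {
        sid: roh.detect_roh(
            gm_qc.geno[r], gm_qc.markers, sample=sid,
            min_markers=config.roh_min_markers, max_het=config.roh_max_het,
            max_missing=config.roh_max_missing,
            min_length_bp=config.roh_min_length_bp,
        )
        for sid, r in zip(case_ids, case_rows)
    }
    roh.segments_to_frame(case_segments).to_csv(out / "roh.tsv", sep="\t", index=False)
    chrom_hint = (config.sim.segment_chrom, 1, config.sim.chrom_length_bp)
    shared = roh.intersect_case_segments(case_segments, region_hint=chrom_hint)
    if shared is None:
        raise RuntimeError("roh stage: no shared homozygosity segment found")
    controls = [s for s in gm_qc.samples if s not in set(case_ids)]
    hom_controls = roh.find_homozygous_controls(
        gm_qc, shared, control_ids=controls,
        max_het=config.roh_max_het, max_missing=config.roh_max_missing,
    )
    summary["shared_segment"] = {
        "chrom": shared.chrom, "start": shared.start, "end": shared.end,
        "length_bp": shared.length_bp, "length_kb": shared.length_kb,
        "n_homozygous_controls": len(hom_controls),
    }
    _stage("roh", t0, shared_kb=shared.length_kb, hom_controls=len(hom_controls))

    t0 = time.time()
    counts, status = call_haplotype_carriers(panel, panel.founder_segment_alleles())
    status.to_csv(out / "carriers.tsv", sep="\t", index=False)
    summary["haplotype"] = {
        "n_het": counts.n_het, "n_hom": counts.n_hom,
        "frequency": haplotype_frequency(counts),
        "hwe_p": hwe_exact_test(counts),
    }
    _stage("haplo", t0, freq=round(summary["haplotype"]["frequency"], 4))

    t0 = time.time()
    vt = simulate_region_variants(config.sim, panel)
    rio.write_vcf(vt, out / "region.vcf")
    chrom, start, end = config.sim.segment_bounds()
    vt_in, class_counts = subset_region(vt, chrom, start, end)
    # haplotype-homozygous non-affected samples may carry the defect allele
    # once, so they are only required to be non-hom-alt; the strict hom-ref
    # control group holds haplotype non-carriers (het carriers are excluded,
    # as they can legitimately carry one defect allele)
    hap_hom = set(status.loc[status["hom_carrier"], "id"]) - set(case_ids)
    plain_controls = status.loc[
        ~status["carrier"] & ~status["id"].isin(case_ids), "id"
    ].tolist()
    compatible = recessive_filter(
        vt_in, case_ids, sorted(hap_hom), plain_controls,
        case_mode=config.filter_case_mode,
    )
    compatible.variants.to_csv(out / "compatible_variants.tsv", sep="\t", index=False)
    summary["varfilter"] = {
        "n_in_segment": vt_in.n_variants,
        "class_counts": class_counts,
        "compatible": compatible.variants["id"].tolist(),
    }
    _stage("filter", t0, in_segment=vt_in.n_variants,
           compatible=len(summary["varfilter"]["compatible"]))

    t0 = time.time()
    cds = default_cds(config.cds_protein_length, config.cds_stop_codon)
    cons = annotate_consequence(cds, config.cds_pos, config.alt_base)
    summary["consequence"] = {
        "effect": cons.effect, "codon_index": cons.codon_index,
        "ref_codon": cons.ref_codon, "alt_codon": cons.alt_codon,
        "truncated_protein_length": cons.truncated_protein_length,
        "residues_lost": cons.residues_lost,
    }
    _stage("annotate", t0, effect=cons.effect)

    t0 = time.time()
    rng = np.random.default_rng(config.sim.seed + 3)
    matings = simulate_mating_cohort(
        config.sim.n_risk_matings, config.sim.n_nonrisk_matings, rng
    )
    records = simulate_survival(matings, config.sim, rng)
    records.to_csv(out / "survival.tsv", sep="\t", index=False)
    curves = {}
    table = {}
    for grp in ("risk", "nonrisk"):
        t, e = surv.records_by_group(records, grp)
        curves[grp] = surv.kaplan_meier(t, e)
        table[grp] = surv.mortality_table(curves[grp], config.survival_days)
        table[grp].to_csv(out / f"km_{grp}.tsv", sep="\t", index=False)
    chi2, p = surv.logrank_test(
        *surv.records_by_group(records, "risk"),
        *surv.records_by_group(records, "nonrisk"),
    )
    summary["survival"] = {
        "n_risk": int((records["group"] == "risk").sum()),
        "n_nonrisk": int((records["group"] == "nonrisk").sum()),
        "survival_300_risk": surv.survival_at(curves["risk"], 300),
        "survival_300_nonrisk": surv.survival_at(curves["nonrisk"], 300),
        "logrank_chi2": chi2,
        "logrank_p": p,
    }
    _stage("survival", t0, logrank_p=p)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    return summary


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
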