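# recmap

Toolkit for mapping a lethal recessive defect in a livestock population from
SNP-array genotypes, whole-genome sequencing variants and calf survival
records — together with a synthetic-cohort simulator that plants a founder
haplotype carrying a nonsense allele, so the whole analysis is testable
end-to-end against known truth.

The pipeline stages mirror a classical recessive-disease mapping study:

1. **simulate** — phased cohort with a low-frequency founder haplotype, a
   mutant allele on a configurable fraction of its copies, a fixed number of
   affected (mutant-homozygous) samples, array genotypes with missingness,
   region sequencing variants with one planted causal record, and survival
   times for calves from risk vs non-risk matings (`recmap.simulate`).
2. **qc** — marker filters (chromosome class, call rate, minor allele
   frequency) plus a log-R sliding-window intensity screen (`recmap.qc`).
3. **grm** — genomic relationship matrix, VanRaden method 1 (`recmap.grm`).
4. **gwas** — per-SNP linear mixed model with polygenic background; exact
   per-SNP REML (Brent search on the variance ratio in eigen-rotated space)
   or a fast null-delta mode; Bonferroni threshold helper (`recmap.lmm`).
5. **roh** — run-of-homozygosity detection and intersection of case
   segments into the shared disease interval (`recmap.roh`).
6. **haplo** — haplotype carrier calling and statistics: frequency,
   Hardy–Weinberg tests (exact conditional and chi-square), concordance,
   defect-allele frequency, exact risk-mating homozygote probabilities and
   expected affected births (`recmap.haplo`).
7. **filter/annotate** — region subsetting of sequencing variants, the
   recessive-compatibility filter, and stop-gain consequence annotation on
   a CDS (`recmap.varfilter`).
8. **survival** — Kaplan–Meier estimation with Greenwood errors, log-rank
   contrast and day-grid mortality tables (`recmap.survival`).

All coordinates are 1-based inclusive; genotypes are coded 0/1/2 copies of
the counted allele with −1 for missing. Intermediates are plain text
(PLINK-text, VCF v4.2, TSV, JSON).

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests against
independent oracles (dense GLS, exact rational enumeration, full-window
brute force, lifelines/cyvcf2 cross-checks) and `tests/test_acceptance.py`,
which holds the acceptance criteria.

## Command line

```bash
recmap run --out demo --seed 1            # full demo pipeline + summary.json
recmap simulate --out sim --seed 7
recmap qc --ped sim/array.ped --map sim/array.map --out-prefix sim/clean
recmap grm --ped sim/clean.ped --map sim/clean.map --out sim/grm.tsv
recmap roh --ped sim/clean.ped --map sim/clean.map --out sim/roh.tsv
recmap haplo freq --total 10355 --het 380 --hom 3
recmap haplo risk --sire-carrier --mgs-carrier
recmap filter --vcf region.vcf --region 21:70550045-71573501 \
    --cases S00000 --controls S00010,S00011 --out compatible.tsv
recmap annotate --cds cds.fasta --pos 645 --alt A
recmap survival --records survival.tsv --out-prefix km
```

`recmap run` executes simulate → qc → grm → gwas → roh → haplo → filter →
annotate → survival with checkpointed plain-text outputs and a machine-
readable `summary.json`; on the bundled demo configuration the
recessive-compatibility filter recovers exactly the planted causal variant.

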