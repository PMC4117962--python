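"""Standard-format input/output: PLINK-text, VCF and TSV.

All intermediates are plain text so every pipeline stage can be inspected
and replaced independently.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .varfilter import VariantTable

__all__ = [
    "read_plink_text",
    "write_plink_text",
    "read_vcf",
    "write_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
]

_PED_META_COLS = 6


def write_plink_text(
    gm: GenotypeMatrix, ped_path, map_path, phenotypes=None
) -> None:
    """Write .ped/.map with A (reference) / B (counted) allele coding."""
    alleles = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    pheno = phenotypes if phenotypes is not None else [-9] * gm.n_samples
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.samples):
            calls = " ".join(alleles[int(g)] for g in gm.geno[i])
            fh.write(f"FAM {sid} 0 0 0 {pheno[i]} {calls}\n")
    with open(map_path, "w") as fh:
        for _, row in gm.markers.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")


def read_plink_text(ped_path, map_path) -> tuple:
    """Parse PLINK-text files into a genotype matrix plus family metadata.

    Genotypes count copies of the 'B' allele when markers use A/B coding,
    otherwise copies of the lexicographically larger observed allele.
    Raises with a line number on ragged or unparsable rows.
    """
    markers = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, mid, _, pos = parts
            elif len(parts) == 3:
                chrom, mid, pos = parts
            else:
                raise ValueError(f"{map_path}:{ln}: expected 3 or 4 columns")
            try:
                markers.append((mid, chrom, int(pos)))
            except ValueError:
                raise ValueError(f"{map_path}:{ln}: bad position {pos!r}") from None
    marker_df = pd.DataFrame(markers, columns=["id", "chrom", "pos"])
    m = len(marker_df)

    samples, meta_rows, allele_rows = [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != _PED_META_COLS + 2 * m:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {_PED_META_COLS + 2 * m} "
                    f"fields, found {len(parts)}"
                )
            meta_rows.append(parts[:_PED_META_COLS])
            samples.append(parts[1])
            allele_rows.append(parts[_PED_META_COLS:])
    if not samples:
        raise ValueError(f"{ped_path}: no samples found")
    fam = pd.DataFrame(
        meta_rows, columns=["fid", "iid", "pat", "mat", "sex", "phenotype"]
    )
    alleles = np.array(allele_rows).reshape(len(samples), m, 2)

    geno = np.empty((len(samples), m), dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        seen = sorted(set(col.ravel()) - {"0"})
        if len(seen) > 2:
            raise ValueError(
                f"{ped_path}: marker {marker_df['id'][j]} has >2 alleles {seen}"
            )
        counted = "B" if set(seen) <= {"A", "B"} else (seen[-1] if seen else "B")
        miss = (col == "0").any(axis=1)
        geno[:, j] = np.where(miss, MISSING, (col == counted).sum(axis=1))
    return GenotypeMatrix(geno=geno, markers=marker_df, samples=samples), fam


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_STRINGS_PHASED = {0: "0|0", 2: "1|1", MISSING: ".|."}


def write_vcf(vt: VariantTable, path) -> None:
    """Minimal VCF v4.2 with a GT field; phase separators are written when
    allele-level calls are attached to the table."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(vt.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in vt.samples)
            + "\n"
        )
        for i, row in vt.variants.iterrows():
            if vt.alleles is not None:
                gts = []
                for k in range(len(vt.samples)):
                    a = vt.alleles[i, k]
                    sep = "|" if (vt.phased is not None and vt.phased[i, k]) else "/"
                    gts.append(
                        sep.join("." if x < 0 else str(int(x)) for x in a)
                    )
            else:
                gts = [_GT_STRINGS[int(g)] for g in vt.geno[i]]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path, region: tuple | None = None, multiallelic: str = "error") -> VariantTable:
    """Read a VCF (v4.x, GT field required) into a variant table.

    ``region`` is an optional ``(chrom, start, end)`` 1-based inclusive
    filter.  Multi-allelic records are rejected (default) or skipped per
    ``multiallelic``.  Phased ("|") and unphased ("/") calls are both
    accepted; phase flags are preserved on the returned table.
    """
    if multiallelic not in ("error", "skip"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    rows, geno_rows, allele_rows, phased_rows = [], [], [], []
    samples = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10 or cols[8] != "FORMAT" and "FORMAT" not in cols:
                    raise ValueError(f"{path}:{ln}: header lacks FORMAT/samples")
                samples = cols[9:]
                continue
            if samples is None:
                raise ValueError(f"{path}: missing #CHROM header line")
            fields = line.split("\t")
            chrom, pos, vid, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise ValueError(f"{path}:{ln}: record has no GT field")
            gt_idx = fmt.index("GT")
            if "," in alt:
                if multiallelic == "skip":
                    continue
                raise ValueError(
                    f"{path}:{ln}: multi-allelic record at {chrom}:{pos}"
                )
            if region is not None:
                c0, a0, b0 = region
                if str(chrom) != str(c0) or not a0 <= pos <= b0:
                    continue
            g_row, a_row, p_row = [], [], []
            for s in fields[9:]:
                gt = s.split(":")[gt_idx]
                phased = "|" in gt
                parts = gt.replace("|", "/").split("/")
                try:
                    a = [-1 if x in (".", "") else int(x) for x in parts]
                except ValueError:
                    raise ValueError(f"{path}:{ln}: bad GT {gt!r}") from None
                if len(a) == 1:
                    a = [a[0], a[0]]
                g_row.append(MISSING if min(a) < 0 else sum(1 for x in a if x > 0))
                a_row.append(a[:2])
                p_row.append(phased)
            vclass = "indel" if len(ref) != len(alt) else "snp"
            rows.append((str(chrom), pos, vid, ref, alt, vclass))
            geno_rows.append(g_row)
            allele_rows.append(a_row)
            phased_rows.append(p_row)
    if samples is None:
        raise ValueError(f"{path}: missing #CHROM header line")
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt", "vclass"]
    )
    n = len(samples)
    return VariantTable(
        variants=variants,
        geno=np.array(geno_rows, dtype=np.int8).reshape(len(rows), n),
        samples=samples,
        alleles=np.array(allele_rows, dtype=np.int8).reshape(len(rows), n, 2),
        phased=np.array(phased_rows, dtype=bool).reshape(len(rows), n),
    )


def write_genotype_tsv(gm: GenotypeMatrix, geno_path, marker_path) -> None:
    """Sample-by-marker genotype TSV plus a marker metadata TSV."""
    df = pd.DataFrame(gm.geno, index=gm.samples, columns=gm.markers["id"])
    df.index.name = "sample"
    df.to_csv(geno_path, sep="\t")
    gm.markers.to_csv(marker_path, sep="\t", index=False)


def read_genotype_tsv(geno_path, marker_path) -> GenotypeMatrix:
    df = pd.read_csv(geno_path, sep="\t", index_col=0)
    markers = pd.read_csv(marker_path, sep="\t", dtype={"chrom": str})
    if list(df.columns) != list(markers["id"].astype(str)):
        raise ValueError("marker ids disagree between genotype and marker tables")
    geno = df.to_numpy()
    geno = np.where(pd.isna(geno), MISSING, geno).astype(np.int8)
    return GenotypeMatrix(geno=geno, markers=markers, samples=list(df.index))
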