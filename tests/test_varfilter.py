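import numpy as np
import pandas as pd
import pytest

from recmap.genotypes import MISSING
from recmap.varfilter import (
    CdsModel,
    VariantTable,
    annotate_consequence,
    default_cds,
    recessive_filter,
    subset_region,
)


def make_vt(geno, positions=None, chrom="21", classes=None, samples=None):
    geno = np.asarray(geno, dtype=np.int8)
    nv, ns = geno.shape
    if positions is None:
        positions = np.arange(1, nv + 1) * 100
    if classes is None:
        classes = ["snp"] * nv
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"v{i}" for i in range(nv)],
            "ref": ["A" if c == "snp" else "AT" for c in classes],
            "alt": ["G" if c == "snp" else "A" for c in classes],
            "vclass": classes,
        }
    )
    if samples is None:
        samples = [f"s{i}" for i in range(ns)]
    return VariantTable(variants=variants, geno=geno, samples=samples)


class TestSubsetRegion:
    def test_inclusive_boundaries(self):
        vt = make_vt(np.zeros((4, 2)), positions=[99, 100, 400, 401])
        sub, counts = subset_region(vt, "21", 100, 400)
        assert list(sub.variants["pos"]) == [100, 400]
        assert counts == {"snp": 2, "indel": 0}

    def test_empty_overlap(self):
        vt = make_vt(np.zeros((2, 2)), positions=[10, 20])
        sub, counts = subset_region(vt, "21", 1000, 2000)
        assert sub.n_variants == 0

    def test_wrong_chrom_excluded(self):
        vt = make_vt(np.zeros((2, 2)), positions=[10, 20], chrom="1")
        sub, _ = subset_region(vt, "21", 1, 100)
        assert sub.n_variants == 0

    def test_class_counts_partition(self):
        vt = make_vt(np.zeros((5, 2)), classes=["snp", "indel", "snp", "indel", "snp"])
        sub, counts = subset_region(vt, "21", 1, 10_000)
        assert counts["snp"] + counts["indel"] == sub.n_variants == 5

    def test_invalid_interval(self):
        vt = make_vt(np.zeros((1, 1)))
        with pytest.raises(ValueError):
            subset_region(vt, "21", 10, 5)


def brute_force_filter(vt, cases, hap_homs, controls, case_mode, missing_policy):
    """Independent per-sample triple-loop oracle."""
    keep = []
    for i in range(vt.n_variants):
        g = {s: vt.geno[i, j] for j, s in enumerate(vt.samples)}
        ok = True
        for s in cases:
            v = g[s]
            if v == MISSING:
                ok = ok and missing_policy == "permissive"
            elif case_mode == "hom_alt":
                ok = ok and v == 2
            else:
                ok = ok and v in (1, 2)
        for s in hap_homs:
            v = g[s]
            if v == MISSING:
                ok = ok and missing_policy == "permissive"
            else:
                ok = ok and v in (0, 1)
        for s in controls:
            v = g[s]
            if v == MISSING:
                ok = ok and missing_policy == "permissive"
            else:
                ok = ok and v == 0
        if ok:
            keep.append(i)
    return keep


class TestRecessiveFilter:
    def test_table_pattern_fixture(self):
        # 1 case, 1 haplotype-hom control, 41 plain controls; 200 records of
        # which exactly 4 follow the compatible pattern
        rng = np.random.default_rng(0)
        n_samples = 43
        geno = rng.binomial(2, 0.3, size=(200, n_samples)).astype(np.int8)
        compatible_rows = [7, 50, 120, 199]
        for r in compatible_rows:
            geno[r, 0] = 2                      # case hom-alt
            geno[r, 1] = rng.integers(0, 2)     # hap-hom control: ref or het
            geno[r, 2:] = 0                     # plain controls hom-ref
        # make sure no other row is compatible by chance
        for r in range(200):
            if r not in compatible_rows and geno[r, 0] == 2 and (geno[r, 2:] == 0).all():
                geno[r, 2] = 1
        vt = make_vt(geno)
        out = recessive_filter(vt, ["s0"], ["s1"], [f"s{i}" for i in range(2, 43)])
        assert list(out.variants["id"]) == [f"v{r}" for r in compatible_rows]

    def test_hom_ref_everywhere_excluded(self):
        vt = make_vt(np.zeros((1, 5)))
        out = recessive_filter(vt, ["s0"], [], ["s1", "s2"])
        assert out.n_variants == 0

    @pytest.mark.parametrize("case_mode", ["hom_alt", "segregating"])
    @pytest.mark.parametrize("missing_policy", ["strict", "permissive"])
    def test_matches_triple_loop_oracle(self, case_mode, missing_policy):
        rng = np.random.default_rng(3)
        geno = rng.choice([0, 1, 2, MISSING], size=(100, 10),
                          p=[0.5, 0.2, 0.2, 0.1]).astype(np.int8)
        vt = make_vt(geno)
        cases, hap, ctl = ["s0", "s1"], ["s2"], ["s3", "s4", "s5"]
        out = recessive_filter(vt, cases, hap, ctl, case_mode=case_mode,
                               missing_policy=missing_policy)
        expect = brute_force_filter(vt, cases, hap, ctl, case_mode, missing_policy)
        assert list(out.variants["id"]) == [f"v{i}" for i in expect]

    def test_segregating_mode_admits_het_case(self):
        geno = np.array([[1, 0, 0]], dtype=np.int8)
        vt = make_vt(geno)
        assert recessive_filter(vt, ["s0"], [], ["s1", "s2"],
                                case_mode="hom_alt").n_variants == 0
        assert recessive_filter(vt, ["s0"], [], ["s1", "s2"],
                                case_mode="segregating").n_variants == 1

    def test_anti_monotone_in_controls(self):
        rng = np.random.default_rng(4)
        geno = rng.choice([0, 1, 2], size=(80, 8)).astype(np.int8)
        vt = make_vt(geno)
        small = recessive_filter(vt, ["s0"], [], ["s1", "s2"])
        large = recessive_filter(vt, ["s0"], [], ["s1", "s2", "s3", "s4"])
        assert set(large.variants["id"]) <= set(small.variants["id"])

    def test_overlapping_groups_rejected(self):
        vt = make_vt(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="overlap"):
            recessive_filter(vt, ["s0"], ["s0"], ["s1"])

    def test_unknown_sample_rejected(self):
        vt = make_vt(np.zeros((1, 3)))
        with pytest.raises(KeyError):
            recessive_filter(vt, ["nope"], [], ["s1"])


class TestCdsModel:
    def test_default_cds_structure(self):
        cds = default_cds(487, 215)
        assert len(cds) == (487 + 1) * 3
        assert cds.protein_length == 487
        assert cds.codon(215) == "TGG"
        assert len(cds.translate()) == 487

    @pytest.mark.parametrize("seq", [
        "ATGTA",            # not divisible by 3
        "TTGAAATAA",        # no ATG start
        "ATGAAA",           # no stop end
        "ATGNNNTAA",        # bad characters
    ])
    def test_invalid_sequences(self, seq):
        with pytest.raises(ValueError):
            CdsModel(seq)


class TestAnnotateConsequence:
    def test_stop_gain_at_645(self):
        cds = default_cds(487, 215)
        cons = annotate_consequence(cds, 645, "A")
        assert cons.codon_index == 215
        assert (cons.ref_codon, cons.alt_codon) == ("TGG", "TGA")
        assert cons.effect == "stop_gain"
        assert cons.truncated_protein_length == 214

    def test_residues_lost(self):
        cds = default_cds(487, 215)
        cons = annotate_consequence(cds, 645, "A")
        assert cons.residues_lost == 273

    def test_truncation_roundtrip(self):
        # translating the mutated CDS stops exactly at the truncated length
        cds = default_cds(100, 40)
        cons = annotate_consequence(cds, 40 * 3, "A")
        assert cons.effect == "stop_gain"
        from Bio.Seq import Seq

        mutated = cds.seq[: 40 * 3 - 1] + "A" + cds.seq[40 * 3 :]
        prot = str(Seq(mutated).translate(to_stop=True))
        assert len(prot) == cons.truncated_protein_length

    def test_synonymous_third_position(self):
        cds = CdsModel("ATG" + "GGG" + "TAA")
        cons = annotate_consequence(cds, 6, "A")  # GGG -> GGA, both Gly
        assert cons.effect == "synonymous"

    def test_missense(self):
        cds = CdsModel("ATG" + "GCT" + "TAA")  # Ala
        cons = annotate_consequence(cds, 4, "A")  # GCT -> ACT = Thr
        assert cons.effect == "missense"
        assert (cons.ref_aa, cons.alt_aa) == ("A", "T")

    def test_codon_index_formula(self):
        cds = default_cds(50, 10)
        for pos, expect in [(1, 1), (3, 1), (4, 2), (645 % 150, (645 % 150 + 2) // 3)]:
            if pos <= len(cds.seq):
                ref = cds.seq[pos - 1]
                alt = "A" if ref != "A" else "C"
                cons = annotate_consequence(cds, pos, alt)
                assert cons.codon_index == -(-pos // 3)

    def test_errors(self):
        cds = default_cds(10, 5)
        with pytest.raises(ValueError, match="outside"):
            annotate_consequence(cds, 999, "A")
        with pytest.raises(ValueError, match="equals"):
            annotate_consequence(cds, 1, "A")  # ref at pos 1 is A
        with pytest.raises(ValueError, match="invalid"):
            annotate_consequence(cds, 2, "Z")


class TestVariantTable:
    def test_vclass_consistency_enforced(self):
        variants = pd.DataFrame(
            {"chrom": ["1"], "pos": [10], "id": ["v"], "ref": ["AT"],
             "alt": ["A"], "vclass": ["snp"]}
        )
        with pytest.raises(ValueError, match="vclass"):
            VariantTable(variants=variants, geno=np.zeros((1, 1), dtype=np.int8),
                         samples=["s"])
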