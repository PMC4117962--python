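import numpy as np
import pandas as pd
import pytest

from recmap.genotypes import MISSING
from recmap.roh import (
    RohSegment,
    detect_roh,
    find_homozygous_controls,
    intersect_case_segments,
    segments_to_frame,
)

from conftest import make_gm


def marker_frame(positions, chrom="1"):
    return pd.DataFrame(
        {"id": [f"m{i}" for i in range(len(positions))], "chrom": chrom,
         "pos": positions}
    )


def brute_force_runs(calls, max_het, max_missing):
    """Enumerate every (i, j) window, keep feasible maximal ones."""
    n = len(calls)
    hom = [c in (0, 2) for c in calls]
    feasible = []
    for i in range(n):
        if not hom[i]:
            continue
        for j in range(i, n):
            if not hom[j]:
                continue
            window = calls[i : j + 1]
            if (
                sum(1 for c in window if c == 1) <= max_het
                and sum(1 for c in window if c == MISSING) <= max_missing
            ):
                feasible.append((i, j))
    return {
        (i, j)
        for (i, j) in feasible
        if not any(
            (a <= i and j <= b and (a, b) != (i, j)) for (a, b) in feasible
        )
    }


class TestDetectRoh:
    def test_all_het_empty(self):
        calls = np.ones(50, dtype=np.int8)
        assert detect_roh(calls, marker_frame(range(1, 51)),
                          min_markers=1, min_length_bp=1) == []

    def test_planted_run_exact_boundaries(self):
        calls = np.ones(300, dtype=np.int8)
        calls[50:250] = 0  # 200-marker homozygous run
        pos = np.arange(300) * 10_000 + 1
        segs = detect_roh(calls, marker_frame(pos), min_markers=20,
                          max_het=0, max_missing=2, min_length_bp=500_000)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (pos[50], pos[249])
        assert segs[0].n_markers == 200

    def test_interior_het_budget(self):
        calls = np.ones(120, dtype=np.int8)
        calls[10:110] = 2
        calls[60] = 1
        pos = np.arange(120) * 10_000 + 1
        two = detect_roh(calls, marker_frame(pos), min_markers=10, max_het=0,
                         max_missing=2, min_length_bp=100_000)
        assert len(two) == 2
        one = detect_roh(calls, marker_frame(pos), min_markers=10, max_het=1,
                         max_missing=2, min_length_bp=100_000)
        assert len(one) == 1
        assert one[0].n_het == 1

    def test_run_cannot_end_on_het_or_missing(self):
        calls = np.array([1, 0, 0, 0, MISSING, 1], dtype=np.int8)
        segs = detect_roh(calls, marker_frame(range(1, 7)), min_markers=1,
                          max_het=0, max_missing=2, min_length_bp=1)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (2, 4)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        calls = rng.choice(
            [0, 1, 2, MISSING], size=n, p=[0.35, 0.25, 0.3, 0.1]
        ).astype(np.int8)
        max_het = int(rng.integers(0, 3))
        max_missing = int(rng.integers(0, 3))
        pos = np.arange(1, n + 1)
        segs = detect_roh(calls, marker_frame(pos), min_markers=1,
                          max_het=max_het, max_missing=max_missing,
                          min_length_bp=1)
        got = {(s.start - 1, s.end - 1) for s in segs}
        assert got == brute_force_runs(list(calls), max_het, max_missing)

    def test_reported_segments_verified_by_rescan(self, small_cohort):
        panel, gm, _ = small_cohort
        for i in range(0, 20):
            segs = detect_roh(gm.geno[i], gm.markers, sample=gm.samples[i],
                              min_markers=5, max_het=0, max_missing=2,
                              min_length_bp=100_000)
            for s in segs:
                sel = (gm.markers["chrom"].astype(str) == s.chrom) & gm.markers[
                    "pos"
                ].between(s.start, s.end)
                window = gm.geno[i, sel.to_numpy()]
                assert (window == 1).sum() == 0
                assert (window == MISSING).sum() <= 2
                assert window[0] in (0, 2) and window[-1] in (0, 2)

    def test_unsorted_error(self):
        mk = marker_frame([5, 1, 3])
        with pytest.raises(ValueError, match="sorted"):
            detect_roh(np.zeros(3, dtype=np.int8), mk, min_markers=1,
                       min_length_bp=1)


def seg(sample, start, end, chrom="1"):
    return RohSegment(sample=sample, chrom=chrom, start=start, end=end,
                      n_markers=max(1, (end - start) // 1000), n_het=0,
                      n_missing=0)


def brute_force_intersection(case_segments):
    points = sorted(
        {p for segs in case_segments.values() for s in segs
         for p in (s.start, s.end)}
    )
    best = None
    for a in points:
        for b in points:
            if a > b:
                continue
            if all(
                any(s.start <= a and b <= s.end for s in segs)
                for segs in case_segments.values()
            ):
                if best is None or b - a > best[1] - best[0]:
                    best = (a, b)
    return best


class TestIntersection:
    def test_identical_intervals(self):
        cases = {f"c{i}": [seg(f"c{i}", 100, 900)] for i in range(3)}
        sh = intersect_case_segments(cases)
        assert (sh.start, sh.end) == (100, 900)

    def test_three_case_example(self):
        cases = {
            "a": [seg("a", 100, 900)],
            "b": [seg("b", 300, 1200)],
            "c": [seg("c", 50, 700)],
        }
        sh = intersect_case_segments(cases)
        assert (sh.start, sh.end) == (300, 700)

    def test_no_overlap_returns_none(self):
        cases = {"a": [seg("a", 1, 10)], "b": [seg("b", 20, 30)]}
        assert intersect_case_segments(cases) is None

    def test_case_without_segments_returns_none(self):
        cases = {"a": [seg("a", 1, 10)], "b": []}
        assert intersect_case_segments(cases) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_breakpoint_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        cases = {}
        for c in range(int(rng.integers(2, 5))):
            segs = []
            for _ in range(int(rng.integers(1, 4))):
                a = int(rng.integers(0, 500))
                segs.append(seg(f"c{c}", a, a + int(rng.integers(10, 400))))
            cases[f"c{c}"] = segs
        sh = intersect_case_segments(cases)
        expected = brute_force_intersection(cases)
        if expected is None:
            assert sh is None
        else:
            assert sh.end - sh.start == expected[1] - expected[0]

    def test_monotone_adding_case_shrinks(self):
        rng = np.random.default_rng(77)
        cases = {}
        prev_len = None
        for c in range(5):
            a = int(rng.integers(0, 200))
            cases[f"c{c}"] = [seg(f"c{c}", a, a + 500)]
            sh = intersect_case_segments(cases)
            if sh is None:
                prev_len = -1
                continue
            if prev_len is not None and prev_len >= 0:
                assert sh.length_bp <= prev_len
            prev_len = sh.length_bp

    def test_paper_coordinates_fixture(self):
        # 8 cases homozygous around the printed bounds, eroded at the edges;
        # markers every ~10 kb with anchors at the exact bounds
        start, end = 70_550_045, 71_573_501
        pos = np.unique(
            np.concatenate(
                [np.arange(70_300_000, 71_800_000, 10_000), [start, end]]
            )
        )
        mk = marker_frame(pos, chrom="21")
        rng = np.random.default_rng(8)
        cases = {}
        i0 = int(np.where(pos == start)[0][0])
        i1 = int(np.where(pos == end)[0][0])
        for k in range(8):
            lo = i0 if k == 0 else i0 - int(rng.integers(0, 10))
            hi = i1 if k == 1 else i1 + int(rng.integers(0, 10))
            calls = np.ones(pos.size, dtype=np.int8)
            calls[lo : hi + 1] = 0
            cases[f"case{k}"] = detect_roh(
                calls, mk, sample=f"case{k}", min_markers=20, max_het=0,
                max_missing=2, min_length_bp=500_000,
            )
        sh = intersect_case_segments(cases)
        assert (sh.start, sh.end) == (start, end)
        assert sh.length_bp == 1_023_457
        assert sh.length_kb == 1023


class TestHomozygousControls:
    def _shared(self):
        from recmap.roh import SharedSegment

        return SharedSegment(chrom="1", start=3_000, end=6_000)

    def test_control_identical_to_case_listed(self):
        geno = np.zeros((2, 8), dtype=np.int8)
        geno[1, :] = 0
        gm = make_gm(geno, positions=np.arange(1, 9) * 1000)
        out = find_homozygous_controls(gm, self._shared(), ["S00001"])
        assert out == ["S00001"]

    def test_het_in_segment_excluded(self):
        geno = np.zeros((1, 8), dtype=np.int8)
        geno[0, 4] = 1  # pos 5000, inside segment
        gm = make_gm(geno, positions=np.arange(1, 9) * 1000)
        assert find_homozygous_controls(gm, self._shared(), max_het=0) == []

    def test_simulator_cross_check(self, small_config, small_cohort):
        panel, gm, cohort = small_cohort
        from recmap.roh import SharedSegment

        shared = SharedSegment(
            chrom=small_config.segment_chrom,
            start=small_config.segment_start,
            end=small_config.segment_end,
        )
        got = set(find_homozygous_controls(gm, shared, max_het=0, max_missing=2))
        # independent vectorized scan
        sel = (
            (gm.markers["chrom"].astype(str) == shared.chrom)
            & gm.markers["pos"].between(shared.start, shared.end)
        ).to_numpy()
        window = gm.geno[:, sel]
        expect = ((window == 1).sum(axis=1) == 0) & (
            (window == MISSING).sum(axis=1) <= 2
        )
        assert got == {gm.samples[i] for i in np.flatnonzero(expect)}
        # founder homozygotes (no het possible in segment) must be included
        founder_hom = panel.founder_copy.all(axis=1)
        hom_ids = {gm.samples[i] for i in np.flatnonzero(founder_hom)}
        missing_heavy = {
            gm.samples[i]
            for i in np.flatnonzero((window == MISSING).sum(axis=1) > 2)
        }
        assert hom_ids - missing_heavy <= got


def test_segments_to_frame_roundtrip():
    segs = [seg("a", 10, 20), seg("b", 5, 8)]
    df = segments_to_frame(segs)
    assert list(df["length_bp"]) == [11, 4]
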