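"""Run-of-homozygosity detection and case-segment intersection.

Coordinates are 1-based inclusive; segment boundaries are the positions of
the first and last marker in a run, and lengths are ``end - start + 1``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "RohSegment",
    "SharedSegment",
    "detect_roh",
    "detect_roh_matrix",
    "intersect_case_segments",
    "find_homozygous_controls",
    "segments_to_frame",
]


@dataclass(frozen=True)
class RohSegment:
    sample: str
    chrom: str
    start: int
    end: int
    n_markers: int
    n_het: int
    n_missing: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class SharedSegment:
    chrom: str
    start: int
    end: int
    carriers: list = field(default_factory=list)
    homozygous_controls: list = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> int:
        return round(self.length_bp / 1000)


_HOM = (0, 2)


def _runs_one_chrom(calls: np.ndarray, max_het: int, max_missing: int):
    """Maximal index intervals [i, j] with hom endpoints and bounded interior
    het / missing counts.  Two-pointer scan; j is non-decreasing in i, and
    only runs extending the previous end are kept (no containment)."""
    n = calls.size
    is_het = calls == 1
    is_mis = calls == MISSING
    is_hom = ~is_het & ~is_mis
    runs = []
    j = -1
    het = mis = 0
    last_end = -1
    for i in range(n):
        if i > 0:
            # window now starts at i: drop marker i-1 from the counts
            if j >= i - 1:
                het -= int(is_het[i - 1])
                mis -= int(is_mis[i - 1])
            else:
                j = i - 1
                het = mis = 0
        if not is_hom[i]:
            continue
        while j + 1 < n and het + int(is_het[j + 1]) <= max_het and mis + int(
            is_mis[j + 1]
        ) <= max_missing:
            j += 1
            het += int(is_het[j])
            mis += int(is_mis[j])
        # trim the right end down to the last hom call
        end = j
        while end > i and not is_hom[end]:
            end -= 1
        if end > last_end:
            sub_het = int(is_het[i : end + 1].sum())
            sub_mis = int(is_mis[i : end + 1].sum())
            runs.append((i, end, sub_het, sub_mis))
            last_end = end
    return runs


def detect_roh(
    calls: np.ndarray,
    markers: pd.DataFrame,
    sample: str = "",
    min_markers: int = 20,
    max_het: int = 0,
    max_missing: int = 2,
    min_length_bp: int = 500_000,
) -> list:
    """Runs of homozygosity for one sample.

    ``calls`` must be ordered by (chrom, pos); runs cannot start or end on a
    heterozygous or missing call and must satisfy the marker-count, het,
    missing and length thresholds.
    """
    calls = np.asarray(calls)
    if calls.size != len(markers):
        raise ValueError("calls / marker table length mismatch")
    chroms = markers["chrom"].astype(str).to_numpy()
    pos = markers["pos"].to_numpy()
    segments = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"markers on chrom {chrom} are not sorted by pos")
        for i, j, het, mis in _runs_one_chrom(calls[idx], max_het, max_missing):
            n_markers = j - i + 1
            start, end = int(p[i]), int(p[j])
            if n_markers < min_markers or end - start + 1 < min_length_bp:
                continue
            segments.append(
                RohSegment(
                    sample=sample,
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    n_markers=n_markers,
                    n_het=het,
                    n_missing=mis,
                )
            )
    return segments


def detect_roh_matrix(gm: GenotypeMatrix, **kwargs) -> dict:
    """ROH segments for every sample of a genotype matrix."""
    return {
        s: detect_roh(gm.geno[i], gm.markers, sample=s, **kwargs)
        for i, s in enumerate(gm.samples)
    }


def intersect_case_segments(
    case_segments: dict, region_hint: tuple | None = None
) -> SharedSegment | None:
    """Longest interval contained in >= 1 segment of every case.

    ``case_segments`` maps case id -> list of RohSegment.  ``region_hint``
    is an optional ``(chrom, start, end)`` restriction.  Returns ``None``
    when no common interval exists; adding a case can only shrink (or keep)
    the result.
    """
    if not case_segments:
        return None
    # candidate pieces, each contained in one segment of every case seen so
    # far; per-case segments are NOT merged, so a piece never spans two
    # overlapping segments of the same case
    pieces = None
    for sample, segs in case_segments.items():
        ivals = [(str(s.chrom), s.start, s.end) for s in segs]
        if region_hint is not None:
            c0, a0, b0 = region_hint
            ivals = [
                (c, max(a, a0), min(b, b0))
                for c, a, b in ivals
                if c == str(c0) and max(a, a0) <= min(b, b0)
            ]
        ivals = _prune(ivals)
        if pieces is None:
            pieces = ivals
        else:
            pieces = _prune(
                [
                    (cx, max(ax, ay), min(bx, by))
                    for cx, ax, bx in pieces
                    for cy, ay, by in ivals
                    if cx == cy and max(ax, ay) <= min(bx, by)
                ]
            )
        if not pieces:
            return None
    best = max(pieces, key=lambda iv: iv[2] - iv[1])
    return SharedSegment(
        chrom=str(best[0]), start=int(best[1]), end=int(best[2]),
        carriers=sorted(case_segments),
    )


def _prune(ivals):
    """Drop intervals contained in another interval of the list."""
    ivals = sorted(set(ivals))
    out = []
    for c, a, b in ivals:
        if not any(
            cc == c and aa <= a and b <= bb and (aa, bb) != (a, b)
            for cc, aa, bb in ivals
        ):
            out.append((c, a, b))
    return out


def find_homozygous_controls(
    gm: GenotypeMatrix,
    shared: SharedSegment,
    control_ids: list | None = None,
    max_het: int = 0,
    max_missing: int = 2,
) -> list:
    """Controls homozygous across all markers inside the shared segment,
    with the same het / missing allowances as ROH detection."""
    if shared is None:
        raise ValueError("shared segment is empty")
    sel = (gm.markers["chrom"].astype(str) == shared.chrom) & gm.markers[
        "pos"
    ].between(shared.start, shared.end)
    idx = np.flatnonzero(sel.to_numpy())
    if control_ids is None:
        control_ids = gm.samples
    rows = gm.sample_index(control_ids)
    out = []
    for sid, r in zip(control_ids, rows):
        calls = gm.geno[r, idx]
        n_het = int((calls == 1).sum())
        n_mis = int((calls == MISSING).sum())
        if n_het <= max_het and n_mis <= max_missing:
            out.append(sid)
    return out


def segments_to_frame(segments) -> pd.DataFrame:
    """Flat table of segments; coordinates stay 1-based inclusive."""
    if isinstance(segments, dict):
        segments = [s for v in segments.values() for s in v]
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "length_bp": s.length_bp,
                "n_markers": s.n_markers,
                "n_het": s.n_het,
                "n_missing": s.n_missing,
            }
            for s in segments
        ]
    )


def write_bed(segments, path) -> None:
    """True BED (0-based half-open) conversion of 1-based inclusive runs."""
    df = segments_to_frame(segments)
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"] - 1,
            "end": df["end"],
            "name": df["sample"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
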