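"""SNP-array marker quality control.

Three marker filters (chromosome class, call rate, minor allele frequency)
and a sliding-window mean over signal-intensity (log-R) tracks.  Filters
flag failures independently; :func:`apply_qc` removes the union and reports
both per-filter and union counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, minor_allele_frequencies

__all__ = [
    "QcReport",
    "filter_chromosome_class",
    "filter_call_rate",
    "filter_maf",
    "apply_qc",
    "logr_sliding_window",
    "mean_impute",
]

REMOVED_CLASSES = ("MT", "Y", "unknown")


@dataclass
class QcReport:
    """Bookkeeping for one QC pass."""

    n_input: int
    n_removed_by_class: dict
    n_output: int
    fail: np.ndarray  # per-input-marker flag

    def __post_init__(self) -> None:
        if self.n_output != self.n_input - int(np.asarray(self.fail).sum()):
            raise ValueError("n_output inconsistent with fail flags")
        if any(v < 0 for v in self.n_removed_by_class.values()):
            raise ValueError("negative removal count")

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_output

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.n_removed_by_class.items()]
        rows += [("removed_total", self.n_removed), ("output", self.n_output)]
        return pd.DataFrame(rows, columns=["item", "count"])


def filter_chromosome_class(gm: GenotypeMatrix):
    """Drop mitochondrial, Y-chromosomal and unknown-position markers."""
    classes = gm.chromosome_classes()
    fail = np.isin(classes, REMOVED_CLASSES)
    report = QcReport(
        n_input=gm.n_markers,
        n_removed_by_class={c: int((classes == c).sum()) for c in REMOVED_CLASSES},
        n_output=int((~fail).sum()),
        fail=fail,
    )
    return gm.take_markers(~fail), report


def filter_call_rate(gm: GenotypeMatrix, max_missing: float = 0.05):
    """Drop markers whose missing fraction strictly exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing outside [0, 1]")
    frac = (gm.geno == MISSING).mean(axis=0)
    fail = frac > max_missing
    report = QcReport(
        n_input=gm.n_markers,
        n_removed_by_class={"call_rate": int(fail.sum())},
        n_output=int((~fail).sum()),
        fail=fail,
    )
    return gm.take_markers(~fail), report


def filter_maf(gm: GenotypeMatrix, min_maf: float = 0.005):
    """Drop markers with minor allele frequency strictly below ``min_maf``.

    Missing calls are excluded from the frequency denominator; fully missing
    and monomorphic markers are removed, not errors.
    """
    if not 0.0 <= min_maf <= 1.0:
        raise ValueError("min_maf outside [0, 1]")
    maf = minor_allele_frequencies(gm.geno)
    fail = ~(maf >= min_maf)  # nan (no calls) fails too
    report = QcReport(
        n_input=gm.n_markers,
        n_removed_by_class={"maf": int(fail.sum())},
        n_output=int((~fail).sum()),
        fail=fail,
    )
    return gm.take_markers(~fail), report


def apply_qc(
    gm: GenotypeMatrix, max_missing: float = 0.05, min_maf: float = 0.005
):
    """Run all three filters on the input and remove the union of failures.

    Per-filter counts are evaluated on the original matrix, so overlapping
    criteria are visible: the union removal count may be smaller than the
    per-filter sum.
    """
    classes = gm.chromosome_classes()
    fail_class = np.isin(classes, REMOVED_CLASSES)
    frac = (gm.geno == MISSING).mean(axis=0)
    fail_call = frac > max_missing
    maf = minor_allele_frequencies(gm.geno)
    fail_maf = ~(maf >= min_maf)
    fail = fail_class | fail_call | fail_maf
    removed = {c: int((classes == c).sum()) for c in REMOVED_CLASSES}
    removed["call_rate"] = int(fail_call.sum())
    removed["maf"] = int(fail_maf.sum())
    removed["union"] = int(fail.sum())
    report = QcReport(
        n_input=gm.n_markers,
        n_removed_by_class=removed,
        n_output=int((~fail).sum()),
        fail=fail,
    )
    return gm.take_markers(~fail), report


def logr_sliding_window(
    intensities: np.ndarray, positions: np.ndarray | None = None, window: int = 3
):
    """Mean intensity over every run of ``window`` consecutive markers.

    Returns ``(means, midpoints)``; midpoints are the positions of the
    central marker of each window (mean of the two central positions for
    even windows), or window-start indices when positions are omitted.
    """
    x = np.asarray(intensities, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError(f"window={window} exceeds {x.size} markers")
    kernel = np.ones(window) / window
    means = np.convolve(x, kernel, mode="valid")
    if positions is None:
        mid = np.arange(means.size) + (window - 1) / 2.0
    else:
        pos = np.asarray(positions, dtype=float)
        if pos.size != x.size:
            raise ValueError("positions length mismatch")
        lo = (window - 1) // 2
        hi = window // 2
        mid = (pos[lo : lo + means.size] + pos[hi : hi + means.size]) / 2.0
    return means, mid


def mean_impute(gm: GenotypeMatrix) -> np.ndarray:
    """Float genotype matrix with missing calls replaced by the marker mean.

    Markers with no observed calls are imputed to 0.
    """
    g = gm.geno.astype(float)
    obs = g != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = np.where(
            obs.sum(axis=0) > 0,
            np.where(obs, g, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1),
            0.0,
        )
    out = np.where(obs, g, col_mean[None, :])
    return out
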