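"""Per-SNP linear mixed-model association.

Model: y = mu + x*b + u + e with u ~ N(0, sigma_a^2 * G) and
e ~ N(0, sigma_e^2 * I).  The variance ratio delta = sigma_e^2/sigma_a^2 is
REML-estimated on the eigen-rotated data (G = U D U'), either per SNP
("exact" mode, Brent search over log10 delta) or once under the null
intercept-only model ("null-delta" mode).  The SNP effect is tested with a
Wald test against a t reference with n - 2 degrees of freedom, which
reduces exactly to the ordinary least-squares t-test when G carries no
signal.  Case/control status is treated as a quantitative trait; the test
is invariant to affine recoding of the phenotype.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix
from .grm import Grm
from .qc import mean_impute

__all__ = [
    "fit_lmm_gwas",
    "significance_threshold",
    "genomic_inflation",
    "reml_loglik",
]

_LOG10_DELTA_BOUNDS = (-5.0, 5.0)
_PSD_TOL = -1e-8


def _eigendecompose(G: np.ndarray):
    d, U = np.linalg.eigh(G)
    tr = max(np.trace(G), 1.0)
    if d.min() < _PSD_TOL * tr / G.shape[0] - 1e-12:
        raise ValueError(
            "relationship matrix is not positive semi-definite; "
            "add a diagonal ridge (Grm.with_ridge)"
        )
    return np.clip(d, 0.0, None), U


def reml_loglik(delta: float, d: np.ndarray, Wt: np.ndarray, yt: np.ndarray) -> float:
    """Restricted log-likelihood at a given variance ratio.

    ``d`` are the eigenvalues of G, ``Wt``/``yt`` the rotated design and
    phenotype.  Constant terms not depending on ``delta`` are dropped only
    where they cancel in comparisons across ``delta``.
    """
    n, c = Wt.shape
    w = 1.0 / (d + delta)
    A = (Wt * w[:, None]).T @ Wt
    rhs = Wt.T @ (w * yt)
    b = np.linalg.solve(A, rhs)
    resid = yt - Wt @ b
    rss = float(np.sum(w * resid**2))
    df = n - c
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0 or rss <= 0:
        return -np.inf
    return 0.5 * (
        df * np.log(df / (2.0 * np.pi))
        - df
        - df * np.log(rss)
        - float(np.sum(np.log(d + delta)))
        - logdet_a
    )


def _optimize_delta(d, Wt, yt):
    lo, hi = _LOG10_DELTA_BOUNDS

    def neg(t):
        return -reml_loglik(10.0**t, d, Wt, yt)

    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded")
    candidates = [(10.0**res.x, -res.fun), (10.0**lo, -neg(lo)), (10.0**hi, -neg(hi))]
    delta, ll = max(candidates, key=lambda c: c[1])
    return delta, ll


def _gls_stats(delta, d, ut1, Xt, yt):
    """Vectorized GLS for [intercept, snp] designs at a fixed delta.

    Returns per-SNP (beta, se, sigma_a2, degenerate-flag).
    """
    n = yt.size
    w = 1.0 / (d + delta)
    wy = w * yt
    a = float(np.sum(w * ut1**2))
    sy = float(np.sum(ut1 * wy))
    syy = float(np.sum(yt * wy))
    sx = Xt.T @ (w * ut1)
    sxx = (Xt**2).T @ w
    sxy = Xt.T @ wy
    det = a * sxx - sx**2
    degen = det <= 1e-10 * np.maximum(a * sxx, 1e-300)
    det_safe = np.where(degen, 1.0, det)
    beta = (a * sxy - sx * sy) / det_safe
    b0 = (sy - sx * beta) / a
    rss = syy - b0 * sy - beta * sxy
    dfree = n - 2
    sigma_a2 = np.maximum(rss, 0.0) / dfree
    var_beta = sigma_a2 * a / det_safe
    se = np.sqrt(np.maximum(var_beta, 0.0))
    return beta, se, sigma_a2, degen


def fit_lmm_gwas(
    y: np.ndarray,
    gm: GenotypeMatrix,
    grm: Grm | np.ndarray,
    mode: str = "exact",
) -> pd.DataFrame:
    """Association scan of every marker against the phenotype.

    Parameters
    ----------
    y
        Phenotype vector (e.g. affection status coded 1/2).
    gm
        Genotypes; missing calls are mean-imputed per marker.
    grm
        Relationship matrix used as the polygenic covariance.
    mode
        ``"exact"`` re-estimates delta per SNP; ``"null-delta"`` estimates
        it once under the intercept-only model (EMMAX-style).

    Returns
    -------
    pandas.DataFrame
        One row per marker: ``id, chrom, pos, beta, se, wald, p,
        sigma_a2, sigma_e2, delta, degenerate``.  Markers collinear with
        the intercept get ``p = 1`` and are flagged.
    """
    y = np.asarray(y, dtype=float)
    G = grm.matrix if isinstance(grm, Grm) else np.asarray(grm, dtype=float)
    n = y.size
    if gm.n_samples != n or G.shape[0] != n:
        raise ValueError("phenotype, genotypes and GRM dimensions disagree")
    if mode not in ("exact", "null-delta"):
        raise ValueError(f"unknown mode {mode!r}")
    d, U = _eigendecompose(G)
    yt = U.T @ y
    ut1 = U.T @ np.ones(n)
    X = mean_impute(gm)
    Xt = U.T @ X
    dfree = n - 2
    m = gm.n_markers

    beta = np.zeros(m)
    se = np.full(m, np.nan)
    sigma_a2 = np.full(m, np.nan)
    deltas = np.full(m, np.nan)
    degen = np.zeros(m, dtype=bool)

    if mode == "null-delta":
        delta0, _ = _optimize_delta(d, ut1[:, None], yt)
        beta, se, sigma_a2, degen = _gls_stats(delta0, d, ut1, Xt, yt)
        deltas[:] = delta0
    else:
        for j in range(m):
            Wt = np.column_stack([ut1, Xt[:, j]])
            # collinear with intercept (monomorphic leak): flag, p = 1
            A = Wt.T @ Wt
            if np.linalg.det(A) <= 1e-10 * max(A[0, 0] * A[1, 1], 1e-300):
                degen[j] = True
                continue
            dj, _ = _optimize_delta(d, Wt, yt)
            b, s, s2, dg = _gls_stats(dj, d, ut1, Xt[:, j : j + 1], yt)
            beta[j], se[j], sigma_a2[j] = b[0], s[0], s2[0]
            degen[j] |= bool(dg[0])
            deltas[j] = dj

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = np.where(~degen & (se > 0), beta / np.where(se > 0, se, 1.0), 0.0)
    wald = tstat**2
    p = 2.0 * stats.t.sf(np.abs(tstat), dfree)
    p = np.where(degen | ~np.isfinite(p), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta = np.where(degen, 0.0, beta)

    out = gm.markers[["id", "chrom", "pos"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["wald"] = wald
    out["p"] = p
    out["sigma_a2"] = sigma_a2
    out["sigma_e2"] = deltas * sigma_a2
    out["delta"] = deltas
    out["degenerate"] = degen
    return out


def significance_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni family-wise threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha outside (0, 1]")
    return alpha / n_tests


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic-control lambda: median association chi-square over its null
    median (0.4549...)."""
    p = np.asarray(pvalues, dtype=float)
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.isf(0.5, df=1))
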