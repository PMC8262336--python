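"""Simplified negative-binomial differential expression for the Q/NQ signature.

This stage implements the stated selection criteria — NB count model with
median-of-ratios normalization, a Wald test on the group coefficient with an
optional batch covariate, BH-adjusted FDR, and the |linear FC| >= 1.5,
FDR < 0.1 signature filter — as a self-contained pipeline. It deliberately
does not reproduce any particular third-party implementation bit-for-bit:
there is no independent filtering, no outlier replacement, and no shrunken
fold-change estimator. Validity is established by parameter recovery and null
calibration on synthetic cohorts rather than by numerical cloning.

Model: k_ij ~ NB(mean mu_ij, dispersion alpha_i) with
log mu_ij = log s_j + x_j' beta_i, where s_j are median-of-ratios size
factors. Dispersions are gene-wise method-of-moments estimates blended toward
a fitted mean-dispersion trend alpha(mu) = a0/mu + a1. The Wald statistic is
the group coefficient over its Fisher-information standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

logger = logging.getLogger(__name__)

ALPHA_MIN = 1e-8
_MAX_ITER = 60
_TOL = 1e-10


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-invariant)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to unit geometric mean.

    s_j = median over genes (nonzero in every sample) of k_ij / geomean_i(k_i.).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    if mat.shape[1] < 2:
        raise ValueError("size factors require >= 2 samples")
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; cannot form the "
            "median-of-ratios reference (consider a pseudo-reference fallback)"
        )
    ref = mat[all_nonzero].astype(float)
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    s = np.median(ref / geomean[:, None], axis=0)
    s /= np.exp(np.mean(np.log(s)))  # unit geometric mean
    return s


def normalized_counts(counts: CountMatrix, factors: np.ndarray | None = None) -> pd.DataFrame:
    """Genes x samples size-factor-normalized counts."""
    if factors is None:
        factors = size_factors(counts)
    return counts.to_frame() / factors


def log2_normalized(counts: CountMatrix, factors: np.ndarray | None = None) -> pd.DataFrame:
    """log2(normalized count + 1), genes x samples — the expression transform
    used by the PCA, enrichment and panel stages."""
    return np.log2(normalized_counts(counts, factors) + 1.0)


def fit_dispersion_trend(mean: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0/mu + a1 to method-of-moments dispersions (NNLS)."""
    ok = (alpha_mom > ALPHA_MIN) & (mean > 0)
    if ok.sum() < 10:
        return 0.0, float(np.median(alpha_mom[alpha_mom > 0])) if (alpha_mom > 0).any() else ALPHA_MIN
    design = np.column_stack([1.0 / mean[ok], np.ones(ok.sum())])
    coef, _ = nnls(design, alpha_mom[ok])
    return float(coef[0]), float(coef[1])


def estimate_dispersions(
    counts: CountMatrix,
    factors: np.ndarray | None = None,
    groups: pd.Series | np.ndarray | None = None,
    trend_blend: float = 0.5,
    alpha_min: float = ALPHA_MIN,
) -> pd.DataFrame:
    """Gene-wise NB dispersions: within-group method of moments, blended toward
    a fitted mean-dispersion trend.

    alpha_mom = max((var - mu) / mu^2, alpha_min) on normalized counts,
    pooled across groups weighted by within-group degrees of freedom; the final
    estimate is (1 - w) * alpha_mom + w * alpha_trend with w = ``trend_blend``.
    Groups with a single sample contribute nothing; if no group has >= 2
    samples the trend cannot be anchored and a warning falls everything back
    to the pooled estimate.
    """
    if factors is None:
        factors = size_factors(counts)
    norm = (counts.counts / factors[None, :]).astype(float)
    n = norm.shape[1]
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups)

    num = np.zeros(norm.shape[0])
    den = 0.0
    overall_mean = norm.mean(axis=1)
    usable = False
    for level in pd.unique(groups):
        sel = groups == level
        ng = int(sel.sum())
        if ng < 2:
            logger.warning("dispersion estimation: group %r has a single sample; skipped", level)
            continue
        usable = True
        m = norm[:, sel].mean(axis=1)
        v = norm[:, sel].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(m)
        a = np.where(np.isfinite(a), a, 0.0)
        num += (ng - 1) * a
        den += ng - 1
    if not usable:
        raise ValueError("no contrast group has >= 2 samples")
    alpha_mom = np.maximum(num / den, alpha_min)

    a0, a1 = fit_dispersion_trend(overall_mean, alpha_mom)
    with np.errstate(divide="ignore"):
        alpha_trend = np.where(overall_mean > 0, a0 / overall_mean + a1, np.inf)
    alpha_trend = np.maximum(np.minimum(alpha_trend, 10.0), alpha_min)
    alpha = (1.0 - trend_blend) * alpha_mom + trend_blend * alpha_trend
    return pd.DataFrame({
        "gene": counts.genes,
        "alpha_mom": alpha_mom,
        "alpha_trend": alpha_trend,
        "alpha": np.maximum(alpha, alpha_min),
    }).set_index("gene")


def _irls_nb(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS for gene-wise NB GLMs with log link and known dispersion.

    y: (G, n) counts; X: (n, p) shared design; offset: (n,) log size factors;
    alpha: (G,) dispersions. Returns (beta (G, p), cov (G, p, p)).
    """
    G, n = y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    # initialize the intercept at the log mean normalized count
    beta[:, 0] = np.log(np.maximum((y / np.exp(offset)[None, :]).mean(axis=1), 1e-8))
    eta = beta @ X.T + offset[None, :]
    for _ in range(_MAX_ITER):
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)  # Fisher weights
        z = (eta - offset[None, :]) + (y - mu) / mu  # working response
        A = np.einsum("ni,gn,nj->gij", X, W, X)
        b = np.einsum("ni,gn,gn->gi", X, W, z)
        A += np.eye(p)[None, :, :] * 1e-10  # numerical ridge
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        step = new_beta - beta
        beta = new_beta
        eta = beta @ X.T + offset[None, :]
        if np.nanmax(np.abs(step)) < _TOL:
            break
    eta = np.clip(eta, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("ni,gn,nj->gij", X, W, X) + np.eye(p)[None, :, :] * 1e-12
    cov = np.linalg.inv(A)
    return beta, cov


def test_de(
    counts: CountMatrix,
    design: pd.Series | np.ndarray,
    contrast: tuple[str, str],
    batch: pd.Series | np.ndarray | None = None,
    trend_blend: float = 0.5,
) -> pd.DataFrame:
    """NB Wald differential-expression test for ``contrast = (test, reference)``.

    ``design`` holds a group label per sample of ``counts``; only samples in
    the two contrast groups are used. ``batch``, when given, enters the model
    as additive indicator covariates. log2fc is the coefficient of the test
    group relative to the reference, on the log2 scale.

    Genes that are all-zero in one contrast group are flagged ``separated``
    and their displayed log2fc is recomputed from 0.5-pseudo-counted group
    means (the p-value still comes from the model).
    """
    design = np.asarray(design)
    test_lvl, ref_lvl = contrast
    keep = np.isin(design, [test_lvl, ref_lvl])
    for lvl in contrast:
        if (design == lvl).sum() < 2:
            raise ValueError(f"contrast group {lvl!r} has fewer than 2 samples")
    sub = counts.subset_samples([s for s, k in zip(counts.samples, keep) if k])
    groups = design[keep]
    factors = size_factors(sub)
    disp = estimate_dispersions(sub, factors, groups=groups, trend_blend=trend_blend)
    alpha = disp["alpha"].to_numpy()

    n = len(groups)
    z = (groups == test_lvl).astype(float)
    cols = [np.ones(n), z]
    if batch is not None:
        batch = np.asarray(batch)[keep]
        levels = pd.unique(batch)
        if len(levels) > 1:
            for lvl in levels[1:]:
                cols.append((batch == lvl).astype(float))
        else:
            logger.warning("batch covariate has a single level in the contrast; omitted")
    X = np.column_stack(cols)

    y = sub.counts.astype(float)
    nonzero = y.sum(axis=1) > 0
    beta = np.full((y.shape[0], X.shape[1]), np.nan)
    cov = np.full((y.shape[0], X.shape[1], X.shape[1]), np.nan)
    if nonzero.any():
        beta_nz, cov_nz = _irls_nb(y[nonzero], X, np.log(factors), alpha[nonzero])
        beta[nonzero] = beta_nz
        cov[nonzero] = cov_nz

    ln2 = np.log(2.0)
    log2fc = beta[:, 1] / ln2
    se = np.sqrt(np.maximum(cov[:, 1, 1], 0.0)) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = beta[:, 1] / np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
    pvals = 2.0 * stats.norm.sf(np.abs(wald))

    norm = y / factors[None, :]
    base_mean = norm.mean(axis=1)
    mean_test = norm[:, z == 1].mean(axis=1)
    mean_ref = norm[:, z == 0].mean(axis=1)
    separated = nonzero & ((mean_test == 0) | (mean_ref == 0))
    if separated.any():
        pseudo = np.log2(mean_test[separated] + 0.5) - np.log2(mean_ref[separated] + 0.5)
        log2fc[separated] = pseudo

    q = np.full_like(pvals, np.nan)
    tested = np.isfinite(pvals)
    if tested.any():
        q[tested] = bh_adjust(pvals[tested])

    return pd.DataFrame({
        "gene": sub.genes,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "se": se,
        "stat": wald,
        "p": pvals,
        "q": q,
        "dispersion": alpha,
        "separated": separated,
    }).set_index("gene")


@dataclass
class Signature:
    """Up/down gene partitions passing the fold-change + FDR filter."""

    up: list[str]
    down: list[str]

    @property
    def genes(self) -> list[str]:
        return self.up + self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def signature_filter(de: pd.DataFrame, min_fc: float = 1.5, max_fdr: float = 0.1) -> Signature:
    """Select the signature: |log2fc| >= log2(min_fc) and q < max_fdr."""
    thr = np.log2(min_fc)
    passing = de[(de["log2fc"].abs() >= thr) & (de["q"] < max_fdr)]
    up = passing[passing["log2fc"] > 0].index.tolist()
    down = passing[passing["log2fc"] < 0].index.tolist()
    return Signature(up=up, down=down)
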