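"""The two-gene ATP2B4/ATP2A2 ratio classifier.

The ratio of the plasma-membrane calcium pump transcript (ATP2B4, PMCA4) to
the sarco/endoplasmic-reticulum pump transcript (ATP2A2, SERCA2) drops in
contractile (nonquiescent, NQ) myometrium. It can be computed from RNA-seq
feature counts (where within-sample scaling cancels) or from qPCR Ct values
via the comparative-Ct statistic 2^-dCt with dCt = Ct_ATP2B4 - Ct_ATP2A2 on
well-averaged Cts. ROC analysis against labeled phenotypes yields an AUC (the
tie-adjusted Mann-Whitney concordance of "lower ratio implies NQ") and an
operating threshold tau chosen by Youden's J; samples with ratio <= tau are
called NQ, optionally with a transitional band around tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io import ANCHOR_DENOMINATOR, ANCHOR_NUMERATOR, REFERENCE_GENES, CountMatrix
from .de import log2_normalized, size_factors

logger = logging.getLogger(__name__)

PHENOTYPE_Q = "Q"
PHENOTYPE_NQ = "NQ"
TRANSITIONAL = "transitional"


def ratio_from_counts(
    counts: CountMatrix,
    num: str = ANCHOR_NUMERATOR,
    den: str = ANCHOR_DENOMINATOR,
    mode: str = "raw",
) -> pd.DataFrame:
    """Per-sample numerator/denominator count ratio.

    ``mode="raw"`` uses feature counts directly (sample-level scaling cancels
    within a sample); ``mode="normalized"`` divides size-factor-normalized
    counts and yields identical ratios. Samples with a zero denominator are
    flagged missing (NaN ratio), not a global failure.
    """
    i_num = counts.gene_index(num)
    i_den = counts.gene_index(den)
    numerator = counts.counts[i_num].astype(float)
    denominator = counts.counts[i_den].astype(float)
    if mode == "normalized":
        s = size_factors(counts)
        numerator = numerator / s
        denominator = denominator / s
    elif mode != "raw":
        raise ValueError("mode must be 'raw' or 'normalized'")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denominator > 0, numerator / denominator, np.nan)
    n_missing = int(np.isnan(ratio).sum())
    if n_missing:
        logger.warning("%d sample(s) with zero %s counts flagged missing", n_missing, den)
    return pd.DataFrame({
        "sample_id": counts.samples,
        "ratio": ratio,
        "numerator": numerator,
        "denominator": denominator,
        "source": f"rnaseq_{mode}",
    })


def ratio_from_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Comparative-Ct ratio per sample: 2^-(Ct_ATP2B4 - Ct_ATP2A2).

    Duplicate wells are averaged arithmetically on the Ct scale (the geometric
    mean of the linear quantities). When both reference genes (B2M, RPL30)
    are present, reference-normalized relative abundances
    2^-(Ct_target - Ct_ref) are also emitted, with Ct_ref the arithmetic mean
    of the two reference-gene Cts (log2 of their geometric mean on the linear
    scale); the references cancel in the two-gene ratio itself.
    """
    mean_ct = (
        ct.dropna(subset=["ct"])
        .groupby(["sample_id", "assay"], sort=False)["ct"].mean()
        .unstack("assay")
    )
    for target in (ANCHOR_NUMERATOR, ANCHOR_DENOMINATOR):
        if target not in mean_ct.columns:
            raise ValueError(f"target assay {target!r} absent from Ct table")
    delta = mean_ct[ANCHOR_NUMERATOR] - mean_ct[ANCHOR_DENOMINATOR]
    out = pd.DataFrame({
        "sample_id": mean_ct.index,
        "delta_ct": delta.to_numpy(),
        "ratio": (2.0 ** -delta).to_numpy(),
        "source": "qpcr",
    })
    have_refs = all(r in mean_ct.columns for r in REFERENCE_GENES)
    if have_refs:
        ct_ref = mean_ct[list(REFERENCE_GENES)].mean(axis=1)
        for target in (ANCHOR_NUMERATOR, ANCHOR_DENOMINATOR):
            out[f"rel_{target}"] = (2.0 ** -(mean_ct[target] - ct_ref)).to_numpy()
    else:
        logger.warning("reference gene(s) missing: relative abundances suppressed")
    n_missing = int(out["ratio"].isna().sum())
    if n_missing:
        logger.warning("%d sample(s) with missing target Ct flagged missing", n_missing)
    return out


def auc_mann_whitney(ratios: np.ndarray, is_nq: np.ndarray) -> float:
    """Tie-adjusted concordance P(R_NQ < R_Q) + 0.5 P(R_NQ = R_Q)."""
    r = stats.rankdata(ratios)  # midranks
    n_nq = int(is_nq.sum())
    n_q = int((~is_nq).sum())
    # sum of Q midranks - minimal sum, over the number of pairs
    u_q = r[~is_nq].sum() - n_q * (n_q + 1) / 2.0
    return float(u_q / (n_nq * n_q))


@dataclass
class ROCResult:
    """Stepwise ROC curve, AUC, and the Youden-J operating threshold."""

    auc: float
    threshold: float
    curve: pd.DataFrame  # columns: threshold, sensitivity, specificity
    n_nq: int
    n_q: int
    n_excluded: int


def roc(ratios: pd.DataFrame | np.ndarray, labels) -> ROCResult:
    """ROC analysis of the rule "call NQ iff ratio <= tau".

    AUC is the tie-adjusted Mann-Whitney concordance of lower-ratio-implies-NQ.
    The operating threshold maximizes Youden's J = sensitivity + specificity
    - 1, ties broken toward the higher threshold (favoring NQ sensitivity).
    Samples with a missing ratio are excluded with a logged count.
    """
    values = np.asarray(ratios["ratio"] if isinstance(ratios, pd.DataFrame) else ratios,
                        dtype=float)
    labels = np.asarray(labels, dtype=object)
    ok = np.isfinite(values)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("excluding %d sample(s) with missing ratios from ROC", n_excluded)
    values, labels = values[ok], labels[ok]
    is_nq = labels == PHENOTYPE_NQ
    n_nq, n_q = int(is_nq.sum()), int((~is_nq).sum())
    if n_nq == 0 or n_q == 0:
        raise ValueError("ROC requires both NQ and Q classes to be present")

    auc = auc_mann_whitney(values, is_nq)

    thresholds = np.unique(values)
    sens = np.array([(values[is_nq] <= t).mean() for t in thresholds])
    spec = np.array([(values[~is_nq] > t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[-1]  # ties toward the higher tau
    curve = pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec})
    return ROCResult(auc=auc, threshold=float(thresholds[best]), curve=curve,
                     n_nq=n_nq, n_q=n_q, n_excluded=n_excluded)


def classify(ratios, tau: float, transitional_band: float = 0.0) -> np.ndarray:
    """NQ iff ratio <= tau; with band b > 0, ratios in (tau(1-b), tau(1+b)]
    are called transitional (NQ below, Q above)."""
    if tau <= 0:
        raise ValueError("threshold tau must be > 0")
    values = np.asarray(ratios["ratio"] if isinstance(ratios, pd.DataFrame) else ratios,
                        dtype=float)
    calls = np.where(values <= tau, PHENOTYPE_NQ, PHENOTYPE_Q).astype(object)
    if transitional_band > 0:
        lo = tau * (1.0 - transitional_band)
        hi = tau * (1.0 + transitional_band)
        calls[(values > lo) & (values <= hi)] = TRANSITIONAL
    calls[~np.isfinite(values)] = "missing"
    return calls


class RatioThresholdClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper: fit the ROC threshold, predict Q/NQ from ratios.

    Parameters
    ----------
    threshold : float, optional
        Fixed operating threshold; when None (default) the threshold is
        learned from the training labels by Youden's J.
    transitional_band : float, default 0.0
        Relative band around the threshold called ``transitional``.
    """

    def __init__(self, threshold: float | None = None, transitional_band: float = 0.0):
        self.threshold = threshold
        self.transitional_band = transitional_band

    @staticmethod
    def _values(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X["ratio"].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return X[:, 0] if X.ndim == 2 else X

    def fit(self, X, y):
        values = self._values(X)
        result = roc(values, y)
        self.auc_ = result.auc
        self.threshold_ = self.threshold if self.threshold is not None else result.threshold
        self.curve_ = result.curve
        self.classes_ = np.array([PHENOTYPE_NQ, PHENOTYPE_Q], dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        return classify(self._values(X), self.threshold_, self.transitional_band)


def correlated_panel(
    expr: pd.DataFrame | CountMatrix,
    anchor: str,
    r_min: float = 0.95,
) -> pd.DataFrame:
    """Genes whose log2-normalized expression correlates with the anchor's at
    Pearson r >= r_min across all samples (one-sided; the anchor itself is
    excluded). Order: r descending, then symbol ascending."""
    if isinstance(expr, CountMatrix):
        expr = log2_normalized(expr)
    if expr.shape[1] < 3:
        raise ValueError("correlated panel requires >= 3 samples")
    if anchor not in expr.index:
        raise KeyError(f"anchor gene {anchor!r} absent from expression matrix")
    x = expr.loc[anchor].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"anchor gene {anchor!r} is constant across samples")
    mat = expr.to_numpy(dtype=float)
    xc = x - x.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((mc ** 2).sum(axis=1)) * np.sqrt((xc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mc @ xc) / denom
    out = pd.DataFrame({"gene": expr.index, "r": r})
    out = out[(out["gene"] != anchor) & (out["r"] >= r_min)]
    out = out.sort_values("gene").sort_values("r", ascending=False, kind="stable")
    return out.reset_index(drop=True)
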