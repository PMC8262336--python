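"""Signature PCA phenotyping: train on labeled reference samples, project the
rest, call Q/NQ along the dominant component, and correlate it with clinical
scores.

The estimator follows scikit-learn conventions (``fit`` / ``transform`` /
``predict``, fitted attributes with trailing underscores) and composes with
sklearn pipelines. Input is a samples x genes matrix of log2(size-factor
normalized count + 1) expression restricted to the signature genes.

Orientation is fixed by the labeled training centroids, not by an
eigen-solver's sign convention: after fitting, the nonquiescent (NQ) centroid
lies below the quiescent (Q) centroid on PC1. Phenotype calls use the nearest
reference centroid on PC1 (midpoint threshold, ties toward NQ) with an
optional transitional band around the midpoint.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .io import CountMatrix
from .de import log2_normalized

PHENOTYPE_Q = "Q"
PHENOTYPE_NQ = "NQ"
TRANSITIONAL = "transitional"


class QuiescencePhenotyper(BaseEstimator, ClassifierMixin):
    """PCA projection phenotyper for the quiescent/nonquiescent axis.

    Parameters
    ----------
    signature_genes : list of str, optional
        Gene order defining the feature columns. When X is a DataFrame the
        columns are aligned (and their presence enforced); when None, all
        columns of the training frame are used.
    scale : bool, default False
        Standardize genes to unit variance (correlation PCA) instead of the
        default covariance PCA.
    transitional_band : float, default 0.0
        Fraction of the inter-centroid distance around the PC1 midpoint to
        call ``transitional`` instead of Q/NQ.
    n_components : int, optional
        Number of retained components (default: all).
    """

    def __init__(self, signature_genes=None, scale=False, transitional_band=0.0,
                 n_components=None):
        self.signature_genes = signature_genes
        self.scale = scale
        self.transitional_band = transitional_band
        self.n_components = n_components

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [g for g in self.genes_ if g not in X.columns]
            if missing:
                raise ValueError(f"signature gene(s) missing from input: {missing[:10]}")
            return X.loc[:, self.genes_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.genes_):
            raise ValueError(
                f"expected {len(self.genes_)} signature genes, got {X.shape[1]} columns"
            )
        return X

    def fit(self, X, y):
        """Fit on labeled reference samples (y in {"Q", "NQ"})."""
        y = np.asarray(y, dtype=object)
        if isinstance(X, pd.DataFrame):
            genes = list(self.signature_genes) if self.signature_genes is not None else list(X.columns)
            missing = [g for g in genes if g not in X.columns]
            if missing:
                raise ValueError(f"signature gene(s) missing from input: {missing[:10]}")
            mat = X.loc[:, genes].to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            genes = (list(self.signature_genes) if self.signature_genes is not None
                     else [f"g{i}" for i in range(mat.shape[1])])
        for lvl in (PHENOTYPE_Q, PHENOTYPE_NQ):
            if (y == lvl).sum() < 2:
                raise ValueError(f"need >= 2 training samples labeled {lvl!r}")

        variances = mat.var(axis=0)
        keep = variances > 0
        if not keep.all():
            dropped = [g for g, k in zip(genes, keep) if not k]
            warnings.warn(f"dropping {len(dropped)} zero-variance gene(s): {dropped[:5]}")
            genes = [g for g, k in zip(genes, keep) if k]
            mat = mat[:, keep]
        self.genes_ = genes

        self.center_ = mat.mean(axis=0)
        self.scale_ = mat.std(axis=0, ddof=1) if self.scale else np.ones(mat.shape[1])
        Z = (mat - self.center_) / self.scale_

        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(Z)
        self.components_ = pca.components_  # (k, genes)
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.orientation_sign_ = np.ones(self.components_.shape[0])

        pc1 = scores[:, 0]
        c_nq = pc1[y == PHENOTYPE_NQ].mean()
        c_q = pc1[y == PHENOTYPE_Q].mean()
        if c_nq > c_q:
            self.orientation_sign_[0] = -1.0
            self.components_[0] *= -1.0
            c_nq, c_q = -c_nq, -c_q
        self.centroids_ = {PHENOTYPE_NQ: float(c_nq), PHENOTYPE_Q: float(c_q)}
        self.classes_ = np.array([PHENOTYPE_NQ, PHENOTYPE_Q], dtype=object)
        self.training_scores_ = scores * self.orientation_sign_[None, :]
        return self

    def transform(self, X) -> np.ndarray:
        """Project samples with the training center/scale/loadings (no refit)."""
        check_is_fitted(self, "components_")
        Z = (self._matrix(X) - self.center_) / self.scale_
        return Z @ self.components_.T

    def predict(self, X) -> np.ndarray:
        """Nearest reference centroid on PC1; ties go to NQ; optional band."""
        scores = self.transform(X)
        return self.assign(scores[:, 0])

    def assign(self, pc1: np.ndarray) -> np.ndarray:
        """Classify oriented PC1 scores by the midpoint rule."""
        check_is_fitted(self, "centroids_")
        pc1 = np.asarray(pc1, dtype=float)
        lo, hi = self.centroids_[PHENOTYPE_NQ], self.centroids_[PHENOTYPE_Q]
        mid = 0.5 * (lo + hi)
        calls = np.where(pc1 <= mid, PHENOTYPE_NQ, PHENOTYPE_Q).astype(object)
        if self.transitional_band > 0:
            half = self.transitional_band * (hi - lo)
            calls[(pc1 > mid - half) & (pc1 < mid + half)] = TRANSITIONAL
        return calls

    def fit_predict(self, X, y):
        return self.fit(X, y).predict(X)


def fit_reference_pca(
    expr: pd.DataFrame, signature: list[str], labels, scale: bool = False,
    n_components: int | None = None,
) -> QuiescencePhenotyper:
    """Fit the phenotyper on a samples x genes log-expression frame."""
    model = QuiescencePhenotyper(signature_genes=signature, scale=scale,
                                 n_components=n_components)
    return model.fit(expr, labels)


def project(model: QuiescencePhenotyper, expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample component scores in the training coordinate system."""
    scores = model.transform(expr)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    index = expr.index if isinstance(expr, pd.DataFrame) else None
    return pd.DataFrame(scores, index=index, columns=cols)


def assign_phenotype(scores: pd.Series | np.ndarray, model: QuiescencePhenotyper) -> np.ndarray:
    """Q/NQ (or transitional) calls from oriented PC1 scores."""
    return model.assign(np.asarray(scores, dtype=float))


def expression_for_pca(counts: CountMatrix, factors: np.ndarray | None = None) -> pd.DataFrame:
    """Samples x genes log2(normalized + 1) expression frame from counts."""
    return log2_normalized(counts, factors).T


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Tie-corrected Spearman rho with an exact permutation p for small n.

    rho is the Pearson correlation of midranks. For n > ``exact_max_n`` the
    p-value uses the t approximation t = rho * sqrt((n-2)/(1-rho^2)); for
    n <= ``exact_max_n`` it enumerates all n! orderings exactly (chunked).
    Returns (nan, nan) with a warning if either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant variable: Spearman correlation undefined")
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > exact_max_n:
        if abs(rho) >= 1.0:
            return rho, 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        return rho, float(min(p, 1.0))
    # exact permutation distribution of rho via Sum rx_i * ry_perm(i)
    sd_x = rx.std(ddof=0)
    sd_y = ry.std(ddof=0)
    mean_term = n * rx.mean() * ry.mean()
    denom = n * sd_x * sd_y
    obs = abs(rho)
    total = math.factorial(n)
    extreme = 0
    chunk = 200_000
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        perm_idx = np.array(block, dtype=np.int64)
        sums = ry[perm_idx] @ rx
        rhos = (sums - mean_term) / denom
        extreme += int(np.sum(np.abs(rhos) >= obs - 1e-12))
    return rho, extreme / total


def correlate_clinical(
    pc1: pd.Series, clinical_scores: pd.DataFrame,
    columns: tuple[str, ...] = ("contraction_score", "dilation_score", "membrane_score",
                                "triple_i_score", "ga_score"),
) -> pd.DataFrame:
    """Spearman correlation of PC1 with each clinical score column.

    Samples are paired on the index / sample_id; non-numeric score entries
    (``missing``/``indeterminate``) are excluded per variable.
    """
    scores = clinical_scores.set_index("sample_id") if "sample_id" in clinical_scores else clinical_scores
    common = [s for s in pc1.index if s in scores.index]
    rows = []
    for col in columns:
        if col not in scores.columns:
            continue
        vals = pd.to_numeric(scores.loc[common, col], errors="coerce")
        x = pc1.loc[common].to_numpy(dtype=float)
        ok = vals.notna().to_numpy()
        if ok.sum() < 3:
            rows.append({"variable": col, "rho": np.nan, "p": np.nan, "n": int(ok.sum())})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = spearman(x[ok], vals.to_numpy(dtype=float)[ok])
        rows.append({"variable": col, "rho": rho, "p": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)
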