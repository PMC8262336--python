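"""PCA phenotyper: projection identities, orientation, centroid calls, and
the Spearman clinical correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myoquiesce.de import log2_normalized
from myoquiesce.pca import (
    QuiescencePhenotyper,
    assign_phenotype,
    correlate_clinical,
    fit_reference_pca,
    project,
    spearman,
)


def _toy(n=8, genes=20, seed=0, shift=3.0):
    """Two well-separated groups in log-expression space."""
    rng = np.random.default_rng(seed)
    base = rng.normal(6, 1, size=(n, genes))
    labels = np.array(["NQ"] * (n // 2) + ["Q"] * (n // 2), dtype=object)
    base[: n // 2, : genes // 2] += shift
    X = pd.DataFrame(base, index=[f"s{i}" for i in range(n)],
                     columns=[f"g{i}" for i in range(genes)])
    return X, labels


class TestFit:
    def test_training_reprojection_reproduces_fit_scores(self):
        X, y = _toy()
        m = QuiescencePhenotyper().fit(X, y)
        np.testing.assert_allclose(m.transform(X), m.training_scores_, atol=1e-10)

    def test_two_gene_variance_matches_hand_eigendecomposition(self):
        # 6 samples, 2 anti-correlated genes; compare with the closed-form
        # eigenvalues of the 2x2 covariance matrix
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = 10.0 - 1.3 * x + np.array([0.1, -0.2, 0.15, 0.0, -0.1, 0.05])
        X = pd.DataFrame({"gA": x, "gB": y})
        labels = np.array(["NQ", "NQ", "NQ", "Q", "Q", "Q"], dtype=object)
        m = QuiescencePhenotyper().fit(X, labels)
        cov = np.cov(np.column_stack([x, y]).T, ddof=1)
        tr, det = cov.trace(), np.linalg.det(cov)
        lam1 = (tr + np.sqrt(tr**2 - 4 * det)) / 2
        np.testing.assert_allclose(m.explained_variance_ratio_[0], lam1 / tr, rtol=1e-10)

    def test_flipping_labels_flips_orientation_and_negates_scores(self):
        X, y = _toy()
        m1 = QuiescencePhenotyper().fit(X, y)
        flipped = np.where(y == "NQ", "Q", "NQ")
        m2 = QuiescencePhenotyper().fit(X, flipped)
        np.testing.assert_allclose(m1.training_scores_[:, 0],
                                   -m2.training_scores_[:, 0], atol=1e-10)

    def test_nq_centroid_below_q_after_orientation(self):
        X, y = _toy(seed=5)
        m = QuiescencePhenotyper().fit(X, y)
        assert m.centroids_["NQ"] < m.centroids_["Q"]

    def test_zero_variance_gene_dropped_with_warning(self):
        X, y = _toy()
        X["flat"] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            m = QuiescencePhenotyper().fit(X, y)
        assert "flat" not in m.genes_

    def test_missing_signature_gene_is_an_error(self):
        X, y = _toy()
        with pytest.raises(ValueError, match="missing"):
            QuiescencePhenotyper(signature_genes=["g0", "nope"]).fit(X, y)

    def test_explained_variance_invariant_to_sample_order(self):
        X, y = _toy(seed=2)
        m1 = QuiescencePhenotyper().fit(X, y)
        perm = np.random.default_rng(1).permutation(len(X))
        m2 = QuiescencePhenotyper().fit(X.iloc[perm], y[perm])
        np.testing.assert_allclose(m1.explained_variance_ratio_,
                                   m2.explained_variance_ratio_, atol=1e-10)


class TestProjection:
    def test_mean_sample_projects_to_origin(self):
        X, y = _toy()
        m = QuiescencePhenotyper().fit(X, y)
        mean_sample = pd.DataFrame([X.mean(axis=0)], columns=X.columns)
        np.testing.assert_allclose(m.transform(mean_sample), 0.0, atol=1e-10)

    def test_projection_is_affine(self):
        X, y = _toy()
        m = QuiescencePhenotyper().fit(X, y)
        rng = np.random.default_rng(3)
        a, b = rng.normal(6, 2, size=(2, X.shape[1]))
        for t in (0.0, 0.3, 1.0):
            mix = pd.DataFrame([t * a + (1 - t) * b], columns=X.columns)
            expected = (t * m.transform(pd.DataFrame([a], columns=X.columns))
                        + (1 - t) * m.transform(pd.DataFrame([b], columns=X.columns)))
            np.testing.assert_allclose(m.transform(mix), expected, atol=1e-8)

    def test_planted_nq_samples_project_near_nq_centroid(self, small_cohort):
        labels = small_cohort.samples["true_phenotype"].to_numpy()
        ref = small_cohort.samples["arm"].isin(["TL", "TNL"]).to_numpy()
        expr = log2_normalized(small_cohort.counts).T
        sig = small_cohort.gene_truth.loc[small_cohort.gene_truth["is_de"], "gene"].tolist()
        m = fit_reference_pca(expr.loc[ref], sig, labels[ref])
        scores = project(m, expr)
        calls = assign_phenotype(scores["PC1"], m)
        assert (calls == labels).mean() >= 0.95


class TestAssign:
    def _model(self):
        X, y = _toy()
        return QuiescencePhenotyper().fit(X, y)

    def test_midpoint_ties_toward_nq(self):
        m = self._model()
        mid = 0.5 * (m.centroids_["NQ"] + m.centroids_["Q"])
        assert m.assign(np.array([mid]))[0] == "NQ"

    def test_score_at_centroid_is_that_class(self):
        m = self._model()
        assert m.assign(np.array([m.centroids_["NQ"]]))[0] == "NQ"
        assert m.assign(np.array([m.centroids_["Q"]]))[0] == "Q"

    def test_transitional_band(self):
        m = self._model()
        m.transitional_band = 0.25
        lo, hi = m.centroids_["NQ"], m.centroids_["Q"]
        mid = 0.5 * (lo + hi)
        near = mid + 0.1 * m.transitional_band * (hi - lo)
        assert m.assign(np.array([near]))[0] == "transitional"
        assert m.assign(np.array([lo]))[0] == "NQ"

    def test_sklearn_get_set_params_round_trip(self):
        m = QuiescencePhenotyper(scale=True, transitional_band=0.1)
        params = m.get_params()
        m2 = QuiescencePhenotyper().set_params(**params)
        assert m2.get_params() == params


class TestSpearman:
    def test_perfect_monotone_decrease_is_minus_one(self):
        x = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        y = np.arange(6, dtype=float)
        rho, p = spearman(x, y)
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 720)  # two of 6! orderings are as extreme

    def test_constant_variable_returns_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(rho)

    def test_matches_brute_force_midranks_and_exhaustive_permutation(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 4, size=7).astype(float)  # ties on purpose
        y = rng.normal(size=7)
        rho, p = spearman(x, y)
        # brute-force midrank rho
        def midranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            ranks = [0.0] * len(v)
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = avg
                i = j + 1
            return ranks
        rx, ry = midranks(list(x)), midranks(list(y))
        mean_rx = sum(rx) / len(rx)
        mean_ry = sum(ry) / len(ry)
        num = sum((a - mean_rx) * (b - mean_ry) for a, b in zip(rx, ry))
        den = (sum((a - mean_rx) ** 2 for a in rx)
               * sum((b - mean_ry) ** 2 for b in ry)) ** 0.5
        assert rho == pytest.approx(num / den, abs=1e-12)
        # exhaustive permutation p over all 7! orderings
        count = 0
        total = 0
        for perm in itertools.permutations(range(7)):
            total += 1
            ry_p = [ry[i] for i in perm]
            num_p = sum((a - mean_rx) * (b - mean_ry) for a, b in zip(rx, ry_p))
            if abs(num_p / den) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        rho, p = spearman(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, abs=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [2.0, 1.0])


def test_correlate_clinical_on_cohort(small_cohort):
    from myoquiesce.clinical import score_table

    labels = small_cohort.samples["true_phenotype"].to_numpy()
    ref = small_cohort.samples["arm"].isin(["TL", "TNL"]).to_numpy()
    expr = log2_normalized(small_cohort.counts).T
    sig = small_cohort.gene_truth.loc[small_cohort.gene_truth["is_de"], "gene"].tolist()
    m = fit_reference_pca(expr.loc[ref], sig, labels[ref])
    pc1 = pd.Series(m.transform(expr)[:, 0], index=expr.index)
    corr = correlate_clinical(pc1, score_table(small_cohort.samples))
    by_var = corr.set_index("variable")
    # laboring (NQ) samples sit low on PC1, so contraction correlates negatively
    assert by_var.loc["contraction_score", "rho"] < 0
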