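"""The two-gene expression ratio, comparative-Ct arithmetic, ROC analysis,
classification, and the anchor-correlated gene panel."""

import numpy as np
import pandas as pd
import pytest

from myoquiesce.io import (
    ANCHOR_DENOMINATOR,
    ANCHOR_NUMERATOR,
    REFERENCE_GENES,
    CountMatrix,
)
from myoquiesce.de import log2_normalized
from myoquiesce.ratio import (
    RatioThresholdClassifier,
    auc_mann_whitney,
    classify,
    correlated_panel,
    ratio_from_counts,
    ratio_from_ct,
    roc,
)


def _counts(b4, a2, extra=None):
    genes = [ANCHOR_NUMERATOR, ANCHOR_DENOMINATOR]
    rows = [b4, a2]
    if extra is not None:
        genes += [f"G{i}" for i in range(len(extra))]
        rows += list(extra)
    mat = np.array(rows)
    return CountMatrix(genes, [f"s{j}" for j in range(mat.shape[1])], mat)


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "assay", "well", "ct"])


def brute_force_auc(values, is_nq):
    total, n = 0.0, 0
    for i in np.flatnonzero(is_nq):
        for j in np.flatnonzero(~is_nq):
            n += 1
            if values[i] < values[j]:
                total += 1.0
            elif values[i] == values[j]:
                total += 0.5
    return total / n


class TestRatioFromCounts:
    def test_simple_arithmetic(self):
        cm = _counts([500, 50], [100, 100], extra=[[40, 40]])
        r = ratio_from_counts(cm)
        assert r["ratio"].tolist() == [5.0, 0.5]

    def test_raw_and_normalized_modes_identical(self, small_cohort):
        raw = ratio_from_counts(small_cohort.counts, mode="raw")
        norm = ratio_from_counts(small_cohort.counts, mode="normalized")
        np.testing.assert_allclose(raw["ratio"], norm["ratio"], rtol=1e-12)

    def test_zero_denominator_flagged_missing_not_fatal(self):
        cm = _counts([500, 10], [100, 0], extra=[[5, 5]])
        r = ratio_from_counts(cm)
        assert r["ratio"].iloc[0] == 5.0
        assert np.isnan(r["ratio"].iloc[1])

    def test_missing_gene_is_an_error(self):
        cm = CountMatrix(["OTHER"], ["s0"], np.array([[1]]))
        with pytest.raises(KeyError):
            ratio_from_counts(cm)

    def test_recovers_planted_fold_separation(self):
        """Mean Q/NQ ratio separation tracks the planted anchor contrast
        within 15% over replicate cohorts."""
        from myoquiesce.simulate import SimulationConfig, simulate_cohort

        seps = []
        for k in range(50):
            c = simulate_cohort(SimulationConfig(n_genes=120, seed=2000 + k))
            r = ratio_from_counts(c.counts).set_index("sample_id")
            s = c.samples.set_index("sample_id")
            q = r.loc[s.index[s["true_phenotype"] == "Q"], "ratio"].mean()
            nq = r.loc[s.index[s["true_phenotype"] == "NQ"], "ratio"].mean()
            seps.append(q / nq)
        cfg = SimulationConfig()
        planted = 2.0 ** (cfg.atp2a2_lfc - cfg.atp2b4_lfc)
        assert np.mean(seps) == pytest.approx(planted, rel=0.15)


class TestRatioFromCt:
    def test_equal_cts_give_unit_ratio(self):
        ct = _ct_table([("S1", ANCHOR_NUMERATOR, 1, 25.0),
                        ("S1", ANCHOR_DENOMINATOR, 1, 25.0)])
        r = ratio_from_ct(ct)
        assert r["ratio"].iloc[0] == pytest.approx(1.0)

    def test_two_cycle_difference_gives_quarter(self):
        ct = _ct_table([("S1", ANCHOR_NUMERATOR, 1, 26.0),
                        ("S1", ANCHOR_DENOMINATOR, 1, 24.0)])
        r = ratio_from_ct(ct)
        assert r["delta_ct"].iloc[0] == pytest.approx(2.0)
        assert r["ratio"].iloc[0] == pytest.approx(0.25)

    def test_duplicate_wells_averaged_on_ct_scale(self):
        dup = _ct_table([("S1", ANCHOR_NUMERATOR, 1, 24.8),
                         ("S1", ANCHOR_NUMERATOR, 2, 25.2),
                         ("S1", ANCHOR_DENOMINATOR, 1, 25.0)])
        single = _ct_table([("S1", ANCHOR_NUMERATOR, 1, 25.0),
                            ("S1", ANCHOR_DENOMINATOR, 1, 25.0)])
        assert ratio_from_ct(dup)["ratio"].iloc[0] == \
            pytest.approx(ratio_from_ct(single)["ratio"].iloc[0])

    def test_reference_normalized_abundances_use_geometric_mean(self):
        ct = _ct_table([("S1", ANCHOR_NUMERATOR, 1, 26.0),
                        ("S1", ANCHOR_DENOMINATOR, 1, 24.0),
                        ("S1", REFERENCE_GENES[0], 1, 20.0),
                        ("S1", REFERENCE_GENES[1], 1, 22.0)])
        r = ratio_from_ct(ct)
        # Ct_ref = (20 + 22) / 2 = 21 (log2 of the geometric mean)
        assert r[f"rel_{ANCHOR_NUMERATOR}"].iloc[0] == pytest.approx(2.0 ** -(26 - 21))
        assert r[f"rel_{ANCHOR_DENOMINATOR}"].iloc[0] == pytest.approx(2.0 ** -(24 - 21))

    def test_missing_target_assay_rejected(self):
        ct = _ct_table([("S1", ANCHOR_NUMERATOR, 1, 25.0)])
        with pytest.raises(ValueError, match="ATP2A2"):
            ratio_from_ct(ct)

    def test_round_trips_noiseless_simulated_ct(self, small_cohort):
        from myoquiesce.simulate import SimulationConfig, simulate_cohort
        import dataclasses

        cfg = dataclasses.replace(small_cohort.config, ct_noise_sd=0.0)
        cohort = simulate_cohort(cfg)
        r = ratio_from_ct(cohort.ct).set_index("sample_id")
        r = r.loc[cohort.samples["sample_id"]]
        np.testing.assert_allclose(r["ratio"],
                                   cohort.samples["true_ratio"], rtol=1e-10)


class TestRoc:
    def test_perfect_separation(self):
        values = np.array([1.0, 1.5, 2.0, 6.0, 7.0, 9.0])
        labels = np.array(["NQ", "NQ", "NQ", "Q", "Q", "Q"], dtype=object)
        res = roc(values, labels)
        assert res.auc == 1.0
        calls = classify(values, res.threshold)
        assert (calls == labels).all()
        assert 2.0 <= res.threshold < 6.0

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 6, size=16).astype(float)  # heavy ties
        labels = np.where(rng.random(16) < 0.4, "NQ", "Q").astype(object)
        if len(set(labels)) < 2:
            labels[0], labels[1] = "NQ", "Q"
        res = roc(values, labels)
        assert res.auc == pytest.approx(
            brute_force_auc(values, labels == "NQ"), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        values = rng.lognormal(1, 0.8, size=30)
        labels = np.where(rng.random(30) < 0.3, "NQ", "Q").astype(object)
        labels[:2] = ["NQ", "Q"]
        a1 = roc(values, labels).auc
        a2 = roc(np.log(values) * 3 + 7, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_missing_ratios_excluded(self):
        values = np.array([1.0, np.nan, 5.0, 6.0])
        labels = np.array(["NQ", "NQ", "Q", "Q"], dtype=object)
        res = roc(values, labels)
        assert res.n_excluded == 1
        assert res.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc(np.array([1.0, 2.0]), np.array(["Q", "Q"], dtype=object))


class TestClassify:
    def test_threshold_is_inclusive_on_nq_side(self):
        assert classify(np.array([2.41]), 2.41)[0] == "NQ"
        assert classify(np.array([2.42]), 2.41)[0] == "Q"

    def test_transitional_band_arithmetic(self):
        # band 0.1 around tau = 5.12 -> transitional on (4.608, 5.632]
        calls = classify(np.array([5.0, 4.5, 5.7]), 5.12, transitional_band=0.1)
        assert calls.tolist() == ["transitional", "NQ", "Q"]

    def test_zero_band_recovers_binary_partition(self, rng):
        values = rng.lognormal(1, 1, 50)
        calls = classify(values, 3.0, transitional_band=0.0)
        assert set(calls) <= {"NQ", "Q"}
        np.testing.assert_array_equal(calls, np.where(values <= 3.0, "NQ", "Q"))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify(np.array([1.0]), 0.0)


class TestRatioThresholdClassifier:
    def test_fit_learns_youden_threshold_and_predicts(self):
        values = np.array([1.0, 2.0, 2.4, 6.0, 7.0, 8.0])
        labels = np.array(["NQ", "NQ", "NQ", "Q", "Q", "Q"], dtype=object)
        clf = RatioThresholdClassifier().fit(values, labels)
        assert clf.auc_ == 1.0
        assert (clf.predict(values) == labels).all()

    def test_fixed_threshold_override(self):
        clf = RatioThresholdClassifier(threshold=2.41)
        values = np.array([1.0, 3.0, 6.0, 7.0])
        labels = np.array(["NQ", "NQ", "Q", "Q"], dtype=object)
        clf.fit(values, labels)
        assert clf.threshold_ == 2.41
        assert clf.predict(np.array([2.41, 2.42])).tolist() == ["NQ", "Q"]

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clf = RatioThresholdClassifier(threshold=5.12, transitional_band=0.1)
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()


class TestCorrelatedPanel:
    def _expr(self, rng, n_samples=10):
        anchor = rng.normal(8, 1, n_samples)
        rows = {"ATP2B4": anchor,
                "LINEAR": 2.0 * anchor + 1.0,
                "NEGATED": -anchor,
                "NOISE": rng.normal(8, 1, n_samples)}
        return pd.DataFrame(rows).T

    def test_exact_linear_transform_included_with_r_one(self, rng):
        panel = correlated_panel(self._expr(rng), "ATP2B4")
        assert "LINEAR" in panel["gene"].tolist()
        assert panel.set_index("gene").loc["LINEAR", "r"] == pytest.approx(1.0)

    def test_negated_anchor_excluded_one_sided(self, rng):
        panel = correlated_panel(self._expr(rng), "ATP2B4")
        assert "NEGATED" not in panel["gene"].tolist()

    def test_anchor_itself_excluded(self, rng):
        panel = correlated_panel(self._expr(rng), "ATP2B4", r_min=-1.1)
        assert "ATP2B4" not in panel["gene"].tolist()

    def test_matches_brute_force_pearson(self, rng):
        mat = rng.normal(5, 2, size=(100, 8))
        expr = pd.DataFrame(mat, index=[f"G{i:03d}" for i in range(100)])
        panel = correlated_panel(expr, "G000", r_min=-1.1).set_index("gene")
        x = mat[0]
        for i in range(1, 100):
            y = mat[i]
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert panel.loc[f"G{i:03d}", "r"] == pytest.approx(num / den, abs=1e-12)

    def test_constant_anchor_rejected(self):
        expr = pd.DataFrame({"ATP2B4": [5.0] * 4, "G1": [1.0, 2.0, 3.0, 4.0]}).T
        with pytest.raises(ValueError, match="constant"):
            correlated_panel(expr, "ATP2B4")

    def test_too_few_samples_rejected(self, rng):
        expr = self._expr(rng, n_samples=2)
        with pytest.raises(ValueError):
            correlated_panel(expr, "ATP2B4")


def test_cohort_ratio_separates_planted_phenotypes(small_cohort):
    r = ratio_from_counts(small_cohort.counts)
    labels = small_cohort.samples["true_phenotype"].to_numpy()
    assert roc(r, labels).auc >= 0.95
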