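import numpy as np
import pytest

from smtl import (
    ExperimentConfig,
    confusion_metrics,
    henze_zirkler,
    nested_model_selection,
    paired_ttest,
    stratified_folds,
)
from smtl.synthetic import preset_scenarios, generate

from oracles import auc_all_pairs


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 1, -1, -1])
        m = confusion_metrics(y, y, scores=np.array([2.0, 1.0, -1.0, -2.0]))
        assert (m.ACC, m.SEN, m.SPEC, m.BAC, m.AUC) == (1, 1, 1, 1, 1)

    def test_hand_built_counts(self):
        # TP=3, FN=1, TN=2, FP=2
        y_true = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        y_pred = np.array([1, 1, 1, -1, 1, 1, -1, -1])
        m = confusion_metrics(y_true, y_pred)
        assert m.counts.TP == 3 and m.counts.FN == 1
        assert m.counts.TN == 2 and m.counts.FP == 2
        assert m.ACC == pytest.approx(5 / 8)
        assert m.SEN == pytest.approx(0.75)
        assert m.SPEC == pytest.approx(0.5)
        assert m.BAC == pytest.approx(0.625)
        assert m.BAC == (m.SEN + m.SPEC) / 2  # exact identity
        assert np.isnan(m.AUC)  # no scores supplied

    def test_toy_auc(self):
        y = np.array([1, -1, 1, -1])
        s = np.array([0.9, 0.8, 0.4, 0.3])
        m = confusion_metrics(y, y, scores=s)
        assert m.AUC == pytest.approx(0.75)

    def test_auc_matches_all_pairs_brute_force(self, rng):
        for _ in range(10):
            y = np.where(rng.standard_normal(20) > 0, 1, -1)
            y[:2] = [1, -1]  # both classes present
            s = np.round(rng.standard_normal(20), 1)  # provoke ties
            m = confusion_metrics(y, y, scores=s)
            assert m.AUC == pytest.approx(auc_all_pairs(y, s))

    def test_missing_class_is_nan_not_zero(self):
        y_true = np.array([1, 1, 1])
        m = confusion_metrics(y_true, np.array([1, -1, 1]))
        assert np.isnan(m.SPEC) and np.isnan(m.BAC)
        assert m.SEN == pytest.approx(2 / 3)


class TestStratifiedFolds:
    def test_balanced_divisible_case(self):
        labels = np.array([1] * 20 + [-1] * 20)
        folds = stratified_folds(labels, 10, seed=0)
        for f in range(10):
            mask = folds == f
            assert (labels[mask] == 1).sum() == 2
            assert (labels[mask] == -1).sum() == 2

    def test_imbalanced_near_equal_sizes(self):
        labels = np.array([1] * 51 + [-1] * 52)
        folds = stratified_folds(labels, 10, seed=3)
        for cls in (1, -1):
            sizes = [((folds == f) & (labels == cls)).sum() for f in range(10)]
            assert max(sizes) - min(sizes) <= 1
        assert np.bincount(folds).sum() == 103

    def test_deterministic_under_seed(self):
        labels = np.array([1] * 15 + [-1] * 17)
        f1 = stratified_folds(labels, 5, seed=42)
        f2 = stratified_folds(labels, 5, seed=42)
        np.testing.assert_array_equal(f1, f2)

    def test_class_smaller_than_fold_count_rejected(self):
        labels = np.array([1] * 3 + [-1] * 20)
        with pytest.raises(ValueError, match="fewer samples"):
            stratified_folds(labels, 5, seed=0)


class TestPairedTTest:
    def test_identical_vectors(self):
        r = paired_ttest([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert (r.t, r.p) == (0.0, 1.0) and r.degenerate

    def test_constant_nonzero_difference_is_degenerate(self):
        r = paired_ttest([1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0])
        assert r.degenerate and np.isinf(r.t) and r.t > 0

    def test_closed_form_small_example(self):
        # differences [1, 2, 3]: mean 2, sd 1, df 2
        r = paired_ttest([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert r.t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert r.p == pytest.approx(0.0742, abs=2e-4)
        assert not r.degenerate

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0])


class TestHenzeZirkler:
    def test_agrees_with_independent_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for n, p in ((50, 2), (120, 4)):
            X = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
            hz, pval, _ = henze_zirkler(X)
            ref = pingouin.multivariate_normality(X)
            assert hz == pytest.approx(ref.hz, abs=1e-10)
            assert pval == pytest.approx(ref.pval, abs=1e-10)

    def test_affine_invariance(self, rng):
        X = rng.standard_normal((80, 3))
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)  # invertible
        hz1, _, _ = henze_zirkler(X)
        hz2, _, _ = henze_zirkler(X @ A + rng.standard_normal(3))
        assert hz1 == pytest.approx(hz2, abs=1e-8)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="more samples"):
            henze_zirkler(rng.standard_normal((3, 5)))


class TestNestedModelSelection:
    def test_singleton_grids_return_that_configuration(self):
        table, _ = generate(preset_scenarios(seed=0)["unimodal"])
        config = ExperimentConfig(
            K_grid=(2,), lambda1_grid=(0.1,), lambda2_grid=(0.1,),
            C_grid=(1.0,), n_inner_folds=2, max_iter=200, rel_tol=1e-4,
        )
        fitted = nested_model_selection(table, config, "SMTL", seed=0)
        assert fitted.params["K"] == 2
        assert fitted.params["lambda_frac"] == 0.1
        assert fitted.params["C"] == 1.0

    def test_deterministic_under_seed(self):
        table, _ = generate(preset_scenarios(seed=1)["unimodal"])
        config = ExperimentConfig.reduced(n_inner_folds=3)
        f1 = nested_model_selection(table, config, "STL", seed=5)
        f2 = nested_model_selection(table, config, "STL", seed=5)
        assert f1.params == f2.params
        np.testing.assert_array_equal(f1.selection.selected, f2.selection.selected)

    def test_unknown_method_rejected(self):
        table, _ = generate(preset_scenarios(seed=0)["unimodal"])
        with pytest.raises(ValueError, match="method"):
            nested_model_selection(table, ExperimentConfig.reduced(), "PCA")

    def test_independent_subclass_counts_can_differ(self):
        table, _ = generate(preset_scenarios(seed=0)["unimodal"])
        config = ExperimentConfig(
            K_grid=(1, 2), lambda1_grid=(0.2,), lambda2_grid=(0.2,),
            C_grid=(1.0,), n_inner_folds=2, independent_K=True,
            max_iter=200, rel_tol=1e-4,
        )
        fitted = nested_model_selection(table, config, "SMTL", seed=0)
        assert {"K_plus", "K_minus"} <= set(fitted.params)
        assert fitted.params["K_plus"] in (1, 2)
        assert fitted.params["K_minus"] in (1, 2)
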