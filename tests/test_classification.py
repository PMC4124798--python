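import numpy as np
import pytest

from smtl import (
    combine_kernels,
    modality_kernels,
    grid_search_modality_weights,
    simplex_lattice,
    train_mk_svm,
    train_svm,
)
from smtl.classification import linear_kernel, mk_decision_scores
from smtl.selection import SelectionResult


def selection_of(indices, d):
    norms = np.zeros(d)
    norms[list(indices)] = 1.0
    return SelectionResult(selected=np.asarray(indices, dtype=int),
                           tolerance=1e-6, row_norms=norms,
                           empty=len(indices) == 0)


class TestTrainSvm:
    def test_separable_symmetric_configuration(self):
        X = np.array([[1.0, 1.0], [2.0, 1.0], [-1.0, -1.0], [-2.0, -1.0]])
        y = np.array([1, 1, -1, -1])
        clf = train_svm(X, y, C=1e6)
        assert (clf.predict(X) == y).all()
        # midplane passes between the class means: the origin scores ~0
        assert abs(clf.decision_scores(np.zeros((1, 2)))[0]) < 1e-6

    def test_label_flip_negates_decision_scores(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.where(rng.standard_normal(20) > 0, 1, -1)
        if len(set(y.tolist())) < 2:
            y[0] = -y[0]
        s1 = train_svm(X, y, C=1.0).decision_scores(X)
        s2 = train_svm(X, -y, C=1.0).decision_scores(X)
        # the dual solver stops at a finite tolerance, hence atol
        np.testing.assert_allclose(s1, -s2, atol=5e-3)

    def test_one_dimensional_threshold_at_zero(self):
        X = np.array([[-1.0], [1.0]])
        clf = train_svm(X, np.array([-1, 1]), C=1e6)
        assert abs(clf.decision_scores(np.zeros((1, 1)))[0]) < 1e-9
        assert clf.predict(np.array([[0.2], [-0.2]])).tolist() == [1, -1]

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="both classes"):
            train_svm(X, np.ones(5, dtype=int), C=1.0)
        with pytest.raises(ValueError, match="C"):
            train_svm(X, np.array([1, 1, 1, -1, -1]), C=0.0)


class TestSimplexLattice:
    @pytest.mark.parametrize("m,expected", [(1, 1), (2, 11), (3, 66)])
    def test_lattice_sizes_at_step_0p1(self, m, expected):
        grid = simplex_lattice(m, 0.1)
        assert len(grid) == expected
        assert all(abs(sum(b) - 1.0) < 1e-9 for b in grid)

    def test_step_must_divide_one(self):
        with pytest.raises(ValueError, match="divide"):
            simplex_lattice(2, 0.3)


class TestModalityKernels:
    def test_single_modality_equals_plain_linear_kernel(self, small_table):
        # collapse to one modality
        t = small_table
        t.modality_of = {j: "A" for j in range(t.n_features)}
        sel = selection_of([0, 2, 4], t.n_features)
        kernels = modality_kernels(t, sel)
        assert list(kernels) == ["A"]
        np.testing.assert_allclose(
            kernels["A"].matrix, linear_kernel(t.X[:, [0, 2, 4]])
        )

    def test_degenerate_weight_selects_one_kernel(self, small_table):
        sel = selection_of([0, 1, 3, 4], small_table.n_features)
        kernels = modality_kernels(small_table, sel)
        K = combine_kernels(kernels, {"A": 1.0, "B": 0.0})
        np.testing.assert_allclose(K, kernels["A"].matrix)

    def test_half_half_on_identical_copies_reproduces_single_copy(self, rng):
        from smtl import FeatureTable
        X_half = rng.standard_normal((8, 3))
        X = np.hstack([X_half, X_half])
        t = FeatureTable(
            sample_ids=[f"s{i}" for i in range(8)],
            X=X,
            labels=np.array([1, 1, 1, 1, -1, -1, -1, -1]),
            modality_of={0: "A", 1: "A", 2: "A", 3: "B", 4: "B", 5: "B"},
            feature_names=[f"f{j}" for j in range(6)],
        )
        sel = selection_of(list(range(6)), 6)
        kernels = modality_kernels(t, sel)
        K = combine_kernels(kernels, {"A": 0.5, "B": 0.5})
        np.testing.assert_allclose(K, linear_kernel(X_half), atol=1e-10)

    def test_modality_with_no_selected_features_is_flagged(self, small_table):
        sel = selection_of([0, 1], small_table.n_features)  # only modality A
        kernels = modality_kernels(small_table, sel)
        assert kernels["B"].empty
        np.testing.assert_array_equal(kernels["B"].matrix, 0.0)

    def test_empty_selection_rejected(self, small_table):
        with pytest.raises(ValueError, match="no selected"):
            modality_kernels(small_table, selection_of([], small_table.n_features))

    def test_combined_kernel_psd_over_the_lattice(self, small_table, rng):
        sel = selection_of([0, 1, 3, 4], small_table.n_features)
        kernels = modality_kernels(small_table, sel)
        for beta_t in simplex_lattice(2, 0.1):
            K = combine_kernels(kernels, dict(zip(["A", "B"], beta_t)))
            np.testing.assert_allclose(K, K.T, atol=1e-9)
            assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestMultiKernelConsistency:
    def test_unit_weight_mk_equals_sk_on_that_modality(self, rng):
        from smtl import FeatureTable
        n = 30
        X = rng.standard_normal((n, 6))
        y = np.array([1] * 15 + [-1] * 15)
        X[y == 1, 0] += 1.5
        X[y == 1, 3] += 0.5
        t = FeatureTable(
            sample_ids=[f"s{i}" for i in range(n)], X=X, labels=y,
            modality_of={0: "A", 1: "A", 2: "A", 3: "B", 4: "B", 5: "B"},
            feature_names=[f"f{j}" for j in range(6)],
        )
        sel = selection_of([0, 1, 3, 5], 6)
        tr = np.arange(0, n, 2)
        te = np.arange(1, n, 2)
        t_tr = t.subset_samples(tr)
        kernels = modality_kernels(t_tr, sel)
        for C in (0.5, 2.0):
            mk = train_mk_svm(kernels, y[tr], {"A": 1.0, "B": 0.0}, C)
            cross = {
                "A": linear_kernel(X[np.ix_(te, [0, 1])], X[np.ix_(tr, [0, 1])]),
                "B": linear_kernel(X[np.ix_(te, [3, 5])], X[np.ix_(tr, [3, 5])]),
            }
            scores_mk = mk_decision_scores(mk, cross)
            sk = train_svm(X[np.ix_(tr, [0, 1])], y[tr], C)
            scores_sk = sk.decision_scores(X[np.ix_(te, [0, 1])])
            np.testing.assert_allclose(scores_mk, scores_sk, atol=1e-6)

    def test_grid_search_single_modality_skips_search(self, rng):
        K = linear_kernel(rng.standard_normal((20, 4)))
        y = np.array([1] * 10 + [-1] * 10)
        beta, C, acc = grid_search_modality_weights(
            {"A": K}, y, C_grid=(1.0,), step=0.1, inner_folds=2, seed=0
        )
        assert beta == {"A": 1.0}

    def test_grid_search_weight_sum_and_tie_breaking(self, rng):
        n = 24
        X = rng.standard_normal((n, 4))
        y = np.array([1] * 12 + [-1] * 12)
        X[y == 1, 0] += 3.0  # modality A informative, B pure noise
        KA = linear_kernel(X[:, :2])
        KB = linear_kernel(X[:, 2:])
        beta, C, acc = grid_search_modality_weights(
            {"A": KA, "B": KB}, y, C_grid=(0.25, 1.0), step=0.5,
            inner_folds=3, seed=1,
        )
        assert abs(sum(beta.values()) - 1.0) < 1e-9
        assert beta["A"] >= 0.5  # informative modality dominates
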