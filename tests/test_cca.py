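"""Two-view CCA: oracle equivalence, invariances, augmentation."""

import numpy as np
import pytest

from neurofuse import (
    CCAFusion,
    CohortSpec,
    augment_features,
    fit_cca,
    generate_paired_vectors,
    project_cca,
)
from neurofuse.cca import load_cca, save_cca
from neurofuse.exceptions import InputDataError, NumericalError

from _oracles import cca_correlations_oracle


class TestFit:
    def test_identical_views_perfectly_correlated(self, rng):
        X = rng.standard_normal((50, 4))
        model = CCAFusion(epsilon=0.0).fit(X, X)
        np.testing.assert_allclose(model.correlations_, 1.0, atol=1e-8)

    def test_invariance_under_invertible_linear_map(self, rng):
        X = rng.standard_normal((20, 3))
        A = np.array([[2.0, 1.0, 0.0], [0.0, 1.0, 3.0], [1.0, 0.0, 1.0]])
        assert abs(np.linalg.det(A)) > 1e-6
        ref = CCAFusion(n_components=3, epsilon=0.0).fit(X, X)
        mapped = CCAFusion(n_components=3, epsilon=0.0).fit(X, X @ A.T)
        np.testing.assert_allclose(
            mapped.correlations_, ref.correlations_, atol=1e-8
        )

    @pytest.mark.parametrize("eps", [0.0, 1e-2])
    def test_matches_whitening_svd_oracle(self, rng, eps):
        for _ in range(10):
            d = int(rng.integers(2, 11))
            n = int(rng.integers(d + 3, 51))
            X = rng.standard_normal((n, d))
            Y = rng.standard_normal((n, d))
            model = CCAFusion(n_components=d, epsilon=eps).fit(X, Y)
            oracle = cca_correlations_oracle(X, Y, eps)
            np.testing.assert_allclose(
                model.correlations_, oracle[: model.n_components_],
                atol=1e-8,
            )

    def test_basis_orthogonality_in_regularized_metric(self, rng):
        X = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 6))
        eps = 1e-2
        m = CCAFusion(n_components=6, epsilon=eps).fit(X, Y)
        Xc = X - X.mean(axis=0)
        S11 = Xc.T @ Xc / 39 + eps * np.eye(6)
        gram = m.B1_.T @ S11 @ m.B1_
        np.testing.assert_allclose(gram, np.eye(m.n_components_), atol=1e-8)

    def test_column_permutation_equivariance(self, rng):
        X = rng.standard_normal((30, 4))
        Y = rng.standard_normal((30, 4))
        perm = rng.permutation(30)
        a = CCAFusion(n_components=4, epsilon=1e-3).fit(X, Y)
        b = CCAFusion(n_components=4, epsilon=1e-3).fit(X[perm], Y[perm])
        np.testing.assert_allclose(b.correlations_, a.correlations_,
                                   atol=1e-8)
        Za, _ = a.transform(X, Y)
        Zb, _ = b.transform(X[perm], Y[perm])
        np.testing.assert_allclose(Zb, Za[perm], atol=1e-8)

    def test_rank_deficient_without_ridge_raises(self, rng):
        X = rng.standard_normal((5, 10))  # d > n: singular covariance
        Y = rng.standard_normal((5, 10))
        with pytest.raises(NumericalError, match="epsilon"):
            CCAFusion(epsilon=0.0).fit(X, Y)
        CCAFusion(epsilon=1e-3).fit(X, Y)  # regularized fit succeeds

    def test_input_errors(self, rng):
        X = rng.standard_normal((2, 3))
        with pytest.raises(InputDataError, match="3 subjects"):
            CCAFusion().fit(X, X)
        with pytest.raises(InputDataError, match="equal subject counts"):
            CCAFusion().fit(rng.standard_normal((10, 3)),
                            rng.standard_normal((9, 3)))


class TestProjection:
    def test_training_projections_reproduce_correlations(self, rng):
        X = rng.standard_normal((40, 5))
        Y = 0.5 * X + 0.5 * rng.standard_normal((40, 5))
        model = fit_cca(X, Y, epsilon=0.0)
        Z1, Z2 = project_cca(model, X, Y)
        for i, rho in enumerate(model.correlations_):
            r = np.corrcoef(Z1[:, i], Z2[:, i])[0, 1]
            assert r == pytest.approx(rho, abs=1e-8)

    def test_single_column_is_plain_matrix_arithmetic(self, rng):
        X = rng.standard_normal((20, 4))
        Y = rng.standard_normal((20, 4))
        model = fit_cca(X, Y, epsilon=1e-3)
        x = rng.standard_normal((1, 4))
        y = rng.standard_normal((1, 4))
        Z1, Z2 = model.transform(x, y)
        np.testing.assert_allclose(Z1, (x - model.mean1_) @ model.B1_)
        np.testing.assert_allclose(Z2, (y - model.mean2_) @ model.B2_)

    def test_dimension_mismatch_raises(self, rng):
        model = fit_cca(rng.standard_normal((10, 4)),
                        rng.standard_normal((10, 4)), epsilon=1e-3)
        with pytest.raises(InputDataError, match="dimension"):
            model.transform(rng.standard_normal((2, 5)),
                            rng.standard_normal((2, 4)))

    def test_heldout_leading_correlation_with_strong_shared_signal(self):
        # Train/test split of a strongly shared cohort: the leading
        # component generalizes (mean over 5 cohort seeds >= 0.8).
        leading = []
        for seed in range(5):
            spec = CohortSpec(n_per_class=100, latent_dim=4,
                              shared_effect=1.0, modality_noise=0.2,
                              seed=seed)
            X1, X2, _ = generate_paired_vectors(spec, d=10)
            order = np.random.default_rng(seed).permutation(400)
            tr, te = order[:200], order[200:]
            model = fit_cca(X1[tr], X2[tr])
            Z1, Z2 = model.transform(X1[te], X2[te])
            leading.append(np.corrcoef(Z1[:, 0], Z2[:, 0])[0, 1])
        assert np.mean(leading) >= 0.8


class TestAugmentation:
    def test_block_layout_and_round_trip(self, rng):
        X1 = rng.standard_normal((3, 2))
        X2 = rng.standard_normal((3, 2))
        Z1 = rng.standard_normal((3, 2))
        Z2 = rng.standard_normal((3, 2))
        aug = augment_features(X1, X2, Z1, Z2)
        assert aug.F.shape == (3, 8)
        np.testing.assert_array_equal(aug.F[:, :2], X1)
        for name, block in zip(("X1", "X2", "Z1", "Z2"), (X1, X2, Z1, Z2)):
            np.testing.assert_array_equal(aug.block(name), block)

    def test_subject_count_mismatch_raises(self, rng):
        with pytest.raises(InputDataError, match="subject count"):
            augment_features(
                rng.standard_normal((3, 2)), rng.standard_normal((4, 2)),
                rng.standard_normal((3, 1)), rng.standard_normal((3, 1)),
            )


def test_model_persistence_round_trip(tmp_path, rng):
    X = rng.standard_normal((25, 6))
    Y = rng.standard_normal((25, 6))
    model = fit_cca(X, Y, epsilon=1e-3)
    path = tmp_path / "cca.npz"
    save_cca(model, path)
    back = load_cca(path)
    np.testing.assert_array_equal(back.B1_, model.B1_)
    np.testing.assert_array_equal(back.B2_, model.B2_)
    np.testing.assert_array_equal(back.correlations_, model.correlations_)
    assert back.epsilon_ == model.epsilon_
    Z1a, Z2a = model.transform(X, Y)
    Z1b, Z2b = back.transform(X, Y)
    np.testing.assert_array_equal(Z1a, Z1b)
    np.testing.assert_array_equal(Z2a, Z2b)
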