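"""Normalization schemes and explicit kernel feature maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.kernel_approximation import AdditiveChi2Sampler

from neurofuse import (
    HomogeneousKernelMap,
    KernelMapConfig,
    L2AL2W,
    NormalizationConfig,
    apply_kernel_map,
    chi2_kernel_exact,
    js_kernel_exact,
    lp_normalize,
    normalize_cohort_l2al2w,
    power_normalize,
    vector_normalize,
)
from neurofuse.exceptions import ConfigurationError, InputDataError


class TestVectorNormalize:
    def test_signed_square_root(self):
        np.testing.assert_allclose(
            power_normalize(np.array([4.0, -9.0, 0.0]), 0.5),
            [2.0, -3.0, 0.0],
        )

    def test_l2(self):
        np.testing.assert_allclose(lp_normalize(np.array([3.0, 4.0]), 2),
                                   [0.6, 0.8])

    def test_l1_then_l2_on_uniform_vector(self):
        cfg = NormalizationConfig(order=("l1", "l2"))
        out = vector_normalize(np.array([2.0, 2.0, 2.0, 2.0]), cfg)
        np.testing.assert_allclose(out, [0.5, 0.5, 0.5, 0.5])

    def test_zero_vector_guard(self):
        z = np.zeros(4)
        np.testing.assert_array_equal(lp_normalize(z, 2), z)
        np.testing.assert_array_equal(lp_normalize(z, 1), z)

    def test_non_finite_input_raises(self):
        with pytest.raises(InputDataError, match="finite"):
            power_normalize(np.array([1.0, np.inf]))

    def test_invalid_scheme_and_rho(self):
        with pytest.raises(ConfigurationError, match="rho"):
            NormalizationConfig(rho=1.5)
        with pytest.raises(ConfigurationError, match="scheme"):
            NormalizationConfig(order=("l3",))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=12))
    def test_power_preserves_sign_zero_and_units(self, values):
        v = np.array(values)
        out = power_normalize(v, 0.5)
        np.testing.assert_array_equal(np.sign(out), np.sign(v))
        assert np.all(out[v == 0] == 0)
        np.testing.assert_allclose(out[np.abs(v) == 1], v[np.abs(v) == 1])
        # strictly monotone per component
        order = np.argsort(v)
        assert np.all(np.diff(out[order]) >= 0)


class TestL2AL2W:
    def test_two_step_arithmetic(self):
        train = np.array([[3.0, 0.0], [4.0, 0.0]])
        out, _ = normalize_cohort_l2al2w(train)
        np.testing.assert_allclose(out, [[1.0, 0.0], [1.0, 0.0]])

    def test_rows_have_unit_norm(self, rng):
        train = rng.uniform(0, 2, size=(8, 5))
        test = rng.uniform(0, 2, size=(4, 5))
        tr, te = normalize_cohort_l2al2w(train, test)
        np.testing.assert_allclose(np.linalg.norm(tr, axis=1), 1.0)
        np.testing.assert_allclose(np.linalg.norm(te, axis=1), 1.0)

    def test_train_statistics_applied_to_test(self, rng):
        train = rng.uniform(1, 2, size=(6, 3))
        model = L2AL2W(within=False).fit(train)
        test = rng.uniform(1, 2, size=(2, 3))
        out = model.transform(test)
        np.testing.assert_allclose(out,
                                   test / np.linalg.norm(train, axis=0))

    def test_order_does_not_commute(self, rng):
        X = rng.uniform(0.1, 3, size=(5, 4))
        # across-then-within
        aw = L2AL2W().fit(X).transform(X)
        # within-then-across
        rows = lp_normalize(X, 2)
        wa = rows / np.linalg.norm(rows, axis=0)
        assert np.max(np.abs(aw - wa)) > 1e-6

    def test_dimension_mismatch(self, rng):
        model = L2AL2W().fit(rng.uniform(size=(3, 4)))
        with pytest.raises(InputDataError, match="dimension"):
            model.transform(rng.uniform(size=(3, 5)))


class TestKernelMaps:
    def test_hellinger_exact_identity(self):
        x = np.array([4.0, 9.0])
        y = np.array([1.0, 1.0])
        cfg = KernelMapConfig("hellinger")
        dot = apply_kernel_map(x, cfg) @ apply_kernel_map(y, cfg)
        assert dot == pytest.approx(5.0)
        assert dot == pytest.approx(np.sum(np.sqrt(x * y)))

    def test_linear_is_identity(self, rng):
        v = rng.normal(size=7)
        np.testing.assert_array_equal(
            apply_kernel_map(v, KernelMapConfig("linear")), v
        )

    def test_hellinger_l2_equals_power_half_l2(self, rng):
        v = rng.uniform(0, 5, size=10)
        lhs = lp_normalize(apply_kernel_map(v, KernelMapConfig("hellinger")), 2)
        rhs = lp_normalize(power_normalize(v, 0.5), 2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    @pytest.mark.parametrize(
        "kind,exact",
        [("kchi2", chi2_kernel_exact), ("kjs", js_kernel_exact)],
    )
    def test_sampled_maps_approximate_closed_form(self, rng, kind, exact):
        cfg = KernelMapConfig(kind, order_n=3)
        for _ in range(100):
            x = rng.uniform(0, 1, size=10)
            y = rng.uniform(0, 1, size=10)
            approx = apply_kernel_map(x, cfg) @ apply_kernel_map(y, cfg)
            k = exact(x, y)
            assert abs(approx - k) <= 0.02 * k

    @pytest.mark.parametrize(
        "kind,exact",
        [("kchi2", chi2_kernel_exact), ("kjs", js_kernel_exact)],
    )
    def test_error_decreases_with_order(self, rng, kind, exact):
        pairs = [(rng.uniform(0, 1, 8), rng.uniform(0, 1, 8))
                 for _ in range(50)]
        errs = []
        for n in (1, 3, 5):
            cfg = KernelMapConfig(kind, order_n=n)
            errs.append(np.mean([
                abs(apply_kernel_map(x, cfg) @ apply_kernel_map(y, cfg)
                    - exact(x, y))
                for x, y in pairs
            ]))
        assert errs[0] > errs[1] > errs[2]

    def test_chi2_map_agrees_with_sklearn_sampler(self, rng):
        # sklearn's sampler uses the same quadrature; sample_steps=3 there
        # corresponds to order_n=2 here (j = 0, 1, 2).
        X = rng.uniform(0, 1, size=(5, 6))
        Y = rng.uniform(0, 1, size=(5, 6))
        ours = KernelMapConfig("kchi2", order_n=2, period=0.4)
        A, B = apply_kernel_map(X, ours), apply_kernel_map(Y, ours)
        sk = AdditiveChi2Sampler(sample_steps=3, sample_interval=0.4).fit(X)
        As, Bs = sk.transform(X), sk.transform(Y)
        np.testing.assert_allclose(A @ B.T, As @ Bs.T, atol=1e-10)

    def test_negative_entries_rejected_with_index(self):
        v = np.array([0.5, 1.0, -0.2])
        with pytest.raises(InputDataError, match="index: 2"):
            apply_kernel_map(v, KernelMapConfig("kchi2"))

    def test_zero_maps_to_zero_block(self):
        out = apply_kernel_map(np.array([0.0, 1.0]),
                               KernelMapConfig("kchi2", order_n=2))
        np.testing.assert_array_equal(out[:5], 0.0)

    def test_transformer_shape_contract(self, rng):
        X = rng.uniform(0, 1, size=(4, 6))
        out = HomogeneousKernelMap("kjs", order_n=3).fit(X).transform(X)
        assert out.shape == (4, 6 * 7)
        out = HomogeneousKernelMap("hellinger").fit(X).transform(X)
        assert out.shape == X.shape

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError, match="kind"):
            KernelMapConfig("rbf")
        with pytest.raises(ConfigurationError, match="order_n"):
            KernelMapConfig("kchi2", order_n=0)
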