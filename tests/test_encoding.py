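"""Codebook learning, word assignment, BoVW and VLAD encodings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofuse import (
    Codebook,
    PyramidLayout,
    assign_pyramid_cells,
    assign_words,
    encode_bovw,
    encode_vlad,
    fit_codebook,
)
from neurofuse.exceptions import InputDataError

from conftest import make_dset

SINGLE = PyramidLayout("layer1")
STACKED = PyramidLayout("stacked")


class TestCodebook:
    def test_two_separated_clouds_recover_cloud_means(self, rng):
        a = rng.normal(0.0, 0.05, size=(6, 3))
        b = rng.normal(10.0, 0.05, size=(6, 3)) + np.array([0, 10, 0])
        cb = fit_codebook(np.vstack([a, b]), n_words=2, seed=0)
        expected = np.sort(np.vstack([a.mean(0), b.mean(0)]), axis=0)
        got = np.sort(cb.centroids, axis=0)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_single_word_is_global_mean(self, rng):
        X = rng.normal(size=(30, 4))
        cb = fit_codebook(X, n_words=1, seed=0)
        np.testing.assert_allclose(cb.centroids[0], X.mean(axis=0),
                                   atol=1e-9)

    def test_same_seed_same_centroids(self, rng):
        X = rng.normal(size=(200, 8))
        a = fit_codebook(X, n_words=16, seed=3)
        b = fit_codebook(X, n_words=16, seed=3)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_too_few_distinct_descriptors(self):
        X = np.tile([[1.0, 2.0], [3.0, 4.0]], (5, 1))
        with pytest.raises(InputDataError, match="distinct"):
            fit_codebook(X, n_words=3)
        with pytest.raises(InputDataError, match="empty"):
            fit_codebook(np.empty((0, 2)), n_words=1)

    def test_persistence_round_trip(self, tmp_path, rng):
        cb = fit_codebook(rng.normal(size=(50, 5)), n_words=4, seed=1,
                          train_fold_id="fold-0")
        path = tmp_path / "codebook.npz"
        cb.save(path)
        back = Codebook.load(path)
        np.testing.assert_array_equal(back.centroids, cb.centroids)
        assert back.train_fold_id == "fold-0"


class TestAssignment:
    def test_descriptor_at_centroid_gets_its_index(self):
        cb = Codebook(np.array([[0.0, 0], [5, 0], [0, 5], [9, 9]]))
        assert assign_words(cb, np.array([[9.0, 9.0]]), exact=True)[0] == 3

    def test_tie_broken_toward_lowest_index(self):
        cb = Codebook(np.array([[-1.0, 0.0], [1.0, 0.0]]))
        assert cb.assign(np.array([[0.0, 0.0]]), exact=True)[0] == 0

    def test_dimension_mismatch(self):
        cb = Codebook(np.eye(3))
        with pytest.raises(InputDataError, match="dimension"):
            cb.assign(np.zeros((2, 4)))

    def test_approximate_agrees_with_exact_scan(self, rng):
        cb = fit_codebook(rng.normal(size=(500, 16)), n_words=32, seed=0)
        probes = rng.normal(size=(1000, 16))
        approx = cb.assign(probes, exact=False)
        exact = cb.assign(probes, exact=True)
        assert np.mean(approx == exact) >= 0.99


class TestBoVW:
    def test_counting(self):
        centroids = np.array([[0.0, 0.0], [10.0, 10.0]])
        cb = Codebook(centroids)
        desc = np.array([[0.1, 0], [0, 0.1], [0.2, 0.1], [10, 10], [9.5, 10]])
        enc = encode_bovw(cb, make_dset(desc), SINGLE)
        np.testing.assert_array_equal(enc.vector, [3.0, 2.0])

    def test_layer_partition_additivity(self, rng):
        cb = fit_codebook(rng.normal(size=(60, 4)), n_words=5, seed=0)
        dset = make_dset(rng.normal(size=(40, 4)), seed=1)
        enc = encode_bovw(cb, dset, STACKED)
        K = 5
        layer1 = enc.vector[:K]
        layer2 = enc.vector[K:].reshape(4, K)
        np.testing.assert_array_equal(layer2.sum(axis=0), layer1)
        assert layer1.sum() == len(dset)

    def test_empty_cell_gives_zero_block(self, rng):
        cb = fit_codebook(rng.normal(size=(30, 3)), n_words=2, seed=0)
        # all descriptors in the top-left quadrant of a 2x2 layer
        loc = np.column_stack([np.zeros(10, int),
                               rng.integers(0, 30, 10),
                               rng.integers(0, 30, 10)])
        dset = make_dset(rng.normal(size=(10, 3)), locations=loc)
        enc = encode_bovw(cb, dset, PyramidLayout("layer2", (2, 2)))
        blocks = enc.vector.reshape(4, 2)
        assert blocks[0].sum() == 10
        np.testing.assert_array_equal(blocks[1:], 0.0)

    def test_additivity_over_descriptor_sets(self, rng):
        cb = fit_codebook(rng.normal(size=(40, 3)), n_words=4, seed=0)
        d1 = make_dset(rng.normal(size=(15, 3)), seed=2)
        d2 = make_dset(rng.normal(size=(9, 3)), seed=3)
        both = make_dset(
            np.vstack([d1.descriptors, d2.descriptors]),
            locations=np.vstack([d1.locations, d2.locations]),
        )
        total = encode_bovw(cb, both, STACKED).vector
        parts = (encode_bovw(cb, d1, STACKED).vector
                 + encode_bovw(cb, d2, STACKED).vector)
        np.testing.assert_array_equal(total, parts)


class TestVLAD:
    def test_single_zero_centroid_gives_descriptor_sum(self, rng):
        cb = Codebook(np.zeros((1, 4)))
        desc = rng.normal(size=(12, 4))
        enc = encode_vlad(cb, make_dset(desc), SINGLE)
        np.testing.assert_allclose(enc.vector, desc.sum(axis=0))

    def test_descriptors_at_centroids_give_zero_vector(self):
        centroids = np.array([[1.0, 2.0], [3.0, 4.0]])
        cb = Codebook(centroids)
        desc = centroids[[0, 1, 1, 0, 0]]
        enc = encode_vlad(cb, make_dset(desc), SINGLE)
        np.testing.assert_array_equal(enc.vector, 0.0)

    def test_matches_direct_summation_oracle(self, rng):
        centroids = rng.normal(size=(2, 3))
        cb = Codebook(centroids)
        desc = rng.normal(size=(6, 3))
        enc = encode_vlad(cb, make_dset(desc), SINGLE, exact=True)
        words = cb.assign(desc, exact=True)
        expected = np.zeros((2, 3))
        for x, w in zip(desc, words):
            expected[w] += x - centroids[w]
        np.testing.assert_allclose(enc.vector, expected.ravel())

    def test_additivity_over_descriptor_sets(self, rng):
        cb = fit_codebook(rng.normal(size=(40, 3)), n_words=3, seed=0)
        d1 = make_dset(rng.normal(size=(11, 3)), seed=4)
        d2 = make_dset(rng.normal(size=(7, 3)), seed=5)
        both = make_dset(
            np.vstack([d1.descriptors, d2.descriptors]),
            locations=np.vstack([d1.locations, d2.locations]),
        )
        total = encode_vlad(cb, both, STACKED).vector
        parts = (encode_vlad(cb, d1, STACKED).vector
                 + encode_vlad(cb, d2, STACKED).vector)
        np.testing.assert_allclose(total, parts, atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_residual_mass_conservation(seed):
    """Per cell, Σ_k (v_k + count_k·μ_k) equals the raw descriptor sum."""
    rng = np.random.default_rng(seed)
    M = int(rng.integers(3, 40))
    K = int(rng.integers(1, 6))
    D = int(rng.integers(2, 7))
    centroids = rng.normal(size=(K, D))
    cb = Codebook(centroids)
    dset = make_dset(rng.normal(size=(M, D)), seed=seed)
    layout = PyramidLayout("stacked")
    dset = assign_pyramid_cells(dset, layout)
    vlad = encode_vlad(cb, dset, layout, exact=True).vector
    bovw = encode_bovw(cb, dset, layout, exact=True).vector
    cell_offset = 0
    for li, (gr, gc) in enumerate(layout.grids):
        for cell in range(gr * gc):
            flat_cell = cell_offset + cell
            v = vlad[flat_cell * K * D:(flat_cell + 1) * K * D].reshape(K, D)
            counts = bovw[flat_cell * K:(flat_cell + 1) * K]
            in_cell = dset.cells[li] == cell
            lhs = (v + counts[:, None] * centroids).sum(axis=0)
            rhs = dset.descriptors[in_cell].sum(axis=0)
            np.testing.assert_allclose(lhs, rhs, atol=1e-9)
        cell_offset += gr * gc
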