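"""Matrix construction: seed normalization, symmetrization, bilateral assembly."""

import numpy as np
import pytest

from speechconn import (
    ConnectivityMatrix,
    ValidationError,
    assemble_bilateral,
    edge_index,
    enumerate_edges,
    normalize_by_seed,
    symmetrize,
)


class TestNormalizeBySeed:
    def test_divides_each_row_by_its_seed_count(self):
        raw = np.array([[0.0, 10.0], [6.0, 0.0]])
        m = normalize_by_seed(raw, [5, 3], ["a", "b"])
        np.testing.assert_allclose(m.weights, [[0, 2], [2, 0]])
        assert not m.symmetric

    def test_zero_matrix_stays_zero(self):
        m = normalize_by_seed(np.zeros((3, 3)), [1, 2, 3], list("abc"))
        assert np.all(m.weights == 0)

    def test_matches_elementwise_oracle_on_random_input(self, rng):
        raw = rng.uniform(0, 5, size=(6, 6))
        np.fill_diagonal(raw, 0)
        seeds = rng.integers(1, 50, size=6)
        m = normalize_by_seed(raw, seeds, [f"n{i}" for i in range(6)])
        expected = np.array(
            [[raw[i, j] / seeds[i] for j in range(6)] for i in range(6)]
        )
        np.fill_diagonal(expected, 0)
        np.testing.assert_allclose(m.weights, expected)

    def test_homogeneous_in_raw_densities(self, rng):
        raw = rng.uniform(0, 5, size=(5, 5))
        seeds = rng.integers(1, 9, size=5)
        labels = [f"n{i}" for i in range(5)]
        a = normalize_by_seed(raw, seeds, labels).weights
        b = normalize_by_seed(3.5 * raw, seeds, labels).weights
        np.testing.assert_allclose(b, 3.5 * a)

    def test_nonpositive_seed_count_names_the_node(self):
        with pytest.raises(ValidationError, match="bad_node"):
            normalize_by_seed(np.ones((2, 2)), [5, 0], ["ok", "bad_node"])

    def test_negative_raw_density_rejected(self):
        raw = np.array([[0.0, -1.0], [0.0, 0.0]])
        with pytest.raises(ValidationError, match="negative"):
            normalize_by_seed(raw, [1, 1], ["a", "b"])


class TestSymmetrize:
    def test_printed_formula(self):
        m0 = ConnectivityMatrix(np.array([[0.0, 2.0], [4.0, 0.0]]), ("a", "b"), "intra_left")
        m = symmetrize(m0)
        np.testing.assert_allclose(m.weights, [[0, 3], [3, 0]])
        assert m.symmetric

    def test_idempotent_and_zero_diagonal(self, rng):
        w = rng.uniform(0, 2, size=(28, 28))
        m0 = ConnectivityMatrix(w, tuple(f"n{i}" for i in range(28)), "intra_left")
        m1 = symmetrize(m0)
        m2 = symmetrize(m1)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert np.all(np.diag(m1.weights) == 0)

    def test_matches_transpose_average_oracle(self, rng):
        w = rng.uniform(0, 2, size=(28, 28))
        np.fill_diagonal(w, 0)
        m = symmetrize(ConnectivityMatrix(w, tuple(f"n{i}" for i in range(28)), "intra_left"))
        np.testing.assert_allclose(m.weights, (w + w.T) / 2)

    def test_commissural_input_rejected(self):
        m = ConnectivityMatrix(np.ones((2, 2)), ("a", "b"), "commissural", col_labels=("c", "d"))
        with pytest.raises(ValidationError, match="commissural"):
            symmetrize(m)


class TestAssembleBilateral:
    @staticmethod
    def _blocks(rng, n):
        labels = tuple(f"n{i}" for i in range(n))
        left = symmetrize(
            ConnectivityMatrix(rng.uniform(0, 2, (n, n)), labels, "intra_left")
        )
        right = symmetrize(
            ConnectivityMatrix(rng.uniform(0, 2, (n, n)), labels, "intra_right")
        )
        comm = ConnectivityMatrix(
            rng.uniform(0, 2, (n, n)), labels, "commissural", col_labels=labels
        )
        return left, right, comm

    def test_toy_blocks_placed_intact(self, rng):
        left, right, comm = self._blocks(rng, 2)
        bil = assemble_bilateral(left, right, comm)
        assert bil.weights.shape == (4, 4)
        np.testing.assert_array_equal(bil.weights[:2, :2], left.weights)
        np.testing.assert_array_equal(bil.weights[2:, 2:], right.weights)

    def test_zero_commissural_gives_two_disconnected_blocks(self, rng):
        left, right, _ = self._blocks(rng, 3)
        comm = ConnectivityMatrix(
            np.zeros((3, 3)), left.row_labels, "commissural", col_labels=left.row_labels
        )
        bil = assemble_bilateral(left, right, comm)
        assert np.all(bil.weights[:3, 3:] == 0)
        assert np.all(bil.weights[3:, :3] == 0)

    def test_symmetric_and_block_consistent(self, rng):
        left, right, comm = self._blocks(rng, 7)
        bil = assemble_bilateral(left, right, comm)
        np.testing.assert_array_equal(bil.weights, bil.weights.T)
        expected_offdiag = (comm.weights + comm.weights.T) / 2
        np.testing.assert_allclose(bil.weights[:7, 7:], expected_offdiag)
        assert bil.symmetric

    def test_dimension_mismatch_rejected(self, rng):
        left, right, _ = self._blocks(rng, 3)
        comm4 = ConnectivityMatrix(
            np.zeros((4, 4)),
            tuple(f"x{i}" for i in range(4)),
            "commissural",
            col_labels=tuple(f"y{i}" for i in range(4)),
        )
        with pytest.raises(ValidationError, match="mismatch"):
            assemble_bilateral(left, right, comm4)

    def test_unsymmetrized_intra_block_rejected(self, rng):
        left, right, comm = self._blocks(rng, 3)
        raw_left = ConnectivityMatrix(
            rng.uniform(0, 2, (3, 3)), left.row_labels, "intra_left"
        )
        with pytest.raises(ValidationError, match="symmetriz"):
            assemble_bilateral(raw_left, right, comm)


class TestEnumerateEdges:
    @pytest.mark.parametrize(
        "layout,n,expected",
        [
            ("intra", 28, 378),
            ("intra", 2, 1),
            ("bilateral", 28, 1540),
            ("commissural", 28, 784),
            ("intra", 10, 45),
        ],
    )
    def test_counts(self, layout, n, expected):
        assert enumerate_edges(layout, n) == expected

    @pytest.mark.parametrize("n", range(2, 30))
    def test_bilateral_decomposes_into_intra_plus_commissural(self, n):
        assert enumerate_edges("bilateral", n) == 2 * enumerate_edges(
            "intra", n
        ) + enumerate_edges("commissural", n)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_edges("intra", 1)

    @pytest.mark.parametrize(
        "layout,n_matrix,n_hemi",
        [("intra_left", 28, 28), ("bilateral", 56, 28), ("commissural", 28, 28)],
    )
    def test_edge_index_length_matches_count(self, layout, n_matrix, n_hemi):
        u, v, n_nodes = edge_index(layout, n_matrix)
        assert len(u) == len(v) == enumerate_edges(layout, n_hemi)
        assert np.all(u < v) if layout != "commissural" else np.all(u < n_nodes)


class TestConnectivityMatrixValidation:
    def test_negative_weight_names_cell(self):
        w = np.array([[0.0, 1.0], [-0.5, 0.0]])
        with pytest.raises(ValidationError, match=r"\(b, a\)"):
            ConnectivityMatrix(w, ("a", "b"), "intra_left")

    def test_tsv_roundtrip(self, tmp_path, rng):
        w = rng.uniform(0, 2, (5, 5))
        m = symmetrize(
            ConnectivityMatrix(w, tuple(f"n{i}" for i in range(5)), "intra_left")
        )
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        m2 = ConnectivityMatrix.from_tsv(path, "intra_left", symmetric=True)
        np.testing.assert_allclose(m2.weights, m.weights, rtol=1e-10)
        assert m2.row_labels == m.row_labels

    def test_label_mismatch_on_load_names_file(self, tmp_path):
        m = ConnectivityMatrix(np.zeros((2, 2)), ("a", "b"), "intra_left")
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        with pytest.raises(ValidationError, match="m.tsv"):
            ConnectivityMatrix.from_tsv(path, "intra_left", expected_row_labels=("x", "y"))
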