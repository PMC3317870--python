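"""Contiguity construction, standardisation, lags, spectrum, GAL I/O."""
import numpy as np
import pytest

from spanel import (
    SpatialWeights,
    WeightsFormatError,
    build_lattice_weights,
    eigenvalues,
    read_gal,
    row_standardize,
    spatial_lag,
    write_gal,
)
from spanel.weights import subset_weights


def brute_force_adjacency(rows, cols, scheme):
    """Exhaustive pairwise scan over all cell pairs."""
    pairs = set()
    for a in range(rows * cols):
        for b in range(rows * cols):
            if a == b:
                continue
            ia, ja = divmod(a, cols)
            ib, jb = divmod(b, cols)
            di, dj = abs(ia - ib), abs(ja - jb)
            rookish = di + dj == 1
            queenish = max(di, dj) == 1
            if (scheme == "rook" and rookish) or (scheme == "queen" and queenish):
                pairs.add((a, b))
    return pairs


class TestLattice:
    def test_two_cell_lattice_mutual_neighbours(self):
        w = build_lattice_weights(1, 2, "rook")
        assert w.n == 2
        assert list(w.neighbors[0]) == [1]
        assert list(w.neighbors[1]) == [0]

    @pytest.mark.parametrize(
        "scheme,center,corner", [("rook", 4, 2), ("queen", 8, 3)]
    )
    def test_3x3_neighbour_counts(self, scheme, center, corner):
        w = build_lattice_weights(3, 3, scheme)
        assert w.neighbors[4].size == center
        assert w.neighbors[0].size == corner

    @pytest.mark.parametrize("rows,cols,scheme", [(3, 3, "queen"), (4, 5, "rook")])
    def test_edges_match_exhaustive_scan(self, rows, cols, scheme):
        w = build_lattice_weights(rows, cols, scheme)
        got = {(i, int(j)) for i, nb in enumerate(w.neighbors) for j in nb}
        assert got == brute_force_adjacency(rows, cols, scheme)

    @pytest.mark.parametrize("rows,cols", [(0, 3), (3, -1), (1, 1)])
    def test_bad_dimensions_raise(self, rows, cols):
        with pytest.raises(ValueError):
            build_lattice_weights(rows, cols, "rook")

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            SpatialWeights(
                [np.array([1]), np.array([], dtype=int)],
                [np.ones(1), np.ones(0)],
                ["a", "b"],
            )


class TestStandardize:
    def test_row_division(self):
        w = SpatialWeights(
            [np.array([1, 2]), np.array([0]), np.array([0])],
            [np.array([1.0, 1.0]), np.array([1.0]), np.array([1.0])],
            ["a", "b", "c"],
        )
        ws = row_standardize(w)
        dense = ws.dense()
        assert np.allclose(dense[0], [0, 0.5, 0.5])
        assert ws.standardized

    def test_rows_sum_to_one(self, rook3_std):
        sums = np.asarray(rook3_std.sparse().sum(axis=1)).ravel()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_largest_eigenvalue_is_one_power_iteration(self):
        w = row_standardize(build_lattice_weights(5, 5, "rook"))
        lam = eigenvalues(w)
        assert lam.max() == pytest.approx(1.0, abs=1e-10)
        # independent check: power iteration on the dense matrix
        M = w.dense()
        v = np.ones(w.n) / np.sqrt(w.n)
        for _ in range(500):
            v = M @ v
            v /= np.linalg.norm(v)
        assert float(v @ (M @ v)) == pytest.approx(lam.max(), abs=1e-8)

    def test_island_row_left_zero_with_warning(self):
        w = SpatialWeights(
            [np.array([1]), np.array([0]), np.array([], dtype=int)],
            [np.ones(1), np.ones(1), np.ones(0)],
            ["a", "b", "isle"],
        )
        with pytest.warns(UserWarning, match="island"):
            ws = row_standardize(w)
        assert np.allclose(ws.dense()[2], 0.0)
        with pytest.warns(UserWarning, match="island"):
            lag = spatial_lag(ws, np.array([1.0, 2.0, 3.0]))
        assert lag[2] == 0.0


class TestSpatialLag:
    def test_constant_vector_preserved(self, rook3_std):
        out = spatial_lag(rook3_std, np.full(9, 3.7))
        assert np.allclose(out, 3.7)

    def test_two_cell_swap(self):
        w = row_standardize(build_lattice_weights(1, 2, "rook"))
        assert np.allclose(spatial_lag(w, np.array([2.0, 5.0])), [5.0, 2.0])

    def test_matches_neighbour_mean_loop(self, rook3_std, rng):
        x = rng.standard_normal(9)
        got = spatial_lag(rook3_std, x)
        want = np.array([x[nb].mean() for nb in rook3_std.neighbors])
        assert np.allclose(got, want, atol=1e-12)

    @pytest.mark.parametrize("rows,cols", [(2, 7), (8, 8), (20, 20)])
    def test_agrees_with_dense_matvec(self, rows, cols, rng):
        w = row_standardize(build_lattice_weights(rows, cols, "rook"))
        x = rng.standard_normal(w.n)
        assert np.allclose(spatial_lag(w, x), w.dense() @ x, atol=1e-12)

    def test_length_mismatch(self, rook3_std):
        with pytest.raises(ValueError, match="length"):
            spatial_lag(rook3_std, np.ones(4))


class TestSpectrum:
    def test_exchange_matrix(self):
        w = row_standardize(build_lattice_weights(1, 2, "rook"))
        assert np.allclose(sorted(eigenvalues(w)), [-1.0, 1.0])

    def test_contains_one_and_zero_trace(self, rook3_std):
        lam = eigenvalues(rook3_std)
        assert np.any(np.isclose(lam, 1.0))
        # zero diagonal => trace 0 => eigenvalue sum 0
        assert lam.sum() == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("rows,cols", [(4, 4), (5, 7)])
    def test_matches_general_eigensolver(self, rows, cols):
        import scipy.linalg

        w = row_standardize(build_lattice_weights(rows, cols, "queen"))
        lam = eigenvalues(w)
        ref = scipy.linalg.eigvals(w.dense())
        assert np.abs(ref.imag).max() < 1e-8
        assert np.allclose(np.sort(ref.real), lam, atol=1e-8)

    def test_requires_standardized(self, rook3):
        with pytest.raises(ValueError):
            eigenvalues(rook3)


class TestGal:
    def test_two_unit_roundtrip(self, tmp_path):
        path = tmp_path / "tiny.gal"
        path.write_text("2\nA 1\nB\nB 1\nA\n")
        w = read_gal(path)
        assert w.n == 2 and list(w.neighbors[0]) == [1]

    def test_roundtrip_preserves_queen_pairs(self, tmp_path):
        w = build_lattice_weights(3, 3, "queen")
        path = tmp_path / "queen.gal"
        write_gal(w, path)
        back = read_gal(path)
        orig = {(w.ids[i], w.ids[int(j)]) for i, nb in enumerate(w.neighbors) for j in nb}
        new = {
            (back.ids[i], back.ids[int(j)])
            for i, nb in enumerate(back.neighbors)
            for j in nb
        }
        assert orig == new
        assert len({frozenset(p) for p in new}) == 20

    def test_unknown_id_is_format_error(self, tmp_path):
        path = tmp_path / "bad.gal"
        path.write_text("2\nA 1\nZZZ\nB 1\nA\n")
        with pytest.raises(WeightsFormatError, match="ZZZ"):
            read_gal(path)

    def test_malformed_header(self, tmp_path):
        path = tmp_path / "hdr.gal"
        path.write_text("not-a-number\n")
        with pytest.raises(WeightsFormatError, match="header"):
            read_gal(path)

    def test_asymmetric_file(self, tmp_path):
        path = tmp_path / "asym.gal"
        path.write_text("3\nA 1\nB\nB 0\nC 1\nA\n")
        with pytest.raises(WeightsFormatError, match="asymmetric"):
            read_gal(path)


def test_reorder_preserves_lag_under_matching_permutation(rng):
    from spanel import reorder_weights

    w = row_standardize(build_lattice_weights(4, 12, "rook"))
    order = sorted(w.ids)  # string sort differs from construction order
    w2 = reorder_weights(w, order)
    x = rng.standard_normal(w.n)
    perm = [w.ids.index(uid) for uid in order]
    assert np.allclose(spatial_lag(w2, x[perm]), spatial_lag(w, x)[perm], atol=1e-12)


def test_subset_keeps_prefix_and_drops_dangling_edges():
    w = build_lattice_weights(3, 3, "rook")
    sub = subset_weights(w, 5)
    assert sub.n == 5
    assert all(nb.max(initial=-1) < 5 for nb in sub.neighbors)
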