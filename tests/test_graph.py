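"""Spectral graph machinery: adjacency modes, Laplacian spectra, the
Chebyshev recursion against its eigendecomposition oracle, and the
attention-modulated convolution."""

import numpy as np
import pytest

from seizegraph.autodiff import Tensor
from seizegraph.graph import (build_adjacency, cheb_graph_conv,
                              chebyshev_basis, normalized_scaled_laplacian,
                              spectral_filter_oracle)
from seizegraph.montage import TUSZ_CHANNELS


def random_adjacency(rng, n, p_edge=0.7):
    A = rng.random((n, n)) * (rng.random((n, n)) < p_edge)
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    return A


class TestBuildAdjacency:
    def test_fully_connected_is_ones_minus_identity(self):
        A = build_adjacency("fully_connected", n_channels=3)
        np.testing.assert_array_equal(A, np.ones((3, 3)) - np.eye(3))

    def test_distance_gaussian_symmetric_zero_diagonal(self):
        A = build_adjacency("distance_gaussian",
                            channel_names=list(TUSZ_CHANNELS))
        assert A.shape == (22, 22)
        np.testing.assert_allclose(A, A.T)
        np.testing.assert_array_equal(np.diag(A), 0.0)
        assert (A >= 0).all()
        # nearby channel pairs couple more strongly than distant ones
        i, j = 0, 1            # FP1-F7 vs F7-T3 (adjacent chain)
        k = TUSZ_CHANNELS.index("P4-O2")
        assert A[i, j] > A[i, k]

    def test_correlation_mode_recovers_planted_coupling(self, rng):
        # channels 0-2 share one latent series; 3-5 are independent
        B, C, T = 12, 6, 10
        latent = rng.standard_normal((B, C, T))
        feats = rng.standard_normal((B, 6, C, T))
        feats[:, :3] = latent[:, None] + 0.1 * feats[:, :3]
        A = build_adjacency("correlation", features=feats)
        within = A[np.ix_([0, 1, 2], [0, 1, 2])]
        cross = A[np.ix_([0, 1, 2], [3, 4, 5])]
        assert within[np.triu_indices(3, 1)].mean() > cross.mean()

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_adjacency("distance_gaussian")
        with pytest.raises(ValueError):
            build_adjacency("correlation",
                            features=np.zeros((1, 3, 4, 5)))
        with pytest.raises(ValueError):
            build_adjacency("no_such_mode", n_channels=3)


class TestLaplacian:
    def test_two_node_closed_form(self):
        g = normalized_scaled_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(g.L_sym, [[1, -1], [-1, 1]], atol=1e-12)
        assert abs(g.lambda_max - 2.0) < 1e-12
        np.testing.assert_allclose(g.L_tilde, [[0, -1], [-1, 0]], atol=1e-12)

    def test_complete_graph_k4_spectrum(self):
        A = np.ones((4, 4)) - np.eye(4)
        g = normalized_scaled_laplacian(A)
        eig = np.sort(np.linalg.eigvalsh(g.L_sym))
        np.testing.assert_allclose(eig, [0, 4 / 3, 4 / 3, 4 / 3], atol=1e-12)

    def test_spectra_bounded_over_random_graphs(self, rng):
        for _ in range(100):
            n = rng.integers(2, 9)
            g = normalized_scaled_laplacian(random_adjacency(rng, n))
            ls = np.linalg.eigvalsh(g.L_sym)
            lt = np.linalg.eigvalsh(g.L_tilde)
            assert ls.min() >= -1e-9 and ls.max() <= 2 + 1e-9
            assert lt.min() >= -1 - 1e-9 and lt.max() <= 1 + 1e-9

    def test_isolated_node_handled_with_warning(self, caplog):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        with caplog.at_level("WARNING"):
            g = normalized_scaled_laplacian(A)
        assert "isolated" in caplog.text
        assert np.all(np.isfinite(g.L_sym))

    @pytest.mark.parametrize("A", [
        np.array([[0.0, 1.0], [2.0, 0.0]]),       # asymmetric
        -np.ones((2, 2)),                         # negative
        np.zeros((2, 3)),                         # not square
    ])
    def test_invalid_adjacency_rejected(self, A):
        with pytest.raises(ValueError):
            normalized_scaled_laplacian(A)


class TestChebyshevBasis:
    def test_first_terms(self, rng):
        L = rng.standard_normal((4, 4))
        L = 0.5 * (L + L.T) / 4
        basis = chebyshev_basis(L, 3)
        np.testing.assert_array_equal(basis[0], np.eye(4))
        np.testing.assert_array_equal(basis[1], L)
        np.testing.assert_allclose(basis[2], 2 * L @ L - np.eye(4))

    def test_scalar_recursion_value(self):
        basis = chebyshev_basis(np.array([[0.5]]), 3)
        assert abs(basis[2][0, 0] - (-0.5)) < 1e-12

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(2, 7)
            g = normalized_scaled_laplacian(random_adjacency(rng, n))
            lam, U = np.linalg.eigh(g.L_tilde)
            for k, Tk in enumerate(chebyshev_basis(g.L_tilde, 6)):
                expected = (U * np.cos(k * np.arccos(
                    np.clip(lam, -1, 1)))) @ U.T
                np.testing.assert_allclose(Tk, expected, atol=1e-8)

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            chebyshev_basis(np.eye(2), 0)


class TestChebGraphConv:
    def make(self, rng, n=5, c_in=4, c_out=3, K=3, T=6, B=2):
        g = normalized_scaled_laplacian(random_adjacency(rng, n))
        basis = chebyshev_basis(g.L_tilde, K)
        theta = [Tensor(rng.standard_normal((c_in, c_out)),
                        requires_grad=True) for _ in range(K)]
        X = Tensor(rng.standard_normal((B, n, c_in, T)))
        return g, basis, theta, X

    def test_unmodulated_matches_spectral_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 7))
            g, basis, theta, X = self.make(rng, n=n)
            ones = np.ones((n, n))
            out = cheb_graph_conv(X, Tensor(ones), theta, basis).data
            oracle = spectral_filter_oracle(X.data,
                                            [t.data for t in theta], g)
            np.testing.assert_allclose(out, oracle, rtol=1e-6, atol=1e-9)

    def test_k0_only_with_ones_is_feature_map(self, rng):
        g, basis, theta, X = self.make(rng)
        for th in theta[1:]:
            th.data[:] = 0.0
        out = cheb_graph_conv(X, Tensor(np.ones((5, 5))), theta, basis).data
        expected = np.einsum("bnct,co->bnot", X.data, theta[0].data)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_paper_scale_shapes(self, rng):
        g, basis, theta, X = self.make(rng, n=22, c_in=100, c_out=64,
                                       K=3, T=12, B=2)
        S = Tensor(np.ones((22, 22)))
        assert cheb_graph_conv(X, S, theta, basis).shape == (2, 22, 64, 12)

    def test_zero_attention_entry_annihilates_coupling(self, rng):
        g, basis, theta, X = self.make(rng)
        S = np.ones((5, 5))
        S[1, 2] = 0.0
        out_masked = cheb_graph_conv(X, Tensor(S), theta, basis).data
        # perturb node 2's input: node 1's output must not change through
        # the masked (1,2) coupling beyond multi-hop terms that use other
        # paths; compare against explicit masked-basis computation instead
        expected = sum(
            np.einsum("bnct,co->bnot",
                      np.einsum("nm,bmct->bnct", Tk * S, X.data), th.data)
            for Tk, th in zip(basis, [t.data for t in theta]))
        np.testing.assert_allclose(out_masked, expected, atol=1e-10)

    def test_k_minus_one_hop_locality_on_path_graph(self, rng):
        # 10-node path, K=3: perturbing node 0 must not affect nodes > 2 hops
        n, K = 10, 3
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = 1.0
        g = normalized_scaled_laplacian(A)
        basis = chebyshev_basis(g.L_tilde, K)
        theta = [Tensor(rng.standard_normal((2, 2))) for _ in range(K)]
        X0 = rng.standard_normal((1, n, 2, 4))
        X1 = X0.copy()
        X1[0, 0] += 1.0
        ones = Tensor(np.ones((n, n)))
        y0 = cheb_graph_conv(Tensor(X0), ones, theta, basis).data
        y1 = cheb_graph_conv(Tensor(X1), ones, theta, basis).data
        diff = np.abs(y1 - y0).sum(axis=(0, 2, 3))
        assert diff[:K].max() > 0
        np.testing.assert_array_equal(diff[K:], 0.0)

    def test_kernel_basis_mismatch_rejected(self, rng):
        g, basis, theta, X = self.make(rng)
        with pytest.raises(ValueError):
            cheb_graph_conv(X, Tensor(np.ones((5, 5))), theta[:2], basis)


def test_adjacency_csv_round_trip(tmp_path, rng):
    from seizegraph.graph import adjacency_from_csv, adjacency_to_csv
    A = random_adjacency(rng, 4)
    names = ["C3-CZ", "CZ-C4", "FP1-F7", "FP2-F8"]
    path = tmp_path / "adj.csv"
    adjacency_to_csv(A, names, path)
    A2, names2 = adjacency_from_csv(path)
    np.testing.assert_allclose(A2, A)
    assert names2 == names
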