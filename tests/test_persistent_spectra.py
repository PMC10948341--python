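"""Persistent Laplacians, spectra, Betti numbers, barcodes."""

import math

import networkx as nx
import numpy as np
import pytest

from topodiff import (
    ValidationError,
    WeightedNetwork,
    bars_alive,
    build_clique_complex,
    compute_barcode,
    min_nonharmonic,
    persistent_betti,
    persistent_laplacian,
    spectrum,
    toy_complex,
)
from conftest import random_network, rank_persistent_betti


class TestPersistentLaplacian:
    def test_single_edge_is_k2_graph_laplacian(self):
        K = toy_complex("edge")
        L0 = persistent_laplacian(K, 0, 1.0)
        assert np.allclose(L0, [[1, -1], [-1, 1]])

    def test_hollow_triangle_l1_has_one_harmonic(self):
        K = toy_complex("hollow_triangle")
        s = spectrum(persistent_laplacian(K, 1, 1.0))
        assert s.dim == 3 and s.betti == 1

    def test_matches_networkx_graph_laplacian(self, rng):
        """q=0, p=0 equals degree-minus-adjacency of the snapshot."""
        for _ in range(5):
            net = random_network(rng, n=8, p_edge=0.5)
            K = build_clique_complex(net, q_max=2)
            for t in (0.3, 0.7, 1.0):
                L0 = persistent_laplacian(K, 0, t)
                g = nx.Graph()
                g.add_nodes_from(K.vertices)
                for u, v, c in net.edges():
                    if 1 - c <= t:
                        g.add_edge(u, v)
                ref = nx.laplacian_matrix(g, nodelist=sorted(K.vertices)).toarray()
                assert np.allclose(L0, ref)

    def test_two_independent_constructions_agree(self, rng):
        """Up-term via nullspace projection vs a Schur-complement-style
        elimination of the rows born in (t, t+p]."""
        for _ in range(8):
            K = build_clique_complex(random_network(rng, n=7, p_edge=0.6), q_max=2)
            for q in (0, 1):
                for t, p in ((0.2, 0.3), (0.5, 0.2)):
                    L = persistent_laplacian(K, q, t, p)
                    B = K.full_boundary(q + 1)
                    cols = K.mask(q + 1, t + p)
                    rows_in = K.mask(q, t)
                    rows_out = K.mask(q, t + p) & ~rows_in
                    A = B[np.ix_(rows_in, cols)]
                    C = B[np.ix_(rows_out, cols)]
                    # Schur complement of the C-block normal equations:
                    # project out chains with any boundary outside C_q(t)
                    P = np.eye(C.shape[1]) - np.linalg.pinv(C) @ C
                    up_alt = A @ P @ A.T
                    down = np.zeros_like(up_alt)
                    if q >= 1:
                        Bq = K.full_boundary(q)[np.ix_(K.mask(q - 1, t), rows_in)]
                        down = Bq.T @ Bq
                    assert np.allclose(L, up_alt + down, atol=1e-8)

    def test_empty_dimension_gives_empty_spectrum(self):
        K = toy_complex("two_points")
        L1 = persistent_laplacian(K, 1, 1.0)
        s = spectrum(L1)
        assert L1.shape == (0, 0) and s.betti == 0 and s.lambda_min == 0.0


class TestSpectrum:
    def test_k2(self):
        s = spectrum(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        assert s.eigenvalues == pytest.approx([0.0, 2.0])
        assert persistent_betti(s) == 1 and min_nonharmonic(s) == pytest.approx(2.0)

    def test_zero_matrix(self):
        s = spectrum(np.zeros((4, 4)))
        assert s.betti == 4 and s.lambda_min == 0.0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            spectrum(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_psd_3x3_matches_characteristic_polynomial_roots(self, rng):
        for _ in range(10):
            A = rng.normal(size=(3, 3))
            G = A @ A.T
            s = spectrum(G)
            # coefficients of det(G - x I) via trace invariants
            tr = np.trace(G)
            tr2 = 0.5 * (tr**2 - np.trace(G @ G))
            det = np.linalg.det(G)
            roots = np.sort(np.roots([-1.0, tr, -tr2, det]).real)
            assert s.eigenvalues == pytest.approx(roots, abs=1e-6)

    def test_path3_l0_spectrum(self):
        K = toy_complex("path3")
        s = spectrum(persistent_laplacian(K, 0, 1.0))
        assert s.eigenvalues == pytest.approx([0.0, 1.0, 3.0])
        assert min_nonharmonic(s) == pytest.approx(1.0)

    def test_betti_counts_and_invariants(self, rng):
        """betti + #(eig > tol) = dim; eigenvalues sorted and >= 0."""
        for _ in range(5):
            K = build_clique_complex(random_network(rng), q_max=2)
            for q in (0, 1):
                s = spectrum(persistent_laplacian(K, q, 0.8))
                assert s.betti + int(np.sum(s.eigenvalues > s._zero_cut)) == s.dim
                assert np.all(np.diff(s.eigenvalues) >= 0)
                assert np.all(s.eigenvalues >= 0)

    def test_permutation_invariance(self, rng):
        net = random_network(rng, n=7, p_edge=0.5)
        relabel = {v: f"z{ord(v[1]) * 7 % 13:02d}{v}" for v in net.nodes}
        net2 = WeightedNetwork.from_edges(
            [(relabel[u], relabel[v], c) for u, v, c in net.edges()],
            nodes=[relabel[v] for v in net.nodes],
        )
        for q in (0, 1):
            s1 = spectrum(persistent_laplacian(build_clique_complex(net, 2), q, 0.9))
            s2 = spectrum(persistent_laplacian(build_clique_complex(net2, 2), q, 0.9))
            assert s1.eigenvalues == pytest.approx(s2.eigenvalues, abs=1e-8)


class TestBettiFixtures:
    @pytest.mark.parametrize(
        "name,q,expected",
        [
            ("two_points", 0, 2),
            ("edge", 0, 1),
            ("cycle4", 0, 1),
            ("cycle4", 1, 1),
            ("hollow_triangle", 1, 1),
            ("filled_triangle", 1, 0),
            ("tetrahedron_boundary", 2, 1),
        ],
    )
    def test_known_betti(self, name, q, expected):
        K = toy_complex(name)
        s = spectrum(persistent_laplacian(K, q, 1.0))
        assert persistent_betti(s) == expected


class TestBarcode:
    def test_isolated_vertices_all_essential(self):
        net = WeightedNetwork({}, frozenset(f"n{i}" for i in range(5)))
        K = build_clique_complex(net, q_max=1)
        bars = compute_barcode(K, q_max=0)
        assert len(bars) == 5
        assert all(b.dim == 0 and b.birth == 0.0 and math.isinf(b.death) for b in bars)

    def test_simultaneous_cycle_and_fill_leaves_no_bar(self):
        """Triangle with distances 0.1/0.2/0.3: the 1-cycle closes at
        0.3 and is filled at 0.3, so no persistent dim-1 bar."""
        K = toy_complex("filled_triangle")
        bars = compute_barcode(K, q_max=1)
        assert not [b for b in bars if b.dim == 1]
        d0 = sorted(b for b in bars if b.dim == 0)
        assert len(d0) == 3 and sum(math.isinf(b.death) for b in d0) == 1

    def test_alive_bars_equal_snapshot_betti(self, rng):
        for _ in range(10):
            K = build_clique_complex(random_network(rng, n=8, p_edge=0.5), q_max=2)
            bars = compute_barcode(K, q_max=1)
            for t in (0.0, 0.2, 0.5, 0.8, 1.0):
                for q in (0, 1):
                    s = spectrum(persistent_laplacian(K, q, t))
                    assert bars_alive(bars, q, t) == s.betti

    def test_persistent_betti_matches_rank_oracle(self, rng):
        for _ in range(10):
            K = build_clique_complex(random_network(rng, n=7, p_edge=0.5), q_max=2)
            bars = compute_barcode(K, q_max=1)
            for q in (0, 1):
                for t, p in ((0.1, 0.2), (0.3, 0.3), (0.5, 0.4)):
                    expected = rank_persistent_betti(K, q, t, t + p)
                    assert bars_alive(bars, q, t, p) == expected
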