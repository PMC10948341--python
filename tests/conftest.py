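"""Shared fixtures and independent oracles.

The rank-based persistent Betti oracle here deliberately avoids both
the Laplacian-nullity route and the barcode-reduction route used by the
implementation: it works purely from ranks of snapshot boundary
matrices, via

    beta_q^{t,s} = dim Z_q(t) - dim( B(s) boundaries landing in C_q(t) )
                 = (n_q(t) - rank B_q^t) - (rank B_{q+1}^s - rank B_out)

where B_out is the block of B_{q+1}^s on rows (q-simplices) born in
(t, s]. dim(col(M) ∩ V) = rank(M) - rank(rows outside V) for a
coordinate subspace V.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from topodiff import WeightedNetwork
from topodiff.filtered_complex import FilteredComplex, boundary_matrix


def rank(M: np.ndarray) -> int:
    if M.size == 0:
        return 0
    return int(np.linalg.matrix_rank(M, tol=1e-9))


def rank_persistent_betti(K: FilteredComplex, q: int, t: float, s: float) -> int:
    """Persistent Betti number beta_q^{t -> s} from matrix ranks only."""
    n_q_t = int(K.mask(q, t).sum())
    cycles = n_q_t - rank(boundary_matrix(K, q, t)) if q >= 1 else n_q_t
    if q + 1 > K.q_max:
        return cycles
    B = K.full_boundary(q + 1)
    cols = K.mask(q + 1, s)
    rows_out = K.mask(q, s) & ~K.mask(q, t)
    B_cols = B[:, cols]
    boundaries_in_t = rank(B_cols) - rank(B_cols[rows_out, :])
    return cycles - boundaries_in_t


def brute_force_cliques(net: WeightedNetwork, max_size: int) -> set[tuple[str, ...]]:
    """All cliques up to ``max_size`` by direct pair checking."""
    nodes = sorted(net.nodes)
    cliques: set[tuple[str, ...]] = set()
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(nodes, size):
            if all(net.has_edge(u, v) for u, v in itertools.combinations(combo, 2)):
                cliques.add(combo)
    return cliques


def random_network(rng: np.random.Generator, n: int = 8, p_edge: float = 0.4) -> WeightedNetwork:
    """Erdos-Renyi-style network with uniform random confidences."""
    nodes = [f"v{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j], float(rng.uniform(0.05, 1.0)))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p_edge
    ]
    return WeightedNetwork.from_edges(edges, nodes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240314)
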