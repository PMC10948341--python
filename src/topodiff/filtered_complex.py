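"""Filtered clique (Vietoris-Rips) complexes and boundary matrices.

The network is abstracted as a point cloud with pairwise distances
``d = 1 - confidence`` (non-edges at infinite distance). The filtered
complex at scale ``t`` contains every clique of the graph restricted to
edges with distance <= t, up to a configurable maximum simplex dimension
``q_max``. Filtration values follow the max-edge rule: vertices appear
at 0, an edge at its distance, a higher simplex when its last edge does.

Simplices are oriented by the ascending order of their vertices (taken
in sorted-label order), which fixes the signs of the boundary matrices:
the column of a q-simplex has entries (-1)^i on its i-th facet.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.linalg

from .errors import ValidationError
from .ppi_network import WeightedNetwork, confidence_to_distance

Simplex = tuple[int, ...]  # ascending vertex indices


@dataclass
class FilteredComplex:
    """Oriented simplicial complex with monotone filtration values.

    Attributes
    ----------
    vertices
        Sorted vertex labels; simplices store indices into this list.
    simplices
        ``simplices[q]`` is the tuple of q-simplices (ascending vertex
        index tuples), sorted by (filtration value, vertex tuple).
    values
        ``values[q][i]`` is the filtration value of ``simplices[q][i]``.
    """

    vertices: tuple[str, ...]
    simplices: tuple[tuple[Simplex, ...], ...]
    values: tuple[np.ndarray, ...]
    f_max: float = 1.0
    _boundaries: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def q_max(self) -> int:
        return len(self.simplices) - 1

    def n_simplices(self, q: int) -> int:
        if q < 0 or q > self.q_max:
            return 0
        return len(self.simplices[q])

    @property
    def max_value(self) -> float:
        return max((float(v[-1]) for v in self.values if len(v)), default=0.0)

    def counts_at(self, t: float) -> list[int]:
        """Number of simplices per dimension in the snapshot at ``t``."""
        return [int(np.sum(v <= t)) for v in self.values]

    def full_boundary(self, q: int) -> np.ndarray:
        """Dense boundary matrix of the full complex, (q-1)-simplices x
        q-simplices, cached."""
        if q < 1 or q > self.q_max:
            return np.zeros((self.n_simplices(q - 1), self.n_simplices(q)))
        if q not in self._boundaries:
            rows = {s: i for i, s in enumerate(self.simplices[q - 1])}
            B = np.zeros((len(rows), len(self.simplices[q])))
            for j, sigma in enumerate(self.simplices[q]):
                for i in range(len(sigma)):
                    face = sigma[:i] + sigma[i + 1 :]
                    B[rows[face], j] = (-1.0) ** i
            self._boundaries[q] = B
        return self._boundaries[q]

    def mask(self, q: int, t: float) -> np.ndarray:
        """Boolean inclusion mask of dim-q simplices in the snapshot at t."""
        if q < 0 or q > self.q_max:
            return np.zeros(0, dtype=bool)
        return self.values[q] <= t


def build_clique_complex(
    net: WeightedNetwork, q_max: int = 2, f_max: float = 1.0
) -> FilteredComplex:
    """Build the filtered clique complex of a weighted network.

    Cliques of size <= ``q_max + 1`` are enumerated on the graph
    restricted to edges with distance <= ``f_max``; each simplex gets
    the maximum distance over its edges as filtration value. Isolated
    nodes contribute vertices at filtration 0.
    """
    if q_max < 1:
        raise ValidationError(f"q_max must be >= 1, got {q_max}")
    if f_max <= 0:
        raise ValidationError(f"f_max must be > 0, got {f_max}")

    vertices = tuple(sorted(net.nodes))
    index = {v: i for i, v in enumerate(vertices)}

    g = nx.Graph()
    g.add_nodes_from(range(len(vertices)))
    dist: dict[tuple[int, int], float] = {}
    for u, v, c in net.edges():
        d = confidence_to_distance(c)
        if d <= f_max:
            i, j = index[u], index[v]
            key = (i, j) if i < j else (j, i)
            dist[key] = d
            g.add_edge(i, j)

    per_dim: list[list[tuple[float, Simplex]]] = [[] for _ in range(q_max + 1)]
    for clique in nx.enumerate_all_cliques(g):
        q = len(clique) - 1
        if q > q_max:
            break  # cliques come out in nondecreasing size
        sigma = tuple(sorted(clique))
        if q == 0:
            f = 0.0
        else:
            f = max(
                dist[(sigma[a], sigma[b])]
                for a in range(len(sigma))
                for b in range(a + 1, len(sigma))
            )
        per_dim[q].append((f, sigma))

    simplices: list[tuple[Simplex, ...]] = []
    values: list[np.ndarray] = []
    for q in range(q_max + 1):
        per_dim[q].sort()
        simplices.append(tuple(s for _, s in per_dim[q]))
        values.append(np.array([f for f, _ in per_dim[q]], dtype=float))
    return FilteredComplex(vertices, tuple(simplices), tuple(values), f_max=f_max)


def snapshot(K: FilteredComplex, t: float) -> FilteredComplex:
    """Sub-complex of simplices with filtration value <= ``t``."""
    if t < 0:
        raise ValidationError(f"snapshot level must be >= 0, got {t}")
    simplices = []
    values = []
    for q in range(K.q_max + 1):
        m = K.mask(q, t)
        simplices.append(tuple(s for s, keep in zip(K.simplices[q], m) if keep))
        values.append(K.values[q][m])
    return FilteredComplex(K.vertices, tuple(simplices), tuple(values), f_max=K.f_max)


def boundary_matrix(K: FilteredComplex, q: int, t: float) -> np.ndarray:
    """Boundary matrix ``B_q`` of the snapshot at ``t``.

    Rows index (q-1)-simplices and columns q-simplices present at
    filtration level ``t``; entries follow the (-1)^i alternating-sign
    convention. Empty dimensions yield 0 x n / n x 0 matrices.
    """
    if q < 1:
        raise ValidationError(f"boundary dimension must be >= 1, got {q}")
    if q > K.q_max:
        return np.zeros((int(K.mask(q - 1, t).sum()), 0))
    B = K.full_boundary(q)
    # Filtration monotonicity guarantees every face of an included
    # simplex is itself included, so masking rows loses no entries.
    return B[np.ix_(K.mask(q - 1, t), K.mask(q, t))]


@dataclass
class PersistentUpBoundary:
    """Matrix representation of the persistent boundary operator
    mapping (q+1)-chains at scale t+p whose boundaries lie at scale t.

    ``chain_basis`` (n_{q+1}(t+p) x k) spans the admissible chain
    subspace; ``matrix`` (n_q(t) x k) is the restricted boundary map in
    that basis. For p = 0 the basis is the identity and ``matrix`` is
    the plain snapshot boundary matrix.
    """

    chain_basis: np.ndarray
    matrix: np.ndarray

    @property
    def subspace_dim(self) -> int:
        return self.chain_basis.shape[1]


def persistent_up_boundary(
    K: FilteredComplex, q: int, t: float, p: float = 0.0
) -> PersistentUpBoundary:
    """Persistent up-boundary from (q+1)-chains at ``t + p`` into
    q-chains at ``t``.

    The admissible subspace consists of (q+1)-chains at t+p whose
    boundary has no component on q-simplices born in (t, t+p]; its
    basis is the nullspace of the corresponding block of the boundary
    matrix at t+p.
    """
    if p < 0:
        raise ValidationError(f"persistence p must be >= 0, got {p}")
    if t + p > K.f_max + 1e-12:
        raise ValidationError(
            f"t + p = {t + p} exceeds the filtration range [0, {K.f_max}]"
        )
    n_q_t = int(K.mask(q, t).sum())
    if q + 1 > K.q_max:
        return PersistentUpBoundary(np.zeros((0, 0)), np.zeros((n_q_t, 0)))

    B = K.full_boundary(q + 1)
    cols = K.mask(q + 1, t + p)
    rows_in = K.mask(q, t)
    rows_out = K.mask(q, t + p) & ~rows_in
    B_cols = B[:, cols]
    B_out = B_cols[rows_out, :]
    B_in = B_cols[rows_in, :]
    n_cols = B_cols.shape[1]
    if n_cols == 0:
        return PersistentUpBoundary(np.zeros((0, 0)), np.zeros((n_q_t, 0)))
    if B_out.shape[0] == 0 or not B_out.any():
        Z = np.eye(n_cols)
    else:
        Z = scipy.linalg.null_space(B_out)
    return PersistentUpBoundary(chain_basis=Z, matrix=B_in @ Z)


def write_simplex_table(K: FilteredComplex, path: str | Path) -> None:
    """Write simplices as CSV rows (dim, vertices joined by '|', value)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["dim", "vertices", "filtration"])
        for q in range(K.q_max + 1):
            for sigma, f in zip(K.simplices[q], K.values[q]):
                w.writerow([q, "|".join(K.vertices[i] for i in sigma), f"{f:.6g}"])
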