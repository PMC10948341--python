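"""Persistent combinatorial Laplacians, spectra and barcodes.

The p-persistent q-combinatorial Laplacian at filtration level t is

    L_q^{t+p} = B_{q+1}^{t+p} (B_{q+1}^{t+p})^T + (B_q^t)^T B_q^t

where B_q^t is the snapshot boundary matrix at t and B_{q+1}^{t+p} is
the persistent up-boundary: the boundary map restricted to (q+1)-chains
at t+p whose boundaries live at t. The matrix is symmetric positive
semi-definite; the multiplicity of its zero eigenvalue (the harmonic
spectrum) is the p-persistent Betti number beta_q^{t+p}, while the
smallest positive eigenvalue (the non-harmonic minimum) tracks the
homotopic shape evolution of the network along the filtration.

Persistence barcodes are computed separately by the standard Z/2
boundary-matrix reduction in filtration order; at p = 0 the number of
dim-q bars alive at t equals the snapshot Betti number, which the test
suite exploits as a consistency check between the two routes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .errors import ValidationError
from .filtered_complex import (
    FilteredComplex,
    boundary_matrix,
    persistent_up_boundary,
)

#: Relative tolerance below which an eigenvalue counts as zero
#: (harmonic). Scaled by max(1, largest eigenvalue).
ZERO_TOL = 1e-8


@dataclass(frozen=True)
class PersistentSpectrum:
    """Eigenvalues of one persistent Laplacian with metadata."""

    eigenvalues: np.ndarray  # sorted ascending, clipped at 0
    q: int | None = None
    t: float | None = None
    p: float | None = None
    tol: float = ZERO_TOL

    @property
    def dim(self) -> int:
        return len(self.eigenvalues)

    @property
    def _zero_cut(self) -> float:
        scale = max(1.0, float(self.eigenvalues[-1])) if self.dim else 1.0
        return self.tol * scale

    @property
    def betti(self) -> int:
        """Number of harmonic (zero) eigenvalues = Betti number."""
        return int(np.sum(self.eigenvalues <= self._zero_cut))

    @property
    def lambda_min(self) -> float:
        """Smallest non-harmonic eigenvalue; 0 if the spectrum is empty
        or entirely harmonic (keeps feature vectors finite)."""
        nonzero = self.eigenvalues[self.eigenvalues > self._zero_cut]
        return float(nonzero[0]) if len(nonzero) else 0.0


def persistent_laplacian(
    K: FilteredComplex, q: int, t: float, p: float = 0.0
) -> np.ndarray:
    """Dense p-persistent q-combinatorial Laplacian matrix at level t.

    Size n_q(t) x n_q(t). For q = 0 and p = 0 this is exactly the graph
    Laplacian (degree minus adjacency) of the t-thresholded 1-skeleton.
    An empty dimension gives a 0 x 0 matrix (empty spectrum), not an
    error.
    """
    n_q = int(K.mask(q, t).sum()) if 0 <= q <= K.q_max else 0
    if n_q == 0:
        return np.zeros((0, 0))
    up = persistent_up_boundary(K, q, t, p)
    L = up.matrix @ up.matrix.T
    if q >= 1:
        Bq = boundary_matrix(K, q, t)
        L = L + Bq.T @ Bq
    return L


def spectrum(
    L: np.ndarray,
    tol: float = ZERO_TOL,
    q: int | None = None,
    t: float | None = None,
    p: float | None = None,
) -> PersistentSpectrum:
    """Full eigendecomposition of a symmetric PSD matrix.

    Eigenvalues within tolerance of zero are clipped to exactly 0.
    """
    L = np.asarray(L, dtype=float)
    if L.size and not np.allclose(L, L.T, atol=1e-10):
        raise ValidationError("matrix is not symmetric within 1e-10")
    if L.shape[0] == 0:
        return PersistentSpectrum(np.zeros(0), q=q, t=t, p=p, tol=tol)
    eig = np.linalg.eigvalsh(L)
    cut = tol * max(1.0, float(eig[-1]))
    eig = np.where(np.abs(eig) <= cut, 0.0, eig)
    return PersistentSpectrum(np.sort(eig), q=q, t=t, p=p, tol=tol)


def persistent_betti(s: PersistentSpectrum) -> int:
    """Betti number = nullity of the persistent Laplacian."""
    return s.betti


def min_nonharmonic(s: PersistentSpectrum) -> float:
    """Minimum of the non-harmonic (positive) spectrum; 0 if none."""
    return s.lambda_min


# -- persistence barcodes via Z/2 boundary-matrix reduction -----------


class Bar(NamedTuple):
    dim: int
    birth: float
    death: float  # math.inf for essential features


def compute_barcode(K: FilteredComplex, q_max: int | None = None) -> list[Bar]:
    """Persistence barcode by the standard column-reduction algorithm.

    Simplices are processed in filtration order (value, then dimension,
    then vertex tuple); reduction is over Z/2 with columns held as sets
    of row indices. Zero-persistence bars (death == birth) are dropped;
    unpaired simplices give essential bars with death = inf. Bars are
    reported for dimensions 0..q_max (default: all but the top
    dimension of the complex, whose deaths the complex cannot witness).
    """
    if q_max is None:
        q_max = max(K.q_max - 1, 0)

    order: list[tuple[float, int, tuple[int, ...]]] = []
    for q in range(K.q_max + 1):
        for sigma, f in zip(K.simplices[q], K.values[q]):
            order.append((float(f), q, sigma))
    order.sort()
    pos = {sigma: i for i, (_, _, sigma) in enumerate(order)}

    low_to_col: dict[int, set[int]] = {}
    pairs: list[tuple[int, int]] = []  # (birth simplex pos, death simplex pos)
    unpaired: set[int] = set()
    for i, (_, q, sigma) in enumerate(order):
        if q == 0:
            unpaired.add(i)
            continue
        col = {pos[sigma[:k] + sigma[k + 1 :]] for k in range(len(sigma))}
        while col:
            low = max(col)
            other = low_to_col.get(low)
            if other is None:
                break
            col ^= other
        if col:
            low_to_col[low] = col
            pairs.append((low, i))
            unpaired.discard(low)
        else:
            unpaired.add(i)

    bars: list[Bar] = []
    for b, d in pairs:
        fb, qb, _ = order[b]
        fd, _, _ = order[d]
        if fd > fb and qb <= q_max:
            bars.append(Bar(qb, fb, fd))
    for i in sorted(unpaired):
        f, q, _ = order[i]
        if q <= q_max:
            bars.append(Bar(q, f, math.inf))
    bars.sort(key=lambda bar: (bar.dim, bar.birth, bar.death))
    return bars


def bars_alive(bars: list[Bar], q: int, t: float, p: float = 0.0) -> int:
    """Number of dim-q bars with birth <= t and death > t + p: the
    p-persistent Betti number read off the barcode."""
    return sum(1 for b in bars if b.dim == q and b.birth <= t and b.death > t + p)


def write_barcode(bars: list[Bar], path: str | Path) -> None:
    """CSV writer: dim, birth, death ('inf' for essential bars)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["dim", "birth", "death"])
        for b in bars:
            death = "inf" if math.isinf(b.death) else f"{b.death:.6g}"
            w.writerow([b.dim, f"{b.birth:.6g}", death])
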