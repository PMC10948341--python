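"""Synthetic networks, toy complexes, DEG tables and affinity tables
with known ground truth.

These generators emulate the shape of the real inputs — confidence-
weighted interaction networks with planted high-importance hubs, DEG
statistic tables with known up/down counts, affinity tables with known
threshold bin counts — without attempting to match real STRING degree
distributions or microarray noise models. Every generator is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .filtered_complex import FilteredComplex, build_clique_complex
from .ppi_network import WeightedNetwork

# -- toy complexes with documented topology ---------------------------

_TOY_NAMES = (
    "two_points",
    "edge",
    "path3",
    "cycle4",
    "hollow_triangle",
    "filled_triangle",
    "tetrahedron_boundary",
)


def toy_complex(name: str) -> FilteredComplex:
    """Small named complexes with known Betti numbers and L0 spectra.

    ============================  =====================================
    name                          expected topology at full filtration
    ============================  =====================================
    two_points                    beta0 = 2 (no edges)
    edge                          beta0 = 1; L0 spectrum {0, 2}
    path3                         beta0 = 1; L0 spectrum {0, 1, 3}
    cycle4                        beta0 = 1, beta1 = 1 (a circle)
    hollow_triangle               beta0 = 1, beta1 = 1 (2-simplex absent)
    filled_triangle               beta0 = 1, beta1 = 0; edge distances
                                  0.1/0.2/0.3, 2-simplex at 0.3
    tetrahedron_boundary          beta2 = 1 (the 2-sphere: all four
                                  triangles of K4, no solid simplex)
    ============================  =====================================
    """
    c = 0.5  # distance 0.5 for all "plain" edges
    if name == "two_points":
        return build_clique_complex(
            WeightedNetwork({}, frozenset({"A", "B"})), q_max=1
        )
    if name == "edge":
        net = WeightedNetwork.from_edges([("A", "B", c)])
        return build_clique_complex(net, q_max=1)
    if name == "path3":
        net = WeightedNetwork.from_edges([("A", "B", c), ("B", "C", c)])
        return build_clique_complex(net, q_max=2)
    if name == "cycle4":
        net = WeightedNetwork.from_edges(
            [("A", "B", c), ("B", "C", c), ("C", "D", c), ("A", "D", c)]
        )
        return build_clique_complex(net, q_max=2)
    if name == "hollow_triangle":
        net = WeightedNetwork.from_edges(
            [("A", "B", c), ("B", "C", c), ("A", "C", c)]
        )
        return build_clique_complex(net, q_max=1)
    if name == "filled_triangle":
        net = WeightedNetwork.from_edges(
            [("A", "B", 0.9), ("A", "C", 0.8), ("B", "C", 0.7)]
        )
        return build_clique_complex(net, q_max=2)
    if name == "tetrahedron_boundary":
        nodes = "ABCD"
        net = WeightedNetwork.from_edges(
            [(u, v, c) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
        )
        return build_clique_complex(net, q_max=2)
    raise ValidationError(f"unknown toy complex {name!r}; options: {_TOY_NAMES}")


# -- planted-hub networks ---------------------------------------------


@dataclass(frozen=True)
class PlantedHubSpec:
    """Parameters for planted-hub network generation.

    Modules are near-cliques of moderate-confidence edges; hubs connect
    to every module node with confidence above the most stringent
    analysis threshold (default range 0.95-0.99, clearing 0.9), so a
    planted hub survives every thresholded network. Noise edges are
    sparse and weak (0.15-0.5) and vanish at higher thresholds.
    """

    n_modules: int = 2
    module_size: int = 6
    n_hubs: int = 1
    hub_confidence: tuple[float, float] = (0.95, 0.99)
    intra_confidence: tuple[float, float] = (0.4, 0.9)
    intra_prob: float = 0.9
    noise_prob: float = 0.05
    noise_confidence: tuple[float, float] = (0.15, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.module_size < 2:
            raise ValidationError("module_size must be >= 2")
        if self.n_modules < 1 or self.n_hubs < 0:
            raise ValidationError("n_modules >= 1 and n_hubs >= 0 required")
        for lo, hi in (self.hub_confidence, self.intra_confidence, self.noise_confidence):
            if not (0 < lo <= hi <= 1):
                raise ValidationError("confidence ranges must satisfy 0 < lo <= hi <= 1")


def planted_hub_network(
    spec: PlantedHubSpec = PlantedHubSpec(),
) -> tuple[WeightedNetwork, frozenset[str]]:
    """Generate a modular network with planted bridging hubs.

    Returns the network and the ground-truth hub identifiers (named
    ``HUB0``, ``HUB1``, ...; module nodes are ``M<i>N<j>``).
    """
    rng = np.random.default_rng(spec.seed)
    modules = [
        [f"M{m}N{j}" for j in range(spec.module_size)] for m in range(spec.n_modules)
    ]
    hubs = [f"HUB{h}" for h in range(spec.n_hubs)]
    edges: list[tuple[str, str, float]] = []
    for members in modules:
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if rng.random() < spec.intra_prob:
                    edges.append(
                        (members[a], members[b], float(rng.uniform(*spec.intra_confidence)))
                    )
    for h in hubs:
        for members in modules:
            for v in members:
                edges.append((h, v, float(rng.uniform(*spec.hub_confidence))))
    plain = [v for members in modules for v in members]
    for a in range(len(plain)):
        for b in range(a + 1, len(plain)):
            if plain[a][1] != plain[b][1] and rng.random() < spec.noise_prob:
                edges.append((plain[a], plain[b], float(rng.uniform(*spec.noise_confidence))))
    nodes = frozenset(plain) | frozenset(hubs)
    return WeightedNetwork.from_edges(edges, nodes), frozenset(hubs)


# -- DEG tables with planted up/down genes ----------------------------


def synthetic_deg_table(
    n_genes: int,
    n_up: int,
    n_down: int,
    lfc_cut: float,
    p_cut: float,
    seed: int = 0,
    dup_rate: float = 0.1,
    multi_rate: float = 0.05,
) -> tuple[pd.DataFrame, frozenset[str], frozenset[str]]:
    """DEG statistics table with exactly ``n_up``/``n_down`` planted
    differentially expressed genes relative to the given cutoffs.

    Null genes draw |log2fc| strictly inside the cutoff so they never
    pass; planted genes draw beyond it with p below ``p_cut``. Duplicate
    probes (lower mean expression, null-like stats) and multi-gene
    probes are injected at the stated rates to exercise deduplication.
    Returns (table, up_genes, down_genes).
    """
    if n_up + n_down > n_genes:
        raise ValidationError("n_up + n_down must be <= n_genes")
    if lfc_cut <= 0 or not (0 < p_cut <= 1):
        raise ValidationError("lfc_cut > 0 and p_cut in (0, 1] required")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    rows = []
    for i, g in enumerate(genes):
        if i < n_up:
            lfc = lfc_cut + rng.uniform(0.1, 2.0)
            p = p_cut * rng.uniform(1e-3, 0.9)
        elif i < n_up + n_down:
            lfc = -(lfc_cut + rng.uniform(0.1, 2.0))
            p = p_cut * rng.uniform(1e-3, 0.9)
        else:
            lfc = rng.uniform(-0.9, 0.9) * lfc_cut
            p = rng.uniform(0.0, 1.0)
        rows.append((f"P{i:05d}_at", g, float(lfc), float(p), float(rng.uniform(5, 12))))
    # duplicate probes: same gene, strictly lower mean expression, null stats
    n_dup = int(round(dup_rate * n_genes))
    for k in range(n_dup):
        g = genes[int(rng.integers(n_genes))]
        rows.append(
            (f"D{k:05d}_at", g, float(rng.uniform(-0.5, 0.5) * lfc_cut),
             float(rng.uniform(0, 1)), float(rng.uniform(0, 4)))
        )
    # multi-gene probes: always dropped by dedup
    n_multi = int(round(multi_rate * n_genes))
    for k in range(n_multi):
        a, b = rng.choice(n_genes, size=2, replace=False)
        rows.append(
            (f"X{k:05d}_at", f"{genes[a]}///{genes[b]}",
             float(rng.uniform(-3, 3)), float(rng.uniform(0, 1)), float(rng.uniform(5, 12)))
        )
    table = pd.DataFrame(
        rows, columns=["probe_id", "gene", "log2fc", "p_value", "mean_expr"]
    )
    table = table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    return table, frozenset(genes[:n_up]), frozenset(genes[n_up : n_up + n_down])


# -- affinity tables with planted bin counts --------------------------


def synthetic_affinity_table(
    n: int,
    bin_counts: tuple[int, ...],
    cutoffs: tuple[float, ...],
    seed: int = 0,
) -> pd.DataFrame:
    """Affinity table whose values fall in requested strength bins.

    ``cutoffs`` are strictly increasing (strongest first, e.g.
    (-11, -10, -9.54)); ``bin_counts[i]`` rows are sampled inside bin i
    and the remaining ``n - sum(bin_counts)`` rows above the last
    cutoff.
    """
    if len(bin_counts) != len(cutoffs):
        raise ValidationError("bin_counts and cutoffs must have equal length")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValidationError("cutoffs must be strictly increasing")
    if sum(bin_counts) > n:
        raise ValidationError("sum(bin_counts) must be <= n")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    lo = cutoffs[0] - 2.0
    for count, hi in zip(bin_counts, cutoffs):
        values.extend(rng.uniform(lo + 1e-6, hi, size=count).tolist())
        lo = hi
    values.extend(rng.uniform(cutoffs[-1] + 1e-6, cutoffs[-1] + 3.0,
                              size=n - sum(bin_counts)).tolist())
    rng.shuffle(values)
    return pd.DataFrame(
        {
            "drug_id": [f"SYN{i:05d}" for i in range(n)],
            "name": [f"compound-{i}" for i in range(n)],
            "ba_kcal_mol": [round(v, 4) for v in values],
        }
    )
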