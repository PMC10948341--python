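# topodiff

Multiscale topological differentiation of confidence-weighted
interaction networks, built around persistent spectral graph theory,
with companion utilities for differential-expression filtering and
binding-affinity screening.

## The problem

Hub-gene identification from protein–protein interaction (PPI) networks
usually relies on centrality scores that see only the wiring diagram,
not the *strength* of each interaction. `topodiff` instead treats a PPI
network (e.g. a STRING export for a set of differentially expressed
genes) as a metric object: each interaction confidence `c ∈ (0, 1]`
defines a distance `d = 1 − c`, and the network becomes a filtered
clique (Vietoris–Rips) complex

```
∅ = K_0 ⊆ K_1 ⊆ ⋯ ⊆ K_t = K,
```

whose topology is tracked across the distance scale `t`. For each
dimension `q` the p-persistent combinatorial Laplacian

```
L_q^{t+p} = B_{q+1}^{t+p} (B_{q+1}^{t+p})ᵀ + (B_qᵗ)ᵀ B_qᵗ
```

is symmetric positive semi-definite; its nullity is the persistent
Betti number `β_q^{t+p}` (components for q = 0, loops for q = 1) and
the smallest positive eigenvalue — the non-harmonic minimum — tracks
the geometric tightening of the network that Betti numbers cannot see.

A node's importance is measured by **topological differentiation**:
sample `(β0, λ0_min, β1, λ1_min)` on a fixed grid of filtration values,
delete the node, resample on the same grid, and take the Euclidean
distance between the two feature vectors. Ranking nodes at several
confidence thresholds (default 0.15, 0.4, 0.7, 0.9) and intersecting
the per-threshold top-k sets (default k = 25) nominates key genes that
are influential at every interaction-confidence scale.

Two side modules finish the pipeline around the network core:

- `deg_filter` — probe deduplication (keep the highest-expressed probe
  per gene, drop multi-gene probes) and strict `|log2FC|`/p-value
  thresholding of precomputed differential-expression statistics.
- `affinity_report` — Ki ↔ binding-free-energy conversion
  (`ΔG = RT ln Ki` at 298 K, i.e. 1.3633 kcal/mol per log10 unit, so
  Ki = 100 nM ↔ −9.54 kcal/mol), consensus averaging of per-model
  predictions, and threshold screening/binning of predicted-affinity
  tables. Six small published prediction tables for three
  addiction-related targets (mTOR, mGluR5, NMDAR) ship with the
  package.

## Worked example

Generate a synthetic planted-hub network and rank its nodes:

```bash
$ topodiff synth network --seed 7 -o demo_edges.tsv
planted hubs: HUB0
$ topodiff rank demo_edges.tsv -o demo_out
key nodes (13): HUB0, M0N0, M0N1, M0N2, M0N3, M0N4, M0N5, M1N0, ...
$ head -6 demo_out/rankings.tsv
threshold	rank	node	score
0.15	1	HUB0	20.47524119
0.15	2	M1N2	1.750606075
0.15	3	M0N4	1.576730015
0.15	4	M0N3	1.47974122
0.15	5	M1N1	1.238758628
```

The planted hub bridges two modules with high-confidence edges, so
deleting it shifts the Betti curves and non-harmonic spectra far more
than deleting any module-internal node: its score (20.5) dwarfs the
runner-up (1.75) and it survives the four-threshold top-25
intersection (the `key nodes` line; with 13 nodes, every node is in
each top-25, but the hub is rank 1 at every threshold).

The same numbers are available from Python:

```python
>>> from topodiff import ki_to_binding_affinity, load_reference_table, bin_by_affinity
>>> round(ki_to_binding_affinity(100e-9), 2)
-9.54
>>> bin_by_affinity(load_reference_table("mtor_approved"), (-11.0, -10.0, -9.54)).counts
(4, 7, 7)
```

i.e. a 100 nM inhibition constant corresponds to −9.54 kcal/mol, and
the 18 approved-drug mTOR predictions split 4 / 7 / 7 across the
−11 / −10 / −9.54 kcal/mol strength bins.

Other subcommands: `topodiff degs` (up/down gene selection),
`topodiff affinity-filter` (screening/binning), `topodiff barcode`
(persistence barcode CSV export), `topodiff synth` (fixtures).

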