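# Methods

## Model

A confidence-weighted PPI network is a finite metric-like object: nodes
are proteins, and each observed interaction with confidence
`c ∈ (0, 1]` has distance `d = 1 − c`. Unobserved pairs are at infinite
distance, so the filtered complex is a *clique* complex over observed
edges rather than a Čech/alpha complex over coordinates — the data
carry pairwise scores only, no embedding. The filtration value of a
vertex is 0, of an edge its distance, of a higher simplex the maximum
over its edges; the snapshot `K_t` contains all simplices with value
≤ t and is face-closed by construction.

Simplices are oriented by ascending vertex order (vertices sorted by
label), giving boundary matrices `B_q` with the alternating `(−1)^i`
sign convention and `B_{q−1} B_q = 0` at every snapshot.

For persistence offset `p ≥ 0`, the persistent up-boundary restricts
the boundary map on (q+1)-chains at scale `t+p` to the subspace of
chains whose boundary lies in the chain group at scale `t`. That
subspace is computed as the nullspace of the block of `B_{q+1}^{t+p}`
whose rows index q-simplices born in `(t, t+p]` (the standard
persistent-Laplacian construction); with basis `Z` and in-scale block
`B_in`, the up-term is `(B_in Z)(B_in Z)ᵀ`. The persistent Laplacian is
that up-term plus the down-term `(B_qᵗ)ᵀ B_qᵗ`. The test suite verifies
this against an independent Schur-complement-style construction that
projects chains with `P = I − C⁺C` (where `C` is the out-of-scale
block) instead of computing a nullspace basis — the two agree to 1e−8.

Its nullity is the p-persistent Betti number; the suite checks this
against two independent routes: the rank formula
`β_q^{t→s} = (n_qᵗ − rank B_qᵗ) − (rank B_{q+1}ˢ − rank B_out)` and the
number of bars alive in the persistence barcode computed by Z/2
column reduction in filtration order.

## Node scoring and key-gene selection

Each network is summarised on a fixed grid of filtration values by
`(β0, λ0_min, β1, λ1_min)` per grid point, flattened grid-major. A
node's importance is the Euclidean norm of the difference between the
intact network's vector and the vector after deleting the node, both on
the same grid. Deletion rebuilds the complex from scratch — correctness
over speed; incremental updates would be an optimisation, not a
contract. Rankings sort by descending score with lexicographic node-id
tie-breaks, so results are deterministic and permutation-equivariant.

Key genes are the intersection of the per-threshold top-k sets after
thresholding the network at each confidence level, ranking, and taking
the top k. A threshold that empties the network contributes the empty
set (logged), making the intersection empty rather than raising.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| confidence thresholds | 0.15, 0.4, 0.7, 0.9 | confidence | the standard STRING ladder from permissive to highest stringency |
| top-k per threshold | 25 | nodes | a Venn-intersection size that keeps only consistently top-ranked nodes |
| filtration grid | 21 uniform points on [0, 1] | distance | spans the whole achievable distance range; uniform because no scale is privileged a priori; fixed across baseline and deletions so vectors are comparable |
| q_max | 2 | — | homology through dimension 1 (components and loops); configurable upward |
| persistence p | 0 | distance | snapshot Laplacians along the grid; p = one grid step available as an option |
| zero tolerance | 1e−8 × max(1, λ_max) | — | relative spectral tolerance separating harmonic from non-harmonic eigenvalues |
| DEG cuts (stringent) | \|log2FC\| > 2, p < 0.01 | — | strict inequalities; microarray two-group preset |
| DEG cuts (permissive) | \|log2FC\| > 0.2630344 (= log2 1.2), p < 0.05 | — | a 1.2-fold-change preset, exposed as a named constant |
| Ki→ΔG constant | 1.3633 | kcal/mol per log10 | RT·ln 10 at 298 K; reproduces the −9.54 kcal/mol ↔ 100 nM equivalence to 2 d.p. |

Feature content per grid point is deliberately small (two Betti
numbers, two non-harmonic minima): Betti counts carry the topological
persistence and the spectral minima the homotopic shape evolution. No
normalisation is applied before the Euclidean distance — β and λ stay
on their natural scales, and changing that would be a modelling choice,
not a bug fix.

"Binding affinity greater than −9.54 kcal/mol" is implemented as
BA ≤ cutoff (stronger, i.e. more negative, binding); bin boundaries are
inclusive on the weaker side, so BA = −10 falls in the ≤ −10 bin.
Compounds labelled with IC50 rather than Ki potencies are converted
identically; the converter treats any molar potency the same way.

## Synthetic data

The generators emulate the *shape* of the real pipeline inputs, not
their full statistics:

- `planted_hub_network` — near-clique modules (intra-module confidence
  0.4–0.9, edge probability 0.9) bridged by hubs whose edges draw
  confidence 0.95–0.99, strictly above the most stringent analysis
  threshold, plus sparse weak noise edges (probability 0.05, confidence
  0.15–0.5) that vanish at higher thresholds. Default study size: 2
  modules × 6 nodes + 1 hub (13 nodes) — large enough that the
  multiscale intersection logic is exercised (noise edges survive only
  at 0.15; only hub edges survive at 0.9), small enough for quick
  exhaustive re-ranking.
- `synthetic_deg_table` — planted up/down genes draw |log2FC| beyond
  the cutoff with p below the cutoff; null genes draw |log2FC| strictly
  inside, so the planted counts are recovered exactly. Duplicate probes
  (lower mean expression) and multi-gene probes are injected to
  exercise deduplication.
- `synthetic_affinity_table` — values sampled inside requested strength
  bins.

None of these match real STRING degree distributions or microarray
noise models; passing tests demonstrate correctness of the machinery
and exact recovery under idealised ground truth, not performance on
real transcriptomes.

## Numerical choices and edge cases

- Dense symmetric eigensolvers throughout: target networks are at most
  a few hundred nodes (DEG-derived subnetworks), where dense
  `eigvalsh` is simpler and more robust than sparse iteration.
- λ_min of an empty or fully harmonic spectrum is defined as 0 so
  feature vectors stay finite.
- Empty dimensions give 0×0 Laplacians with empty spectra (β = 0), not
  errors; an empty network vectorizes to the zero vector.
- Zero-persistence bars (a cycle closed and filled at the same
  filtration value) are dropped from barcodes; essential features get
  death = ∞.
- Duplicate edge rows keep the maximum confidence; score dialect
  (0–1 vs 0–1000) is auto-detected by the presence of any value > 1.
- Probe-dedup ties (equal mean expression) keep the lexicographically
  smallest probe id, keeping output deterministic.
- Thresholded networks keep all connected components; the analysis is
  not restricted to the largest one.

## Problem sizes used by the verification scripts

The acceptance script and test suite use 50 random ≤8-vertex complexes
for the spectral/homological consistency checks, 20 seeded planted-hub
replicates (13 nodes each) for recovery rates, and the bundled
reference tables (7–18 rows) for screening counts — sizes chosen so the
whole verification run completes in well under a minute while still
exercising every code path, including p > 0 persistent blocks.

## Known limitations

- Node scoring recomputes the full complex per deletion: O(n) complex
  builds per ranking. Fine at DEG-subnetwork scale; a few thousand
  nodes would need incremental updates or parallelism.
- The clique complex is built on observed edges only; if a network's
  confidences are miscalibrated, distances inherit that bias — the
  package deliberately does not recalibrate.
- DEG filtering consumes precomputed statistics; it does not fit the
  differential-expression model itself.
- The consensus utility averages exactly the per-model predictions it
  is given; it does not weight models by validation accuracy.
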