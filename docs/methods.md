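# Methods

## Model

`infonet` treats a protein as a discrete time series. A sequence over
the 20 standard amino acids becomes a 20-state integer series via the
fixed alphabetical bijection A→1 … Y→20; a 3D structure becomes a series
of backbone (φ, ψ) torsion angles, uniformly binned. The pairwise
similarity of two series is the maximum, over all placements of the
shorter series against equal-length windows of the longer, of the
plug-in mutual information between the paired positions. The joint
distribution is estimated from position-paired co-occurrence counts
within the compared window — the standard plug-in estimator — and the
sum runs over state combinations, so the statistic is invariant to any
relabeling of states (property-tested) and requires no residue-level
alignment.

Mutual information is bounded by the entropies of its arguments, so the
matrix of pairwise maxima divided by the largest per-protein entropy has
entries in [0, 1]. This normalized matrix is the weighted adjacency
matrix of an undirected protein network. Classification proceeds by
filtering: at multiplicity c ∈ (0, 1] the mutative threshold
T_c = c · max_ij a_ij zeroes all entries below it (entries equal to T_c
survive — the comparison is ≥), and the connected components of the
filtered graph are the classes at c. Sweeping c from 1.0 downward only
adds edges, so partitions are nested; the sweep is recorded as a merge
tree whose internal nodes carry the first (largest) grid c at which
their children united. The merge multiplicity of two proteins equals
their bottleneck similarity (maximal over paths of the minimal edge
weight) divided by max a_ij, floored to the grid — the hierarchy is
exactly single-linkage clustering on dissimilarity max(a) − a, which the
test suite verifies against SciPy's independent single-linkage
implementation.

Connected components are computed two ways: a union-find-style sparse
traversal (the production route) and positivity of the summed matrix
powers Σ_{s=1..N−1} A^s (plus the identity, so isolated nodes form
well-defined singletons). The two routes must agree on every input and
are cross-checked on hundreds of random graphs. The power sum is
accumulated on the 0/1 support pattern of the filtered matrix: the
positivity pattern is identical to that of the weighted powers, but long
path products of sub-unit weights cannot underflow to zero.

## Assumptions

- Similarity is meaningful only through state co-occurrence within a
  single global placement of one series against the other. Internal
  insertions or deletions shift the pairing for everything downstream of
  them; the sliding maximum compensates a net offset, not internal gaps
  (see Limitations).
- Self-similarity is never used: the adjacency diagonal is fixed to 0.
  A diagonal of H_i / max H would dominate the mutative threshold
  (which is a multiple of the maximum entry) and distort every T_c.
- A precomputed matrix supplied via the matrix branch is assumed
  symmetric and normalized to [0, 1].

## Parameters

| parameter | default | meaning |
|---|---|---|
| log base | 2 (bits) | entropy/MI unit; the normalized adjacency is base-invariant to 1e-10 (tested), so this only affects the raw matrix and entropy CSVs |
| torsion bins | 20 | uniform bins of [−180°, 180°) per angle; 20 matches the sequence alphabet so both branches use the same state space |
| torsion layout | interleaved | ψ₁, φ₂, ψ₂, …, φₙ in residue order; φ-only and ψ-only layouts are available |
| grid step / min | 0.01 / 0.1 | threshold multiplicities 1.00, 0.99, …, 0.10; merge multiplicities are reported as grid values (two decimals) |
| alphabet policy | drop | non-standard residues (X, B, Z, U, O, gaps) are dropped with a logged count; `error` aborts; `map-to-nearest` remaps B→D, Z→E, J→L, U→C, O→K and still drops X/gaps, which have no nearest standard residue |
| chain / model policy | concat / first | PDB chains concatenated in file order from the first model; torsions spanning a chain boundary are excluded, not computed across the break |

## Numerical choices

- MI is computed as H(X) + H(Y) − H(X, Y) from bincounts, clamped at 0;
  0·log 0 is treated as 0 throughout.
- Ties among equally maximal window offsets resolve to the smallest
  offset; ties of three or more clusters uniting at one grid c are
  recorded as a single multi-way merge node, never an arbitrary binary
  order.
- Each unordered pair is computed once and mirrored, so a_ij == a_ji
  exactly (no floating asymmetry).
- Dihedrals use the atan2 formulation with the IUPAC sign convention;
  an exactly planar-trans arrangement is reported as −180° (the angle
  range is half-open, [−180°, 180°)).
- Empirical window entropies can exceed the full-series entropy, so a
  normalized entry can in principle exceed 1; such entries are clipped
  to 1 and counted in the run manifest (the counter is expected to stay
  0 in practice, and the per-window bound I ≤ min(H(X), H(Y_i)) is
  enforced as a property test).
- Degenerate inputs are rejected with specific errors: datasets of
  fewer than two series, all-constant datasets, all-zero matrices at
  the filtering stage, empty FASTA files, records shorter than two
  residues after sanitization, structures without a complete backbone
  residue.

## Synthetic data

The family generator draws one uniform-random ancestor per family and
derives each member by i.i.d. substitutions (rate 0.05/site by default,
uniform over the other 19 residues) and single-site indel events (rate
0.01/site, geometric length with continuation probability 0.5,
insertion or deletion with equal probability). Defaults — 3 families ×
6 members, ancestral length 200, seed 7 — define the reference fixture.
Indels make member lengths unequal, deliberately exercising the
sliding-window path.

What the generator does *not* emulate: realistic substitution matrices,
rate heterogeneity across sites, phylogenetic (non-star) family
topology, domain shuffling, and compositional bias. Passing tests
therefore demonstrate the method's mechanics — bound, symmetry,
nesting, hierarchy equivalence, recovery of well-separated families —
not classification accuracy on real protein superfamilies.

The structure generator builds backbone coordinates from ideal peptide
bond geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; trans ω) at
prescribed (φ, ψ) targets: helix (−60°, −45°), sheet (−120°, +120°), or
a half/half mixture, with optional Gaussian angle noise. Because the
generator logs its realized target angles, the torsion computation is
validated by round-trip to ~1e-12 degrees.

## Limitations

- **Internal indels and the bias floor.** The plug-in MI of two
  independent 20-state series of length ~200 is strongly positively
  biased (~1.4 bits), which after normalization puts unrelated pairs
  near 0.35 rather than 0. A within-family pair whose members carry
  indels near their start loses position pairing for most of its length
  and falls to that same bias floor. Family structure is still
  recovered because classification depends on bottleneck connectivity —
  each family stays internally linked through its well-aligned pairs
  above every between-family edge — but the *pairwise* within/between
  margin is not strict at the default rates.
- **Grid resolution.** Merge multiplicities are floored to the 0.01
  grid. When a within-family bottleneck and the strongest
  between-family link differ by less than one grid step (observed for
  roughly one in ten generator seeds at the default rates), the exact
  three-block partition is skipped over; a finer `grid_step` resolves
  such cases.
- **Torsion discretization.** MI on binned angles depends on the bin
  count; 20 uniform bins is a documented choice, not an estimate of the
  continuous MI. Kernel or adaptive estimators are out of scope.
- **Scaling.** Adjacency construction is O(N²) pairs × O((N−M+1)·M) per
  pair; the matrix-power component route and the connectivity profile
  are O(N⁴) per threshold and intended for verification and small-N
  inspection, not production component extraction (the union-find route
  is near-linear in edges).
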