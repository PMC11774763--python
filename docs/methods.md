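# Methods

This note records the models and procedures implemented in `strengthnulls`,
the parameters that matter, the numerical choices, and the limits of what
the synthetic benchmarks can show.

## Data model

A network is a dense square matrix `A` of edge weights with two flags
(`directed`, `signed`). Exact zero encodes an absent edge and the diagonal
is always zero. Undirected networks are stored symmetric, but edge
iteration uses the upper triangle so that each undirected edge is one
logical object. A consequence of the zero-means-absent convention is that
signed networks cannot carry zero-weight edges; this matches the adjacency
matrix representation and is a documented limitation rather than a bug.

Strength is the sum of incident weights: row sums for undirected networks,
row/column sums (out/in) for directed ones, and separate positive and
negative sums for signed ones, with negative strength stored as a
non-negative magnitude.

## Degree-preserving scaffolds

All strength-preserving nulls are built on a rewired scaffold so that size,
density and degree sequence(s) are conserved by construction and the null
ensembles of different algorithms share their binary topology null-by-null
(per-null seeds depend only on the master seed and the null index).

Swap proposals draw two distinct edges uniformly from the current edge list
and are rejected if they would create a self-loop or a multi-edge. For
undirected swaps, the two admissible reconnection patterns are chosen
between uniformly, since nothing favors one orientation. The target number
of swap rounds is `round(swaps_per_edge × E)` with a default of ten swaps
per edge; each round allows up to 50 proposals before moving on, and
`RewireResult` reports both proposals attempted and swaps effected.

**Connectedness guard.** The guarded variants never emit a network with an
unreachable node. The check is local: starting from a connected graph,
replacing edges (a,b), (c,d) by (a,d), (c,b) leaves the graph connected if
and only if b is still reachable from a afterwards — any walk through a
removed edge can then be rerouted via the new edges (a–d and c–b link the
four endpoints into one component once a reaches b). For directed swaps the
same argument shows strong connectivity is preserved iff a⇝b and c⇝d both
hold in the updated graph. One (or two) truncated breadth-first searches
per accepted proposal therefore suffice; directed connectedness is
interpreted as *strong* connectivity, the reading under which no node is
unreachable in either direction. Signed connection switching swaps within a
sign class (preserving positive and negative degree sequences exactly) and
makes no connectedness guarantee.

Networks with fewer than 4 edges are returned unchanged with a warning
rather than rewired.

## Rank-matched weight reassignment

The rank-matching algorithm reassigns the original weights greedily: with
residual strengths r_i = s_i − Σ_u Â_iu (initialized to the empirical
strengths), unassigned scaffold edges are ranked by expected magnitude
ê_ij ∝ r_i r_j and the remaining original weights by magnitude; a random
unassigned edge receives the original weight of its ê-rank, both are
removed, and the ranking is repeated until all edges are assigned. For
unsigned networks the procedure runs over all edges at once; for signed
networks it is applied separately to the positive and the negative edges
against the corresponding strength sequences. Directed networks are not
supported (the procedure is used on undirected scaffolds only).

Ties in ê are broken uniformly at random — the chosen edge's rank among
equal-ê edges is drawn uniformly, equivalent to a random shuffle before a
stable sort. Ties in weight magnitude need no ordering because only the
value at a rank matters. Residuals are updated incrementally (only the two
endpoints of an assigned edge change); the test suite backs this with a
full-recompute reference implementation and checks that both achieve the
same strength fidelity.

## Simulated annealing

The annealing energy is the mean squared error between strength sequences,
E = (1/n) Σ_i (s_i − ŝ_i)². Directed networks use mse(in) + mse(out);
signed networks use mse(positive) + mse(negative); the alternative directed
variant uses mse(in) alone. Each iteration proposes swapping the weights of
two edges drawn uniformly (within a sign class for the signed objective;
within one random node's outgoing edges for the alternative directed
variant, resampling nodes with fewer than two out-edges). A proposal is
accepted if it lowers E or if u < exp(−(E′−E)/T) for a uniform variate u
drawn from the same seeded stream as the edge draws. Identical-weight swaps
are proposed and trivially accepted; no special-casing is applied.

Schedule defaults: 100 stages of 10,000 proposals, initial temperature
1,000, multiplied by 0.5 at each stage end (a geometric schedule that is
effectively greedy in the last stages). An optional energy threshold turns
on early stopping: the energy is checked at stage ends only, and the run
halts at the first stage with E ≤ threshold or after `max_stages` (default
1,000) stages; a threshold of 1e-4 is the setting intended for
participant-level batches where a uniform final energy across networks
matters more than a fixed stage count.

ΔE is evaluated incrementally — a swap changes at most four node strengths
(two for the out-strength-exact variant), with shared endpoints merged
before the update. To bound floating-point drift, the energy is fully
recomputed from the weights at every stage end; the largest observed
discrepancy is compared against a tolerance of 1e-9 · n · max(1, E₀) and a
violation raises. The returned configuration is the *final* one (plain
annealing); the best energy seen is recorded in the trace for diagnostics.
The trace stores per-stage end energies, acceptance counts, and the
initial/final/best energies.

Degenerate inputs are legal: a perfect matching (every node of degree 1)
admits only energy-toggling swaps and simply returns a low-energy
configuration; uniform-weight networks start at E = 0.

**Exactness of conserved quantities.** Weight multisets are conserved
bit-exactly by every algorithm (weights are moved, never recomputed). For
directed rewiring and the out-strength-exact annealing variant, the
conserved object is the per-row weight multiset; recomputed row sums can
differ from the originals by float summation order (observed ≲ 1e-14
relative), so tests assert bit-exact row multisets and `allclose` on sums.

## Graph metrics

Metrics apply to undirected, positively weighted networks (matching their
use on such networks; other kinds raise).

- **Clustering**: triangle-intensity form C_u = 2/(k_u(k_u−1)) Σ_{i<j}
  (w_ui w_ij w_ju)^{1/3} with weights scaled by the network maximum;
  computed as diag((W^{1/3})³)/(k(k−1)), with C_u = 0 for k_u < 2 (the
  prefactor is singular there). The network value averages over all nodes,
  including zero-clustering ones.
- **Characteristic path length**: weights map monotonically to lengths —
  −ln(w) (requires w ∈ (0,1]; suited to max-normalized connectome weights)
  or 1/w (any positive weights; the default for the synthetic fixtures).
  Absent edges have infinite length. Dijkstra shortest paths are averaged
  over unordered node pairs; disconnected inputs raise with the unreachable
  nodes named. No silent rescaling is performed for the −ln mapping: the
  precondition is checked and an explicit error instructs the caller to
  rescale.
- **Assortativity**: the symmetric Pearson form over edge endpoint
  strengths, r = [M⁻¹Σ s_i t_i − (M⁻¹Σ ½(s_i+t_i))²] /
  [M⁻¹Σ ½(s_i²+t_i²) − (M⁻¹Σ ½(s_i+t_i))²], each undirected edge
  contributing once (the symmetric terms make orientation irrelevant).
  Degenerate strength variance raises.
- **Modularity**: Q = (1/2m) Σ_ij (w_ij − s_i s_j/2m) δ(c_i,c_j), maximized
  by Louvain (delegated to networkx's implementation, which randomizes the
  node visiting order from a per-run seed) and averaged over
  `modularity_runs` runs (default 250). Q of the returned partition is
  always evaluated by this package's own quality function; the per-community
  normalized form keeps the all-in-one-community partition at exactly 0.

## Hubs and heavy tails

Right-tailedness of a sample is p_R = P(X > Q3 + 3·IQR), estimated with
strict exceedance counts and linear-interpolation sample quantiles (the
common default; the estimator is a documented choice since several quartile
conventions exist). For any exponential distribution the fence exceedance
is exp(−(ln 4 + 3 ln 3)) = 1/108 ≈ 0.009 independent of the rate; this
constant is computed analytically in code and a sample is called
heavy-tailed when its empirical p_R exceeds it. Hubs are the nodes whose
strength strictly exceeds the fence.

Hub-partition similarity uses the z-scored Rand index: the pair count w of
co-assigned node pairs standardized under the fixed-margins hypergeometric
permutation model. The variance follows the standard pair-counting
moments; because the formula comes from the literature rather than being
re-derived here, the implementation is validated against a permutation-null
Monte-Carlo estimator (also exported, as `zrand_permutation`).

## Weighted rich club

The club at threshold k is the set of nodes with binary degree ≥ k and
W_≥k the total weight of its internal edges. The `simplified` variant
reports φ(k) = W_≥k: under null models preserving the degree sequence and
the weight multiset, classical denominators are equal between empirical and
null networks and cancel in the normalized ratio φ_norm = φ/mean(φ_null)
(this cancellation is asserted in tests). The `top_ranked` variant divides
by the sum of the E_≥k globally heaviest weights (ties are irrelevant since
only the prefix sum of the sorted multiset matters), giving φ ∈ [0,1].

Default thresholds run from 1 to max degree − 1; thresholds where the
empirical coefficient is undefined (club smaller than two nodes or without
internal edges) are dropped from the curve and from the Bonferroni count.
Nulls undefined at a given k are excluded from the null mean and from the
p denominator at that k, with the retained count recorded on the curve;
exclusion avoids contaminating the mean with undefined values. The p-value
is one-sided with strict inequality (a null exactly equal to the empirical
coefficient does not count against significance).

## Benchmarking and morphospace

Spearman, Kolmogorov–Smirnov and Mann–Whitney U statistics come from scipy;
CLES is computed from the U statistic as 100·U/(n_a n_b) with U counting
a-over-b wins plus half-ties (exact-enumeration p for tie-free groups of
≤ 20, tie-corrected normal approximation otherwise). Constant strength
vectors make Spearman undefined and yield NaN with a warning.

The morphospace embeds each network as (characteristic path length, mean
clustering); ensemble variances use the unbiased (n−1) denominator (a
convention choice). Subsample convergence draws subsamples *without*
replacement — a subsample is a set of distinct nulls, and the drawn indices
are sorted so the statistics do not depend on draw order (making the
relative difference at the full ensemble size exactly zero). The relative
difference |stat_sub − stat_full|/|stat_full| is reported as a magnitude by
default (a signed variant is available via a flag, since figure-style
trajectories are sometimes plotted signed), averaged over 1,000 resamples
with a 95% percentile bootstrap interval.

## Synthetic fixtures

The generator emulates connectome-like weighted networks: binary topology
by uniform pair sampling without replacement, with connectivity (when
requested) enforced by seeding a uniform random spanning tree
(Prüfer-decoded) for undirected networks or a random Hamiltonian cycle
(guaranteeing strong connectivity) for directed ones. Weights are i.i.d.
log-normal(μ = 0, σ = 1) by default — heavy-tailed heterogeneity typical of
streamline-density or tracer-strength connectomes — with uniform and
Pareto(α = 1.5) alternatives; signed networks negate a configurable
fraction (default 0.3) of edges. Realized density is within one edge of
the request and all draws are deterministic given the seed.

What the fixtures do *not* reproduce: spatial embedding and
distance-dependent weight decay, modular/hierarchical mesoscale structure,
degree–strength coupling beyond what i.i.d. weights induce, and measurement
noise. Passing benchmarks on these fixtures therefore demonstrates the
algorithms' conservation laws, optimization behavior and relative ordering
(annealing > rank matching > rewiring in strength fidelity), not
performance guarantees on any particular empirical dataset.

## Problem sizes used in the shipped benchmarks

The test suite and `scripts/acceptance.py` run the full benchmark on a
200-node, 20%-density log-normal fixture with 50 nulls per algorithm under
the default annealing schedule, a 100-node directed fixture for the
directed contracts, and a 50-fixture mixed battery (30–200 nodes, 5–50%
density) for the conservation suite — sizes chosen so the whole pipeline
reruns from scratch in minutes on a single CPU while remaining in the
regime (hundreds of nodes, thousands of edges) where the algorithms'
behavior is representative.

## Known limitations

- Double-edge-swap sampling is not a uniform sampler of the degree-fixed
  graph space (no curveball/stub-matching alternatives are provided).
- Rank matching is greedy and typically leaves a small systematic strength
  bias at high-strength nodes; this is inherent to the algorithm, and the
  benchmarking stack exists precisely to quantify it.
- Annealing returns the final configuration, not the best-seen one; with
  the default cold tail the two coincide in practice.
- Graph metrics are restricted to undirected positive networks; directed
  and signed metric variants are out of scope.
- Dense matrix storage bounds practical sizes to a few thousand nodes.
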