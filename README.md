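# strengthnulls

Strength-sequence-preserving null models for weighted networks, with the
evaluation stack used to benchmark them.

## The problem

Null network models are the workhorse of inference in network neuroscience
and network science at large: an observed feature (a rich club, a
short characteristic path length, a hub set) is judged against what would be
expected "by chance" in randomized networks that conserve some lower-order
properties of the data. The classic Maslov–Sneppen double-edge swap
conserves size, density and the binary degree sequence, but in a weighted
network it lets each node's *strength* — the sum of its incident edge
weights, s_i = Σ_j A_ij — drift far from its empirical value. Because many
weighted statistics are driven by the strength sequence, a degree-only null
can badly miscalibrate inference (for example, over- or under-detecting
weighted rich clubs).

This package randomizes a weighted network while preserving, in addition to
size, density, degree sequence and the exact multiset of edge weights, the
empirical strength sequence — either approximately optimally (simulated
annealing) or heuristically (rank matching). It targets researchers working
with connectomes and other weighted graphs (undirected, directed or signed)
who need conservative, reproducible null ensembles.

## The algorithms

All strength-preserving nulls are built in two steps. First, a
degree-preserving rewired *scaffold* is generated (Maslov–Sneppen swaps for
undirected or directed networks with an optional connectedness guard;
within-sign-class connection switching for signed networks; roughly ten
swaps per edge). Second, the original weights are rearranged on the
scaffold's topology:

- **Rank matching (Rubinov–Sporns).** Iteratively assign the largest
  remaining original weight rank-for-rank to the scaffold edge with the
  highest expected magnitude ê_ij ∝ (s_i − Σ_u Â_iu)(s_j − Σ_u Â_ju),
  where the residuals are the empirical strengths minus the weight already
  placed; one randomly drawn edge is fixed per step.
- **Simulated annealing.** Minimize the energy
  E = (1/n) Σ_i (s_i − ŝ_i)² — the mean squared error between empirical
  and randomized strength sequences — by swapping random pairs of edge
  weights, accepting uphill moves with probability exp(−(E′−E)/T) under a
  geometric cooling schedule (by default 100 stages of 10,000 swap
  proposals, T₀ = 1000 halved per stage). Directed networks sum the in- and
  out-strength errors; signed networks sum positive- and negative-strength
  errors; an alternative directed variant permutes weights only within each
  node's outgoing edges, keeping out-strengths exactly fixed while
  annealing the in-strength error.

Both preserve the weight multiset exactly, so ensembles generated from a
shared master seed also share their binary topology null-by-null across
algorithms — differences between ensembles isolate the effect of weight
placement alone.

The evaluation stack covers: strength-fidelity statistics (per-null Spearman
ρ and Kolmogorov–Smirnov distance, Mann–Whitney U with common-language
effect sizes), weighted graph metrics (triangle-intensity clustering,
characteristic path length under weight→length transforms, strength
assortativity, Louvain-averaged modularity), nonparametric heavy-tail/hub
detection (outlier fence Q3 + 3·IQR against the analytic exponential
reference 1/108 ≈ 0.009, z-scored Rand index of hub partitions), weighted
rich-club normalization with one-sided significance, and morphospace
ensemble summaries with subsample-convergence analysis.

## Worked example

```python
import numpy as np
import strengthnulls as sn

# a connectome-like fixture: 200 nodes, 20% density, log-normal weights
net = sn.generate_synthetic(n=200, density=0.2, weight_dist="lognormal",
                            connected=True, seed=1)

ensembles = {algo: sn.generate_ensemble(net, algo, n_nulls=50, seed=11)
             for algo in ("ms", "rs", "sa")}

for algo, ens in ensembles.items():
    rho = sn.strength_spearman(net, ens)
    ks = sn.strength_ks(net, ens)
    print(f"{algo}: mean Spearman rho = {np.nanmean(rho):.4f}, "
          f"mean KS = {np.mean(ks):.4f}")
```

Output:

```
ms: mean Spearman rho = 0.3404, mean KS = 0.0769
rs: mean Spearman rho = 0.9670, mean KS = 0.0414
sa: mean Spearman rho = 0.9999, mean KS = 0.0069
```

Degree-preserving rewiring alone (`ms`) decorrelates the strengths almost
completely (ρ ≈ 0.34): node strength is not dictated by degree. Rank
matching (`rs`) recovers most of the sequence (ρ ≈ 0.97), and simulated
annealing (`sa`) reproduces it near-perfectly (ρ ≈ 1.0) while also matching
the strength *distribution* most closely (smallest KS). The same pipeline
runs from the shell:

```bash
strengthnulls synth --n 200 --density 0.2 --seed 1 --out net.csv
strengthnulls randomize net.csv --algorithm sa --n-nulls 50 --seed 11 --out-dir sa_nulls
strengthnulls benchmark net.csv sa_nulls --out report.json
```

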