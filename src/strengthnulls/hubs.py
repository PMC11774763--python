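"""Nonparametric heavy-tail detection, hub identification and hub-partition
similarity.

Right-tailedness of a sample is the probability mass beyond the Tukey-style
far-outlier fence Q3 + 3*IQR.  For an exponential distribution this mass is
the same for every rate: P(X > Q3 + 3*IQR) = exp(-(ln 4 + 3 ln 3)) = 1/108
(~0.009), which serves as the reference threshold — a distribution whose
empirical p_R exceeds it decays slower than exponentially and is called
heavy-tailed.  Hubs are the nodes whose strength exceeds the fence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .net_core import WeightedNetwork, strengths

__all__ = [
    "HubReport",
    "exponential_tail_threshold",
    "right_tailedness",
    "identify_hubs",
    "zrand",
]


def exponential_tail_threshold() -> float:
    """P(X > Q3 + 3*IQR) for any exponential distribution, in closed form.

    Q3 = ln(4)/lambda, IQR = ln(3)/lambda, so the fence is
    (ln 4 + 3 ln 3)/lambda and the exceedance probability is
    exp(-(ln 4 + 3 ln 3)) = 1/108, independent of the rate.
    """
    return float(np.exp(-(np.log(4.0) + 3.0 * np.log(3.0))))


@dataclass
class HubReport:
    q1: float
    q3: float
    iqr: float
    outlier_threshold: float
    p_r: float
    heavy_tailed: bool
    hub_indices: np.ndarray


def right_tailedness(values: np.ndarray) -> HubReport:
    """Fraction of observations strictly exceeding Q3 + 3*IQR.

    Quartiles use the linear-interpolation sample-quantile rule.  The sample
    is heavy-tailed when p_R exceeds the exponential reference 1/108.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("right-tailedness needs at least 4 values")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    fence = q3 + 3.0 * iqr
    hub_idx = np.nonzero(values > fence)[0]
    p_r = hub_idx.size / values.size
    return HubReport(
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        outlier_threshold=float(fence),
        p_r=float(p_r),
        heavy_tailed=bool(p_r > exponential_tail_threshold()),
        hub_indices=hub_idx,
    )


def identify_hubs(network: WeightedNetwork) -> HubReport:
    """Hub detection on the strength distribution of an undirected,
    unsigned network."""
    if network.directed or network.signed:
        raise ValueError("hub identification expects an undirected, unsigned network")
    return right_tailedness(strengths(network).s)


def zrand(partition_a: np.ndarray, partition_b: np.ndarray) -> float:
    """z-scored Rand index between two node partitions.

    Standardizes the count w of node pairs co-assigned in both partitions
    under the fixed-margins (hypergeometric) permutation model:
    z = (w - E[w]) / sd(w).  Accepts any number of classes; degenerate
    partitions (a single class) have zero variance and raise.
    """
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be equal-length 1-d label vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 nodes")

    def _pair_count(labels: np.ndarray) -> tuple[float, np.ndarray]:
        _, sizes = np.unique(labels, return_counts=True)
        return float((sizes * (sizes - 1) // 2).sum()), sizes.astype(float)

    M = n * (n - 1) / 2.0
    M1, sizes_a = _pair_count(a)
    M2, sizes_b = _pair_count(b)
    # pairs co-assigned in both = sum over contingency cells of C(n_ij, 2)
    joint = {}
    for x, y in zip(a.tolist(), b.tolist()):
        joint[(x, y)] = joint.get((x, y), 0) + 1
    w = sum(c * (c - 1) // 2 for c in joint.values())

    mu = M1 * M2 / M
    c1 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * M1 + 4 * np.sum(sizes_a**3)
    c2 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * M2 + 4 * np.sum(sizes_b**3)
    var = (
        M / 16.0
        - ((4 * M1 - 2 * M) ** 2) * ((4 * M2 - 2 * M) ** 2) / (256.0 * M**2)
        + c1 * c2 / (16.0 * n * (n - 1) * (n - 2))
        + (((4 * M1 - 2 * M) ** 2 - 4 * c1 - 4 * M)
           * ((4 * M2 - 2 * M) ** 2 - 4 * c2 - 4 * M))
        / (64.0 * n * (n - 1) * (n - 2) * (n - 3))
    )
    if var <= 0:
        raise ValueError("undefined z-Rand: a partition has zero pair-count variance")
    return float((w - mu) / np.sqrt(var))


def zrand_permutation(
    partition_a: np.ndarray,
    partition_b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation-based estimate of the z-scored Rand index (verification
    fallback for :func:`zrand`)."""
    a = np.asarray(partition_a)
    b = np.asarray(partition_b).copy()
    rng = np.random.default_rng(seed)

    def _w(x, y):
        joint = {}
        for p, q in zip(x.tolist(), y.tolist()):
            joint[(p, q)] = joint.get((p, q), 0) + 1
        return sum(c * (c - 1) // 2 for c in joint.values())

    w_obs = _w(a, b)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _w(a, rng.permutation(b))
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("undefined z-Rand: degenerate permutation null")
    return float((w_obs - null.mean()) / sd)
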