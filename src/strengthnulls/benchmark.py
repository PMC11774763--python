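"""Statistical comparison of null ensembles and morphospace summaries.

Per-null strength fidelity is measured by the Spearman rank correlation
(sequence preservation) and the two-sample Kolmogorov–Smirnov statistic
(distribution preservation).  Ensembles are compared with the Mann–Whitney U
rank test and its common-language effect size (CLES: the percentage of
cross-ensemble pairs supporting a given direction).  The morphospace embeds
each null as a (characteristic path length, mean clustering) point, and the
subsample-convergence analysis quantifies how quickly ensemble summary
statistics stabilize with ensemble size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .graph_metrics import (
    MetricConfig,
    characteristic_path_length,
    clustering_coefficient,
)
from .net_core import WeightedNetwork, strengths
from .strength_nulls import NullEnsemble

__all__ = [
    "MorphospaceSummary",
    "ConvergenceTrajectory",
    "BenchmarkReport",
    "strength_spearman",
    "strength_ks",
    "mwu_cles",
    "morphospace",
    "subsample_convergence",
    "compare_ensembles",
]


def _null_list(ensemble) -> list[WeightedNetwork]:
    return ensemble.networks if isinstance(ensemble, NullEnsemble) else list(ensemble)


def _strength_vector(net: WeightedNetwork) -> np.ndarray:
    s = strengths(net)
    if s.s is None:
        raise ValueError("strength benchmarking expects undirected, unsigned networks")
    return s.s


def strength_spearman(reference: WeightedNetwork, ensemble) -> np.ndarray:
    """Per-null Spearman rank correlation between reference and null
    strength sequences (average ranks on ties); NaN for a null with a
    constant strength vector."""
    s_ref = _strength_vector(reference)
    out = []
    for null in _null_list(ensemble):
        s_null = _strength_vector(null)
        if np.all(s_null == s_null[0]) or np.all(s_ref == s_ref[0]):
            warnings.warn("constant strength vector: Spearman undefined", stacklevel=2)
            out.append(np.nan)
        else:
            out.append(stats.spearmanr(s_ref, s_null).statistic)
    return np.asarray(out, dtype=float)


def strength_ks(reference: WeightedNetwork, ensemble) -> np.ndarray:
    """Per-null two-sample KS statistic (sup distance between the empirical
    and null cumulative strength distributions)."""
    s_ref = _strength_vector(reference)
    return np.asarray(
        [
            # the statistic (sup CDF distance) is method-independent; the
            # asymptotic p-value path avoids exact-enumeration overflow
            stats.ks_2samp(s_ref, _strength_vector(null), method="asymp").statistic
            for null in _null_list(ensemble)
        ],
        dtype=float,
    )


def mwu_cles(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float, float]:
    """Mann–Whitney U rank test plus common-language effect size.

    Returns (U, two-sided p, CLES%) where U counts a-over-b wins plus half
    ties and CLES = 100 * U / (n_a * n_b).  Exact enumeration is used for
    tie-free groups of size <= 20, the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.intersect1d(a, b).size > 0 or (
        np.unique(a).size < a.size or np.unique(b).size < b.size
    )
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    cles = 100.0 * u / (a.size * b.size)
    return u, float(res.pvalue), cles


@dataclass
class MorphospaceSummary:
    """Null networks embedded by (characteristic path length, clustering)."""

    points: np.ndarray  # (n_nulls, 2): [cpl, mean clustering]
    reference_point: tuple[float, float]
    ensemble_mean_cpl: float
    ensemble_var_cpl: float
    ensemble_mean_clu: float
    ensemble_var_clu: float


@dataclass
class ConvergenceTrajectory:
    """Relative difference of subsample summaries to the full ensemble."""

    sample_sizes: np.ndarray
    mean_reldiff: dict  # stat name -> per-size mean relative difference
    ci_low: dict
    ci_high: dict
    n_resamples: int
    signed: bool


@dataclass
class BenchmarkReport:
    spearman_per_null: dict
    ks_per_null: dict
    pairwise: dict  # (name_a, name_b) -> {"U", "p", "cles"}


def morphospace(
    reference: WeightedNetwork,
    ensemble,
    metric_config: MetricConfig | None = None,
) -> MorphospaceSummary:
    """Compute the 2-d morphospace coordinates for every null and the
    reference, with ensemble means and (unbiased) variances."""
    metric_config = metric_config or MetricConfig()
    nulls = _null_list(ensemble)
    pts = np.array(
        [
            (
                characteristic_path_length(nn, metric_config),
                clustering_coefficient(nn)[1],
            )
            for nn in nulls
        ]
    )
    ref_pt = (
        characteristic_path_length(reference, metric_config),
        clustering_coefficient(reference)[1],
    )
    ddof = 1 if len(nulls) > 1 else 0
    return MorphospaceSummary(
        points=pts,
        reference_point=ref_pt,
        ensemble_mean_cpl=float(pts[:, 0].mean()),
        ensemble_var_cpl=float(pts[:, 0].var(ddof=ddof)),
        ensemble_mean_clu=float(pts[:, 1].mean()),
        ensemble_var_clu=float(pts[:, 1].var(ddof=ddof)),
    )


_STATS = ("mean_clu", "var_clu", "mean_cpl", "var_cpl")


def _summaries(points: np.ndarray) -> dict:
    return {
        "mean_clu": points[:, 1].mean(),
        "var_clu": points[:, 1].var(ddof=1),
        "mean_cpl": points[:, 0].mean(),
        "var_cpl": points[:, 0].var(ddof=1),
    }


def subsample_convergence(
    summary: MorphospaceSummary,
    sample_sizes,
    n_resamples: int = 1000,
    seed: int = 0,
    signed: bool = False,
) -> ConvergenceTrajectory:
    """Relative difference between subsample and full-ensemble summaries.

    For each size, ``n_resamples`` subsamples are drawn without replacement;
    the relative difference |stat_sub - stat_full| / |stat_full| (signed
    version available) is averaged over resamples with a 95% bootstrap
    percentile interval.
    """
    pts = summary.points
    n_full = pts.shape[0]
    sample_sizes = np.asarray(sample_sizes, dtype=int)
    if np.any(sample_sizes > n_full):
        raise ValueError("subsample size exceeds the ensemble size")
    if np.any(sample_sizes < 2):
        raise ValueError("subsample sizes must be >= 2 (variance needs 2 points)")
    full = _summaries(pts)
    for name, val in full.items():
        if val == 0:
            raise ValueError(f"full-ensemble statistic {name} is zero; "
                             "relative difference undefined")
    rng = np.random.default_rng(seed)
    mean_rd = {s: np.empty(sample_sizes.size) for s in _STATS}
    lo = {s: np.empty(sample_sizes.size) for s in _STATS}
    hi = {s: np.empty(sample_sizes.size) for s in _STATS}
    for si, size in enumerate(sample_sizes):
        vals = {s: np.empty(n_resamples) for s in _STATS}
        for r in range(n_resamples):
            # a subsample is a set of nulls: sorting the indices makes the
            # statistics independent of draw order (and exactly zero
            # relative difference at the full ensemble size)
            idx = np.sort(rng.choice(n_full, size=size, replace=False))
            sub = _summaries(pts[idx])
            for s in _STATS:
                rd = (sub[s] - full[s]) / abs(full[s])
                vals[s][r] = rd if signed else abs(rd)
        for s in _STATS:
            mean_rd[s][si] = vals[s].mean()
            lo[s][si] = np.percentile(vals[s], 2.5)
            hi[s][si] = np.percentile(vals[s], 97.5)
    return ConvergenceTrajectory(
        sample_sizes=sample_sizes,
        mean_reldiff=mean_rd,
        ci_low=lo,
        ci_high=hi,
        n_resamples=n_resamples,
        signed=signed,
    )


def compare_ensembles(
    reference: WeightedNetwork, ensembles: dict
) -> BenchmarkReport:
    """Per-null Spearman/KS for each named ensemble plus pairwise
    Mann–Whitney/CLES comparisons of the Spearman vectors."""
    spear = {name: strength_spearman(reference, ens) for name, ens in ensembles.items()}
    ks = {name: strength_ks(reference, ens) for name, ens in ensembles.items()}
    pairwise = {}
    names = list(ensembles)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            u, p, cles = mwu_cles(spear[na], spear[nb])
            pairwise[(na, nb)] = {"U": u, "p": p, "cles": cles}
    return BenchmarkReport(spearman_per_null=spear, ks_per_null=ks, pairwise=pairwise)
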