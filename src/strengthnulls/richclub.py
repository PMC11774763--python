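"""Weighted rich-club coefficients, null normalization and significance.

The rich club at degree threshold k is the set of nodes with binary degree
>= k; its weighted connectedness W_>=k is the total weight of edges with both
endpoints in the club.  Two coefficient variants are provided:

* ``simplified`` — phi(k) = W_>=k.  Against null models that preserve the
  degree sequence and the weight multiset, most classical denominators are
  identical between empirical and null networks and cancel in the normalized
  ratio, so only the numerator matters.
* ``top_ranked`` — phi(k) = W_>=k / sum of the E_>=k globally heaviest
  weights: the share of weight the rich nodes carry relative to the most
  they could carry if linked by the network's strongest connections
  (phi in [0, 1]).

Normalization divides the empirical coefficient by the null-ensemble mean,
and a one-sided p-value is the proportion of nulls whose coefficient
strictly exceeds the empirical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .net_core import WeightedNetwork
from .strength_nulls import NullEnsemble

__all__ = ["RichClubCurve", "rich_club_coefficient", "normalized_rich_club"]


@dataclass
class RichClubCurve:
    """Per-threshold empirical, null-averaged and normalized coefficients."""

    k_values: np.ndarray
    phi: np.ndarray
    phi_null_mean: np.ndarray
    phi_norm: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    variant: str
    club_sizes: np.ndarray
    e_ge_k: np.ndarray
    n_nulls_defined: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "club_size": self.club_sizes,
                "E_ge_k": self.e_ge_k,
                "phi": self.phi,
                "phi_null_mean": self.phi_null_mean,
                "phi_norm": self.phi_norm,
                "p": self.p_values,
                "significant": self.significant,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rich_club_coefficient(
    network: WeightedNetwork, k: int, variant: str = "top_ranked"
) -> tuple[float, int, int]:
    """Weighted rich-club coefficient at one degree threshold.

    Returns (phi, club_size, E_>=k); phi is NaN when the club has fewer than
    2 nodes or no internal edges.
    """
    if network.directed or network.signed:
        raise ValueError("rich club is defined for undirected, unsigned networks")
    if variant not in ("simplified", "top_ranked"):
        raise ValueError(f"unknown variant {variant!r}")
    A = network.weights
    deg = (A != 0).sum(axis=1)
    club = deg >= k
    club_size = int(club.sum())
    sub = A[np.ix_(club, club)]
    iu = np.triu_indices(club_size, 1)
    club_w = sub[iu]
    e_ge_k = int(np.count_nonzero(club_w))
    if club_size < 2 or e_ge_k == 0:
        return float("nan"), club_size, e_ge_k
    W_ge_k = float(club_w.sum())
    if variant == "simplified":
        return W_ge_k, club_size, e_ge_k
    all_w = A[np.triu_indices(network.n_nodes, 1)]
    all_w = np.sort(all_w[all_w != 0])[::-1]
    denom = float(all_w[:e_ge_k].sum())
    return W_ge_k / denom, club_size, e_ge_k


def normalized_rich_club(
    network: WeightedNetwork,
    ensemble: NullEnsemble | list[WeightedNetwork],
    k_range: np.ndarray | None = None,
    variant: str = "top_ranked",
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> RichClubCurve:
    """Normalize the empirical rich-club curve against a null ensemble.

    phi_norm(k) = phi(k) / mean(phi_null(k)); the one-sided p-value at each k
    is the proportion of nulls with phi_null strictly greater than phi.
    Thresholds where the empirical phi is undefined are dropped from the
    curve and from the correction count; nulls undefined at a given k are
    excluded from the mean and the p denominator at that k.
    """
    nulls = ensemble.networks if isinstance(ensemble, NullEnsemble) else list(ensemble)
    if len(nulls) == 0:
        raise ValueError("empty null ensemble")
    for null in nulls:
        if null.n_nodes != network.n_nodes:
            raise ValueError("ensemble/network size mismatch")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if k_range is None:
        max_deg = int((network.weights != 0).sum(axis=1).max())
        k_range = np.arange(1, max(max_deg, 2))
    k_range = np.asarray(k_range, dtype=int)

    rows = []
    for k in k_range:
        phi, club_size, e_ge_k = rich_club_coefficient(network, int(k), variant)
        if np.isnan(phi):
            continue
        null_phis = np.array(
            [rich_club_coefficient(nn, int(k), variant)[0] for nn in nulls]
        )
        defined = ~np.isnan(null_phis)
        n_def = int(defined.sum())
        if n_def == 0:
            continue
        null_mean = float(null_phis[defined].mean())
        p = float((null_phis[defined] > phi).sum() / n_def)
        rows.append((int(k), club_size, e_ge_k, phi, null_mean, p, n_def))

    if not rows:
        raise ValueError("rich-club coefficient undefined at every threshold")
    ks, sizes, eks, phis, means, ps, ndefs = map(np.array, zip(*rows))
    phi_norm = phis / means
    threshold = alpha / len(ks) if correction == "bonferroni" else alpha
    significant = ps < threshold
    return RichClubCurve(
        k_values=ks,
        phi=phis,
        phi_null_mean=means,
        phi_norm=phi_norm,
        p_values=ps,
        significant=significant,
        variant=variant,
        club_sizes=sizes,
        e_ge_k=eks,
        n_nulls_defined=ndefs,
    )
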