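"""Quantitative views on sampled connectomes.

Connectivity-matrix style analysis: neurons ordered along a chart axis (the
septo-temporal or proximo-distal analog), normalized index differences
between connected pairs (how far a neuron's projections scatter along the
axis), band-wise spread along the axis, distance histograms, and a
two-sample Kolmogorov-Smirnov comparison for distance distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, special

from .layers import NeuronPopulation
from .sampling import Connectome

__all__ = [
    "Ordering",
    "OrderedConnectivity",
    "order_by_axis",
    "index_difference_histogram",
    "index_differences",
    "spread_by_band",
    "distance_histogram",
    "ks_compare",
]


@dataclass
class Ordering:
    """A population sorted along one chart axis.

    ``permutation[k]`` is the neuron id at rank ``k``; ``normalized_index``
    maps neuron id -> rank/(size-1) in [0, 1].  The sort is stable with ties
    broken by id, so orderings are reproducible.
    """

    axis: int
    permutation: np.ndarray
    normalized_index: np.ndarray


def order_by_axis(population: NeuronPopulation, axis: int = 0) -> Ordering:
    """Stable sort of a population by one UV component (0 = u, 1 = v)."""
    if axis not in (0, 1):
        raise ValueError("axis must be 0 (u) or 1 (v)")
    perm = np.argsort(population.uv[:, axis], kind="stable")
    rank = np.empty(population.size, dtype=np.intp)
    rank[perm] = np.arange(population.size)
    denom = max(population.size - 1, 1)
    return Ordering(axis=axis, permutation=perm, normalized_index=rank / denom)


@dataclass
class OrderedConnectivity:
    """Sparse boolean adjacency with both populations ordered along an axis."""

    pre: Ordering
    post: Ordering
    adjacency: sparse.spmatrix

    @classmethod
    def from_connectome(
        cls, conn: Connectome, pre_pop: NeuronPopulation, post_pop: NeuronPopulation,
        axis: int = 0,
    ) -> "OrderedConnectivity":
        pre_o = order_by_axis(pre_pop, axis)
        post_o = order_by_axis(post_pop, axis)
        adj = sparse.coo_matrix(
            (np.ones(len(conn), dtype=bool), (conn.pre_id, conn.post_id)),
            shape=(conn.n_pre, conn.n_post),
        ).tocsr()
        return cls(pre=pre_o, post=post_o, adjacency=adj)


def index_differences(conn: Connectome, orderings: tuple) -> np.ndarray:
    """Normalized pre index minus normalized post index, one per synapse.

    Indices are normalized to [0, 1] before differencing so populations of
    different sizes are comparable; differences lie in [-1, 1].
    """
    pre_o, post_o = orderings
    return pre_o.normalized_index[conn.pre_id] - post_o.normalized_index[conn.post_id]


def index_difference_histogram(conn: Connectome, orderings: tuple, bins: int = 50):
    """Histogram of normalized index differences over [-1, 1].

    Returns ``(counts, edges)``; empty connectome yields all-zero counts.
    """
    d = index_differences(conn, orderings)
    return np.histogram(d, bins=bins, range=(-1.0, 1.0))


def spread_by_band(
    conn: Connectome,
    orderings: tuple,
    n_bands: int = 4,
    band_index: np.ndarray | None = None,
):
    """Standard deviation of index differences per band of pre neurons.

    Pre neurons are partitioned into ``n_bands`` equal bands of normalized
    index (by default along the ordering axis; pass ``band_index`` to band
    by a different per-pre-neuron coordinate in [0, 1]).  Bands without
    synapses come back NaN — undefined spread, flagged rather than guessed.
    """
    d = index_differences(conn, orderings)
    pre_o = orderings[0]
    coord = pre_o.normalized_index if band_index is None else np.asarray(band_index)
    band = np.minimum((coord[conn.pre_id] * n_bands).astype(int), n_bands - 1)
    out = np.full(n_bands, np.nan)
    for b in range(n_bands):
        sel = band == b
        if sel.sum() >= 2:
            out[b] = d[sel].std(ddof=1)
    return out


def grouped_std_err(values: np.ndarray, groups: np.ndarray, n_groups: int) -> tuple:
    """Standard deviation of ``values`` with a group-jackknife standard error.

    Synapses of one pre-synaptic neuron are correlated draws, so the
    uncertainty of a spread estimate is computed by delete-one-group
    jackknife over pre neurons (O(1) per group via sufficient statistics).
    Returns ``(std, se)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two values")
    sums = np.zeros(n_groups)
    sqs = np.zeros(n_groups)
    cnt = np.zeros(n_groups)
    np.add.at(sums, groups, values)
    np.add.at(sqs, groups, values * values)
    np.add.at(cnt, groups, 1)
    occupied = cnt > 0
    S, Q = values.sum(), (values * values).sum()
    rem_n = n - cnt[occupied]
    loo_var = ((Q - sqs[occupied]) - (S - sums[occupied]) ** 2 / rem_n) / (rem_n - 1)
    loo_s = np.sqrt(np.maximum(loo_var, 0.0))
    g = int(occupied.sum())
    se = np.sqrt((g - 1) / g * ((loo_s - loo_s.mean()) ** 2).sum())
    return float(values.std(ddof=1)), float(se)


def distance_histogram(conn: Connectome, bins=30):
    """Histogram of total connection lengths (mm); counts sum to records."""
    return np.histogram(conn.total_mm, bins=bins)


def ks_compare(sample_a, sample_b) -> tuple:
    """Two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` with the exact supremum distance between the two
    empirical CDFs and the asymptotic p-value from the Kolmogorov
    distribution (reported as computed, however small).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be non-empty")
    both = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, both, side="right") / na
    cdf_b = np.searchsorted(b, both, side="right") / nb
    d = float(np.abs(cdf_a - cdf_b).max())
    en = na * nb / (na + nb)
    p = float(special.kolmogorov(np.sqrt(en) * d))
    return d, min(max(p, 0.0), 1.0)
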