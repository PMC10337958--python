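"""Structural comparison of co-abundance networks.

Similarity between two networks is the Jaccard index of their edge sets,
J = |E_A ∩ E_B| / |E_A ∪ E_B|.  Observed values are judged against an
ensemble of shuffled networks in which each edge set is replaced by a
uniform random set of the same size over all node pairs; the empirical
p-value is the fraction of shuffled realizations whose Jaccard is equal
to or larger than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .abundance import AbundanceTable
from .network import CoAbundanceNetwork, NetworkParams, reconstruct_network

__all__ = [
    "NetworkComparison",
    "jaccard_similarity",
    "expected_null_jaccard",
    "shuffled_network_ensemble",
    "compare_with_null",
    "indirect_group_shift",
    "bootstrap_similarity_distribution",
]


@dataclass(frozen=True)
class NetworkComparison:
    jaccard: float
    n_intersection: int
    n_union: int
    null_jaccards: tuple[float, ...]
    p_empirical: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_jaccards))

    @property
    def null_std(self) -> float:
        return float(np.std(self.null_jaccards, ddof=1))

    @property
    def p_label(self) -> str:
        """Empirical p, floored at 1/n_realizations when no null reaches it."""
        n = len(self.null_jaccards)
        return f"<{1 / n:g}" if self.p_empirical == 0 else f"{self.p_empirical:g}"


def jaccard_similarity(
    net_a: CoAbundanceNetwork, net_b: CoAbundanceNetwork
) -> float:
    """Jaccard index of two networks' edge sets (edges as unordered pairs)."""
    ea, eb = net_a.edges, net_b.edges
    union = len(ea | eb)
    if union == 0:
        raise ValueError("both edge sets empty: Jaccard undefined (0/0)")
    return len(ea & eb) / union


def expected_null_jaccard(n_nodes: int, m_a: int, m_b: int) -> float:
    """First-order expectation of J between two uniform random edge sets.

    With M = C(n_nodes, 2) possible pairs, the intersection size is
    hypergeometric with mean m_a * m_b / M; the expectation of the ratio is
    approximated by the ratio of expectations (excellent for m << M).
    """
    m_pairs = math.comb(n_nodes, 2)
    e_inter = m_a * m_b / m_pairs
    return e_inter / (m_a + m_b - e_inter)


def _require_shared_nodes(
    net_a: CoAbundanceNetwork, net_b: CoAbundanceNetwork
) -> int:
    if set(net_a.node_ids) != set(net_b.node_ids):
        raise ValueError("networks must share one node universe")
    return net_a.n_nodes


def shuffled_network_ensemble(
    net_a: CoAbundanceNetwork,
    net_b: CoAbundanceNetwork,
    n_realizations: int = 1000,
    rng_seed: int = 0,
) -> list[float]:
    """Jaccard values between pairs of edge-shuffled surrogate networks.

    Each realization redraws both edge sets uniformly at random (same node
    set, same edge counts) and records their Jaccard index, giving the
    similarity level expected of two independent networks of these sizes.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    n_nodes = _require_shared_nodes(net_a, net_b)
    m_pairs = math.comb(n_nodes, 2)
    m_a, m_b = net_a.n_edges, net_b.n_edges
    if m_a > m_pairs or m_b > m_pairs:
        raise ValueError(
            f"edge count exceeds the {m_pairs} possible pairs on {n_nodes} nodes"
        )
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_realizations):
        ea = rng.choice(m_pairs, size=m_a, replace=False)
        eb = rng.choice(m_pairs, size=m_b, replace=False)
        inter = np.intersect1d(ea, eb, assume_unique=True).size
        out.append(inter / (m_a + m_b - inter))
    return out


def compare_with_null(
    net_a: CoAbundanceNetwork,
    net_b: CoAbundanceNetwork,
    n_realizations: int = 1000,
    rng_seed: int = 0,
) -> NetworkComparison:
    """Observed Jaccard plus shuffled-ensemble null and empirical p-value."""
    observed = jaccard_similarity(net_a, net_b)
    nulls = shuffled_network_ensemble(net_a, net_b, n_realizations, rng_seed)
    p = sum(1 for j in nulls if j >= observed) / len(nulls)
    inter = len(net_a.edges & net_b.edges)
    return NetworkComparison(
        jaccard=observed,
        n_intersection=inter,
        n_union=len(net_a.edges | net_b.edges),
        null_jaccards=tuple(nulls),
        p_empirical=p,
    )


def indirect_group_shift(
    reference: CoAbundanceNetwork,
    target_before: CoAbundanceNetwork,
    target_after: CoAbundanceNetwork,
) -> tuple[float, float]:
    """Similarity of a target group to a reference, before and after.

    Returns (J(reference, before), J(reference, after)); a drop in the
    second value indicates the target group diverged from the reference.
    """
    _require_shared_nodes(reference, target_before)
    _require_shared_nodes(reference, target_after)
    return (
        jaccard_similarity(reference, target_before),
        jaccard_similarity(reference, target_after),
    )


def bootstrap_similarity_distribution(
    table_a: AbundanceTable,
    table_b: AbundanceTable,
    params: NetworkParams = NetworkParams(),
    n_bootstrap: int = 100,
    rng_seed: int = 0,
) -> list[float]:
    """Bootstrap distribution of the Jaccard similarity of two cohorts.

    Subjects of each cohort are resampled with replacement, networks
    rebuilt under identical parameters, and the Jaccard recorded — one
    value per replicate.  This turns a single network-pair similarity into
    a distribution suitable for rank-based group tests; it is this
    package's own construction for that purpose.
    """
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_bootstrap):
        ids_a = list(rng.choice(table_a.sample_ids, size=table_a.n_samples))
        ids_b = list(rng.choice(table_b.sample_ids, size=table_b.n_samples))
        # re-index with unique names so resampled duplicates are kept
        da = table_a.data.loc[ids_a].set_axis([f"b{i}" for i in range(len(ids_a))])
        db = table_b.data.loc[ids_b].set_axis([f"b{i}" for i in range(len(ids_b))])
        ta = AbundanceTable(data=da, is_relative=table_a.is_relative)
        tb = AbundanceTable(data=db, is_relative=table_b.is_relative)
        na = reconstruct_network(
            ta, n_edges=params.n_edges, w_threshold=params.w_threshold,
            n_shuffles=params.n_shuffles, rng_seed=params.rng_seed,
            rank_abs=params.rank_abs,
            resample_with_replacement=params.resample_with_replacement,
        )
        nb = reconstruct_network(
            tb, n_edges=params.n_edges, w_threshold=params.w_threshold,
            n_shuffles=params.n_shuffles, rng_seed=params.rng_seed,
            rank_abs=params.rank_abs,
            resample_with_replacement=params.resample_with_replacement,
        )
        out.append(jaccard_similarity(na, nb))
    return out
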