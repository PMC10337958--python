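"""Co-abundance network reconstruction.

A cohort's network is built from its relative-abundance table in three
steps: (1) Pearson correlation for every OTU pair; (2) a Monte-Carlo
significance filter — each OTU's abundance vector is shuffled many times
independently of the others, and the observed correlation C is converted
into the Z-score

    W = (C - mean(C_shuffle)) / std(C_shuffle),

with pairs below a W threshold (default 1) discarded; (3) the surviving
pairs are ranked by Pearson value and a fixed number of top edges
(default 500) kept, so that networks of different cohorts are compared at
equal size.

The shuffle null preserves each OTU's empirical abundance distribution
while destroying inter-OTU correlations.  ``reconstruct_network`` draws
one joint realization per shuffle (every OTU column permuted
independently, the full correlation matrix evaluated at once); the
per-pair entry point ``shuffle_null_for_pair`` uses a spawn-keyed
substream per pair.  Both are draws from the same null.  Columns are
canonicalised (sorted OTU ids, sorted values) before shuffling, so the
reconstructed edge set is invariant to sample and OTU input order.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceTable

__all__ = [
    "EdgeCandidate",
    "CoAbundanceNetwork",
    "NetworkParams",
    "pairwise_pearson",
    "shuffle_null_for_pair",
    "zscore",
    "pairwise_statistics",
    "reconstruct_network",
    "network_size_sweep",
    "read_edge_list",
]

Pair = tuple[str, str]

_SHUFFLE_CHUNK = 64  # realizations per vectorised block; bounds memory


def _as_pair(a: str, b: str) -> Pair:
    """Canonical unordered pair: lexicographically sorted id tuple."""
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class EdgeCandidate:
    pair: Pair
    r: float
    w: float
    null_mean: float
    null_std: float


@dataclass(frozen=True)
class NetworkParams:
    """Reconstruction parameters (defaults follow the published procedure)."""

    n_edges: int = 500
    w_threshold: float = 1.0
    n_shuffles: int = 1000
    rng_seed: int = 0
    rank_abs: bool = False
    resample_with_replacement: bool = False


@dataclass(frozen=True)
class CoAbundanceNetwork:
    """Binary OTU co-abundance network: node set + significant edge set."""

    node_ids: tuple[str, ...]
    edges: frozenset[Pair]
    edge_attrs: Mapping[Pair, tuple[float, float]]  # pair -> (r, w)
    n_edges_requested: int
    params: NetworkParams | None = None

    def __post_init__(self) -> None:
        nodes = set(self.node_ids)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop {a!r}")
            if a > b:
                raise ValueError(f"edge {a, b} not in canonical order")
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge endpoint outside node set: {(a, b)}")
        if len(self.edges) > self.n_edges_requested:
            raise ValueError("more edges than requested")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def shortfall(self) -> int:
        """How many edges short of the requested count the network is."""
        return self.n_edges_requested - len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for pair in sorted(self.edges):
            r, w = self.edge_attrs[pair]
            g.add_edge(*pair, pearson_r=r, z_score=w)
        return g

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"otu_a": a, "otu_b": b, "pearson_r": self.edge_attrs[(a, b)][0],
             "z_score": self.edge_attrs[(a, b)][1]}
            for a, b in sorted(self.edges)
        ]
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "pearson_r", "z_score"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_edge_list().to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path, node_ids: Sequence[str] | None = None,
                   n_edges_requested: int | None = None) -> CoAbundanceNetwork:
    """Load a network from an edge-list TSV written by :meth:`to_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"otu_a": str, "otu_b": str})
    pairs = [_as_pair(a, b) for a, b in zip(df["otu_a"], df["otu_b"])]
    attrs = {p: (float(r), float(w))
             for p, r, w in zip(pairs, df["pearson_r"], df["z_score"])}
    if node_ids is None:
        node_ids = sorted({n for p in pairs for n in p})
    return CoAbundanceNetwork(
        node_ids=tuple(node_ids),
        edges=frozenset(pairs),
        edge_attrs=attrs,
        n_edges_requested=n_edges_requested or len(pairs),
    )


# ---------------------------------------------------------------------------
# correlations and the shuffle null


def _check_table(table: AbundanceTable) -> np.ndarray:
    if not table.is_relative:
        raise ValueError("network reconstruction expects relative abundances "
                         "(run normalize_relative first)")
    if table.n_samples < 3:
        raise ValueError(f"need >=3 samples, got {table.n_samples}")
    return table.values


def _pearson_matrix(values: np.ndarray) -> np.ndarray:
    """Column-wise Pearson matrix; NaN where either column is constant."""
    n = values.shape[0]
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    constant = np.ptp(values, axis=0) == 0  # exactly constant columns
    sd[constant] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mu) / sd
    corr = z.T @ z / n
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    return np.clip(corr, -1.0, 1.0, out=corr)


def pairwise_pearson(table: AbundanceTable) -> dict[Pair, float]:
    """Pearson r for every unordered OTU pair.

    Pairs where either OTU is constant across samples map to NaN (the
    undefined marker) and are excluded from network reconstruction.
    """
    values = _check_table(table)
    corr = _pearson_matrix(values)
    ids = table.otu_ids
    out: dict[Pair, float] = {}
    p = len(ids)
    for i in range(p):
        for j in range(i + 1, p):
            out[_as_pair(ids[i], ids[j])] = float(corr[i, j])
    return out


def _row_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of two (m, n) arrays."""
    xz = x - x.mean(axis=1, keepdims=True)
    yz = y - y.mean(axis=1, keepdims=True)
    num = (xz * yz).sum(axis=1)
    den = np.sqrt((xz**2).sum(axis=1) * (yz**2).sum(axis=1))
    return num / den


def shuffle_null_for_pair(
    table: AbundanceTable,
    pair: Pair,
    n_shuffles: int = 1000,
    rng_seed: int = 0,
    resample_with_replacement: bool = False,
) -> tuple[float, float]:
    """Null mean and s.d. of Pearson r for one OTU pair under shuffling.

    Each shuffle resamples both OTUs' abundance vectors from their own
    empirical distributions (permutation by default; with-replacement
    resampling optionally), independently of each other.  The random
    substream is keyed on the pair's column indices, so every pair's null
    is reproducible regardless of evaluation order.
    """
    values = _check_table(table)
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    ids = table.otu_ids
    try:
        i, j = ids.index(pair[0]), ids.index(pair[1])
    except ValueError as exc:
        raise KeyError(f"pair {pair} not in table") from exc
    x, y = values[:, i], values[:, j]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"degenerate pair {pair}: zero variance")
    rng = np.random.default_rng(
        np.random.SeedSequence(rng_seed, spawn_key=(min(i, j), max(i, j)))
    )
    n = len(x)
    if resample_with_replacement:
        xs = x[rng.integers(0, n, size=(n_shuffles, n))]
        ys = y[rng.integers(0, n, size=(n_shuffles, n))]
    else:
        xs = x[rng.random((n_shuffles, n)).argsort(axis=1)]
        ys = y[rng.random((n_shuffles, n)).argsort(axis=1)]
    r = _row_pearson(xs, ys)
    return float(r.mean()), float(r.std(ddof=1))


def zscore(r: float, null_mean: float, null_std: float) -> float:
    """Standardise an observed correlation against its shuffle null (W)."""
    if null_std <= 0:
        raise ValueError("null_std must be positive for a defined Z-score")
    return (r - null_mean) / null_std


def _null_moments(
    values: np.ndarray,
    n_shuffles: int,
    rng: np.random.Generator,
    with_replacement: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair mean and s.d. of the shuffled correlation matrix.

    One realization = every column independently permuted (or resampled),
    then the full Pearson matrix.  Columns are pre-sorted so the result
    depends only on each OTU's value multiset, not on sample order.
    """
    n, p = values.shape
    sorted_cols = np.sort(values, axis=0)
    total = np.zeros((p, p))
    total_sq = np.zeros((p, p))
    done = 0
    while done < n_shuffles:
        m = min(_SHUFFLE_CHUNK, n_shuffles - done)
        if with_replacement:
            idx = rng.integers(0, n, size=(m, n, p))
        else:
            idx = rng.random((m, n, p)).argsort(axis=1)
        shuffled = sorted_cols[idx, np.arange(p)]  # (m, n, p)
        mu = shuffled.mean(axis=1, keepdims=True)
        sd = shuffled.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (shuffled - mu) / sd
        z = np.nan_to_num(z)
        corr = np.einsum("mnp,mnq->mpq", z, z) / n
        total += corr.sum(axis=0)
        total_sq += (corr**2).sum(axis=0)
        done += m
    mean = total / n_shuffles
    var = (total_sq - n_shuffles * mean**2) / (n_shuffles - 1)
    std = np.sqrt(np.clip(var, 0.0, None))
    return mean, std


def pairwise_statistics(
    table: AbundanceTable,
    n_shuffles: int = 1000,
    rng_seed: int = 0,
    resample_with_replacement: bool = False,
) -> pd.DataFrame:
    """Pearson r, null moments and Z-score W for every defined OTU pair.

    Returns a DataFrame with one row per unordered pair (otu_a < otu_b)
    and columns otu_a, otu_b, pearson_r, null_mean, null_std, z_score.
    Zero-variance OTUs and zero-null-std pairs are excluded.
    """
    _check_table(table)
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    # canonical column order -> results invariant to input OTU order
    data = table.data.reindex(sorted(table.otu_ids), axis=1)
    values = data.to_numpy(dtype=float)
    ids = np.array(data.columns)
    corr = _pearson_matrix(values)
    rng = np.random.default_rng(rng_seed)
    null_mean, null_std = _null_moments(
        values, n_shuffles, rng, resample_with_replacement
    )
    iu, ju = np.triu_indices(len(ids), k=1)
    r = corr[iu, ju]
    nm = null_mean[iu, ju]
    ns = null_std[iu, ju]
    ok = np.isfinite(r) & (ns > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (r - nm) / ns
    return pd.DataFrame(
        {
            "otu_a": ids[iu[ok]],
            "otu_b": ids[ju[ok]],
            "pearson_r": r[ok],
            "null_mean": nm[ok],
            "null_std": ns[ok],
            "z_score": w[ok],
        }
    )


def reconstruct_network(
    table: AbundanceTable,
    n_edges: int = 500,
    w_threshold: float = 1.0,
    n_shuffles: int = 1000,
    rng_seed: int = 0,
    rank_abs: bool = False,
    resample_with_replacement: bool = False,
) -> CoAbundanceNetwork:
    """Build the fixed-size co-abundance network of one cohort.

    Pairs with W below ``w_threshold`` are discarded; the survivors are
    ranked by Pearson r (signed by default; ``rank_abs`` ranks by \\|r\\|)
    and the top ``n_edges`` kept.  Ties at the cutoff are broken by the
    lexicographic order of the sorted OTU-id pair.  If fewer pairs survive
    than requested, all are kept and the shortfall is recorded.
    """
    if n_edges <= 0:
        raise ValueError("n_edges must be positive")
    stats = pairwise_statistics(
        table, n_shuffles=n_shuffles, rng_seed=rng_seed,
        resample_with_replacement=resample_with_replacement,
    )
    surviving = stats[stats["z_score"] >= w_threshold].copy()
    key = surviving["pearson_r"].abs() if rank_abs else surviving["pearson_r"]
    surviving["_rank_key"] = -key
    surviving = surviving.sort_values(
        ["_rank_key", "otu_a", "otu_b"], kind="mergesort"
    ).head(n_edges)
    edges = frozenset(
        _as_pair(a, b) for a, b in zip(surviving["otu_a"], surviving["otu_b"])
    )
    attrs = {
        _as_pair(a, b): (float(r), float(w))
        for a, b, r, w in zip(
            surviving["otu_a"], surviving["otu_b"],
            surviving["pearson_r"], surviving["z_score"],
        )
    }
    params = NetworkParams(
        n_edges=n_edges, w_threshold=w_threshold, n_shuffles=n_shuffles,
        rng_seed=rng_seed, rank_abs=rank_abs,
        resample_with_replacement=resample_with_replacement,
    )
    return CoAbundanceNetwork(
        node_ids=tuple(table.otu_ids),
        edges=edges,
        edge_attrs=attrs,
        n_edges_requested=n_edges,
        params=params,
    )


def network_size_sweep(
    table: AbundanceTable,
    w_thresholds: Sequence[float],
    n_shuffles: int = 1000,
    rng_seed: int = 0,
) -> dict[float, int]:
    """Edge count as a function of the W threshold (no fixed-size cap).

    Shows how unfixed network size varies with the significance threshold,
    motivating the fixed-edge-count design.
    """
    if len(w_thresholds) == 0:
        raise ValueError("w_thresholds must be non-empty")
    stats = pairwise_statistics(table, n_shuffles=n_shuffles, rng_seed=rng_seed)
    w = stats["z_score"].to_numpy()
    return {float(t): int((w >= t).sum()) for t in w_thresholds}
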