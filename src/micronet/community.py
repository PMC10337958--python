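"""Conventional community-level analysis: rJSD beta diversity and PCoA.

The root Jensen-Shannon divergence between two relative-abundance
vectors x, y is

    rJSD(x, y) = sqrt( [ D_KL(x_hat, m) + D_KL(y_hat, m) ] / 2 ),

where x_hat, y_hat are the abundances renormalised over the shared
support (taxa nonzero in both samples) and m is their midpoint.  With
base-2 logarithms the value lies in [0, 1].  Pairwise rJSD matrices feed
within-group beta diversity, mean distance to a reference group,
classical PCoA ordination and rank-based group tests — the community
baseline the network analysis is contrasted with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .abundance import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "rjsd",
    "distance_matrix",
    "within_group_beta",
    "mean_distance_to_reference",
    "pcoa",
    "rank_sum_test",
    "bonferroni",
    "differential_abundance",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise sample distances with zero diagonal."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = self.d
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        pos = [self.ids.index(i) for i in ids]
        return DistanceMatrix(ids=tuple(ids), d=self.d[np.ix_(pos, pos)])


def rjsd(x: np.ndarray, y: np.ndarray, shared_support: bool = True) -> float:
    """Root Jensen-Shannon divergence between two abundance vectors.

    By default both vectors are renormalised over the taxa present in
    *both* samples before the divergence is taken; ``shared_support=False``
    uses the vectors as given (renormalised over their own totals), the
    more common JSD variant, for sensitivity checks.  Base-2 logs, so the
    result is in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share one OTU list")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundances")
    if shared_support:
        s = (x > 0) & (y > 0)
        if not s.any():
            raise ValueError("no shared taxa between the two samples")
        x, y = x[s], y[s]
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("zero-total abundance vector")
    x = x / x.sum()
    y = y / y.sum()
    # jensenshannon returns sqrt(JSD) already, i.e. the rJSD metric
    val = float(jensenshannon(x, y, base=2))
    return 0.0 if np.isnan(val) else val


def distance_matrix(
    table: AbundanceTable, shared_support: bool = True
) -> DistanceMatrix:
    """All pairwise rJSD distances between samples of a table."""
    if not table.is_relative:
        raise ValueError("distance_matrix expects relative abundances")
    values = table.values
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = rjsd(values[i], values[j], shared_support)
    return DistanceMatrix(ids=tuple(table.sample_ids), d=d)


def within_group_beta(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    group: str,
    timepoint: str,
    shared_support: bool = True,
) -> list[float]:
    """Within-group beta diversity: all C(n,2) pairwise rJSD distances."""
    meta = metadata.set_index("sample_id")
    ids = [
        s for s in table.sample_ids
        if meta.at[s, "group"] == group and meta.at[s, "timepoint"] == timepoint
    ]
    if len(ids) < 2:
        raise ValueError(f"group {group}:{timepoint} has fewer than 2 samples")
    dm = distance_matrix(table.select_samples(ids), shared_support)
    iu, ju = np.triu_indices(len(ids), k=1)
    return [float(v) for v in dm.d[iu, ju]]


def mean_distance_to_reference(
    sample: np.ndarray, reference: AbundanceTable, shared_support: bool = True
) -> float:
    """Mean rJSD from one sample's abundance vector to every reference sample."""
    if reference.n_samples == 0:
        raise ValueError("reference table is empty")
    ref = reference.values
    return float(
        np.mean([rjsd(sample, ref[i], shared_support) for i in range(len(ref))])
    )


@dataclass(frozen=True)
class PCoAResult:
    """Classical-scaling ordination of a distance matrix."""

    coordinates: pd.DataFrame  # samples x axes (PC1, PC2, ...)
    explained_fraction: np.ndarray  # over the positive spectrum
    negative_eigenvalue_magnitude: float  # sum |negative eigenvalues|

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Principal coordinates analysis (classical metric scaling).

    Double-centres -D^2/2, eigendecomposes, and keeps the ``n_axes``
    largest non-negative eigenvalues.  Explained fractions are taken over
    the positive spectrum only; negative eigenvalues (non-Euclidean part
    of the distance) are dropped and their total magnitude reported.
    """
    n = len(dm.ids)
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm.d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals).max()) if n else 0.0
    positive = eigvals > tol
    n_pos = int(positive.sum())
    neg_mag = float(-eigvals[eigvals < -tol].sum())
    if n_axes > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes",
            RuntimeWarning,
            stacklevel=2,
        )
        n_axes = n_pos
    lam = eigvals[:n_axes]
    coords = eigvecs[:, :n_axes] * np.sqrt(lam)
    pos_sum = eigvals[positive].sum()
    explained = lam / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i+1}" for i in range(n_axes)]
    )
    return PCoAResult(
        coordinates=frame,
        explained_fraction=explained,
        negative_eigenvalue_magnitude=neg_mag,
    )


def rank_sum_test(a, b, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def bonferroni(pvalues) -> np.ndarray:
    """Bonferroni-adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    return np.minimum(p * len(p), 1.0)


def differential_abundance(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
) -> pd.DataFrame:
    """Per-OTU rank-sum screen between two (group, timepoint) cohorts.

    Returns a DataFrame indexed by OTU id with raw and Bonferroni-adjusted
    two-sided Mann-Whitney p-values.
    """
    meta = metadata.set_index("sample_id")

    def _ids(g, tp):
        return [
            s for s in table.sample_ids
            if meta.at[s, "group"] == g and meta.at[s, "timepoint"] == tp
        ]

    ids_a, ids_b = _ids(*group_a), _ids(*group_b)
    if not ids_a or not ids_b:
        raise ValueError("both cohorts must be non-empty")
    va = table.select_samples(ids_a).values
    vb = table.select_samples(ids_b).values
    pvals = [rank_sum_test(va[:, j], vb[:, j]) for j in range(table.n_otus)]
    return pd.DataFrame(
        {"p_value": pvals, "p_bonferroni": bonferroni(pvals)},
        index=table.otu_ids,
    )
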