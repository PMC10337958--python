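"""Leave-one-out network impact of individual samples.

How much does one subject bend its cohort's co-abundance network?  Two
scores answer this, both built from networks reconstructed with and
without the subject under identical parameters and seed:

* direct impact (Jaccard dissimilarity of the cohort network to itself
  after removing sample k):

      1 - J(B^n, B^{n-k})          in [0, 1]

* indirect impact (shift of the cohort network's similarity to a
  reference cohort's network A^m when sample k is removed):

      J(A^m, B^{n-k}) - J(A^m, B^n)   in [-1, 1]

A positive indirect impact means removing k makes the cohort *more*
similar to the reference, i.e. k was pulling it away.  Unlike
single-sample network inference, only the magnitude of each sample's
perturbation is estimated, not a per-sample network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable
from .compare import jaccard_similarity
from .network import CoAbundanceNetwork, NetworkParams, reconstruct_network

__all__ = [
    "ImpactProfile",
    "direct_impact",
    "indirect_impact",
    "impact_profile",
    "impact_outlier_test",
]


def _reconstruct(table: AbundanceTable, params: NetworkParams) -> CoAbundanceNetwork:
    return reconstruct_network(
        table,
        n_edges=params.n_edges,
        w_threshold=params.w_threshold,
        n_shuffles=params.n_shuffles,
        rng_seed=params.rng_seed,
        rank_abs=params.rank_abs,
        resample_with_replacement=params.resample_with_replacement,
    )


@dataclass(frozen=True)
class ImpactProfile:
    """Per-sample leave-one-out impact scores for one cohort."""

    cohort_id: str
    scores: pd.DataFrame  # index sample_id; direct_impact [, indirect_impact]
    n_edges: int
    seed: int

    @property
    def direct(self) -> pd.Series:
        return self.scores["direct_impact"]

    @property
    def indirect(self) -> pd.Series | None:
        if "indirect_impact" not in self.scores:
            return None
        return self.scores["indirect_impact"]

    def to_tsv(self, path: str | Path) -> None:
        self.scores.rename_axis("sample_id").to_csv(path, sep="\t")


def _check_membership(cohort: AbundanceTable, sample_k: str) -> None:
    if sample_k not in cohort.sample_ids:
        raise KeyError(f"sample {sample_k!r} not in cohort")
    if cohort.n_samples < 4:
        raise ValueError("cohort needs >=4 samples so >=3 remain after removal")


def direct_impact(
    cohort: AbundanceTable, sample_k: str, params: NetworkParams = NetworkParams()
) -> float:
    """1 - J between the cohort network with and without sample k."""
    _check_membership(cohort, sample_k)
    full = _reconstruct(cohort, params)
    loo = _reconstruct(cohort.drop_sample(sample_k), params)
    return 1.0 - jaccard_similarity(full, loo)


def indirect_impact(
    cohort: AbundanceTable,
    reference: AbundanceTable,
    sample_k: str,
    params: NetworkParams = NetworkParams(),
) -> float:
    """Shift of the cohort-to-reference similarity when sample k is removed."""
    _check_membership(cohort, sample_k)
    if sample_k in reference.sample_ids:
        raise ValueError(f"sample {sample_k!r} is in the reference cohort")
    ref_net = _reconstruct(reference, params)
    full = _reconstruct(cohort, params)
    loo = _reconstruct(cohort.drop_sample(sample_k), params)
    return jaccard_similarity(ref_net, loo) - jaccard_similarity(ref_net, full)


def impact_profile(
    cohort: AbundanceTable,
    reference: AbundanceTable | None = None,
    params: NetworkParams = NetworkParams(),
    cohort_id: str = "cohort",
) -> ImpactProfile:
    """Leave-one-out impact scores for every sample of a cohort.

    The full-cohort network B^n (and the reference network, if given) is
    reconstructed once and reused across all leave-one-out evaluations;
    every reconstruction uses the same master seed, so the profile is
    deterministic and invariant to the order samples are listed.
    """
    if cohort.n_samples < 4:
        raise ValueError("cohort needs >=4 samples")
    if reference is not None:
        overlap = set(cohort.sample_ids) & set(reference.sample_ids)
        if overlap:
            raise ValueError(f"cohort and reference share samples: {sorted(overlap)}")
    full = _reconstruct(cohort, params)
    ref_net = _reconstruct(reference, params) if reference is not None else None
    j_ref_full = (
        jaccard_similarity(ref_net, full) if ref_net is not None else None
    )
    rows = {}
    for sample_k in cohort.sample_ids:
        loo = _reconstruct(cohort.drop_sample(sample_k), params)
        row = {"direct_impact": 1.0 - jaccard_similarity(full, loo)}
        if ref_net is not None:
            row["indirect_impact"] = (
                jaccard_similarity(ref_net, loo) - j_ref_full
            )
        rows[sample_k] = row
    scores = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return ImpactProfile(
        cohort_id=cohort_id,
        scores=scores,
        n_edges=params.n_edges,
        seed=params.rng_seed,
    )


def impact_outlier_test(
    profile: ImpactProfile, sample_k: str, which: str = "direct_impact"
) -> float:
    """One-sided signed-rank p-value that sample k's impact is unusually high.

    Tests the differences {score_j - score_k : j != k} against zero
    location with the Wilcoxon signed-rank test, one-sided towards k
    being higher (differences negative).  All-zero differences give p = 1.
    """
    if which not in profile.scores.columns:
        raise KeyError(f"no {which!r} column in profile")
    s = profile.scores[which]
    if sample_k not in s.index:
        raise KeyError(f"sample {sample_k!r} not in profile")
    others = s.drop(sample_k).to_numpy(dtype=float)
    if len(others) < 6:
        raise ValueError("need >=6 other samples for the signed-rank test")
    diffs = others - float(s[sample_k])
    if np.all(diffs == 0):
        return 1.0
    return float(
        stats.wilcoxon(diffs, alternative="less", zero_method="wilcox").pvalue
    )
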