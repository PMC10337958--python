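"""Synthetic microbiome cohorts with a planted co-abundance structure.

Cohorts are simulated with a latent Gaussian copula: correlated standard
normals (target correlation ``rho`` on the planted OTU pairs, zero
elsewhere, nearest-PSD repair applied if needed) are pushed through a
per-OTU log-normal to produce heavy-tailed absolute abundances, closed to
relative abundances, and sequenced by a multinomial draw at a fixed read
depth.  The construction gives direct control of the pairwise correlation
structure while keeping the compositional, discrete character of real
amplicon data; it is a stand-in for such data, not a model of any
particular cohort.

Optional outlier samples have their correlation pattern disrupted —
by default through a within-sample permutation of OTU values, which
preserves the sample's abundance distribution (community-level distances
barely move) while destroying its co-abundance pattern (network impact
moves).  The ground truth returned alongside each table suffices to score
planted-edge recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .network import CoAbundanceNetwork, Pair, _as_pair

__all__ = [
    "SyntheticCommunitySpec",
    "generate_cohort",
    "block_planted_edges",
    "study_scale_fixture",
    "merge_cohorts",
    "edge_recovery",
]

IndexPair = tuple[int, int]


@dataclass(frozen=True)
class SyntheticCommunitySpec:
    """Parameters of the planted-network community generator.

    Defaults emulate one cohort of the kind of 16S study this package
    targets: 30 subjects, 108 OTUs after filtering, ~5e4 reads/sample.
    """

    n_samples: int = 30
    n_otus: int = 108
    planted_edges: tuple[IndexPair, ...] = ()
    rho: float = 0.9
    log_mean_scale: float = 1.0  # per-OTU log-abundance location ~ N(0, scale^2)
    log_sigma: float = 0.8  # per-OTU log-abundance scale (heavy tail)
    sequencing_depth: int = 50_000
    #: (sample index, mode) or (sample index, mode, strength in (0, 1]);
    #: strength is the fraction of OTU labels the disruption touches
    outlier_samples: tuple[tuple, ...] = ()
    seed: int = 0
    otu_prefix: str = "OTU"
    sample_prefix: str = "s"

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must be strictly between 0 and 1")
        for i, j in self.planted_edges:
            if i == j:
                raise ValueError(f"planted self-pair ({i}, {j})")
            if not (0 <= i < self.n_otus and 0 <= j < self.n_otus):
                raise ValueError(f"planted edge ({i}, {j}) outside OTU range")
        for entry in self.outlier_samples:
            idx, mode, strength = self._outlier_entry(entry)
            if not 0 <= idx < self.n_samples:
                raise ValueError(f"outlier index {idx} outside sample range")
            if mode not in ("permute", "swap"):
                raise ValueError(f"unknown disruption mode {mode!r}")
            if not 0 < strength <= 1:
                raise ValueError(f"disruption strength {strength} outside (0, 1]")

    @staticmethod
    def _outlier_entry(entry) -> tuple[int, str, float]:
        if len(entry) == 2:
            idx, mode = entry
            return int(idx), str(mode), 1.0
        idx, mode, strength = entry
        return int(idx), str(mode), float(strength)

    @property
    def otu_ids(self) -> list[str]:
        width = len(str(self.n_otus))
        return [f"{self.otu_prefix}{i:0{width}d}" for i in range(self.n_otus)]

    @property
    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"{self.sample_prefix}{i:0{width}d}" for i in range(self.n_samples)]

    def planted_id_pairs(self) -> frozenset[Pair]:
        ids = self.otu_ids
        return frozenset(_as_pair(ids[i], ids[j]) for i, j in self.planted_edges)


def _planted_correlation(
    n_otus: int, edges: Sequence[IndexPair], rho: float, max_shift: float = 0.05
) -> np.ndarray:
    """Target latent correlation matrix with nearest-PSD repair.

    Eigenvalues are clipped at a small positive floor and the matrix
    rescaled to unit diagonal.  If the repair moves any planted
    correlation by more than ``max_shift``, the planted structure is too
    dense/strong to be realisable and an error is raised.
    """
    corr = np.eye(n_otus)
    for i, j in edges:
        corr[i, j] = corr[j, i] = rho
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() > 1e-8:
        return corr
    vals, vecs = np.linalg.eigh(corr)
    repaired = (vecs * np.clip(vals, 1e-8, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    shifts = [abs(repaired[i, j] - rho) for i, j in edges]
    if shifts and max(shifts) > max_shift:
        raise ValueError(
            f"PSD repair moved a planted correlation by {max(shifts):.3f} "
            f"(> {max_shift}); use fewer or weaker planted edges"
        )
    return repaired


def _latent_to_counts(
    z: np.ndarray,
    log_mean: np.ndarray,
    log_sigma: float,
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    latent = np.exp(log_mean + log_sigma * z)
    rel = latent / latent.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, p) for p in rel])


def generate_cohort(
    spec: SyntheticCommunitySpec,
) -> tuple[AbundanceTable, dict]:
    """Simulate one cohort's OTU count table plus its ground truth.

    Returns the counts table (samples x OTUs, ``is_relative=False``) and a
    ground-truth record with the planted edge set (as OTU-id pairs), the
    realised latent correlation matrix, the per-OTU log-normal parameters
    and the disrupted sample ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    corr = _planted_correlation(spec.n_otus, spec.planted_edges, spec.rho)
    chol = np.linalg.cholesky(corr)
    log_mean = rng.normal(0.0, spec.log_mean_scale, size=spec.n_otus)
    z = rng.standard_normal((spec.n_samples, spec.n_otus)) @ chol.T
    counts = _latent_to_counts(
        z, log_mean, spec.log_sigma, spec.sequencing_depth, rng
    )

    disrupted: dict[str, str] = {}
    sample_ids = spec.sample_ids
    for entry in spec.outlier_samples:
        idx, mode, strength = SyntheticCommunitySpec._outlier_entry(entry)
        if mode == "permute":
            # permute the values at a `strength` fraction of OTU positions
            n_touch = max(2, int(round(strength * spec.n_otus)))
            touched = rng.choice(spec.n_otus, size=n_touch, replace=False)
            counts[idx, touched] = counts[idx, rng.permutation(touched)]
        else:  # swap: redraw from a shifted (rewired) planted network
            shift = spec.n_otus // 2
            alt_edges = [
                ((i + shift) % spec.n_otus, (j + shift) % spec.n_otus)
                for i, j in spec.planted_edges
            ]
            alt_corr = _planted_correlation(spec.n_otus, alt_edges, spec.rho)
            z_alt = np.linalg.cholesky(alt_corr) @ rng.standard_normal(spec.n_otus)
            counts[idx] = _latent_to_counts(
                z_alt[None, :], log_mean, spec.log_sigma,
                spec.sequencing_depth, rng,
            )[0]
        disrupted[sample_ids[idx]] = f"{mode}:{strength:g}"

    table = AbundanceTable(
        data=pd.DataFrame(counts, index=sample_ids, columns=spec.otu_ids),
        is_relative=False,
    )
    truth = {
        "planted_edges": spec.planted_id_pairs(),
        "rho": spec.rho,
        "latent_correlation": corr,
        "log_mean": log_mean,
        "log_sigma": spec.log_sigma,
        "disrupted_samples": disrupted,
        "seed": spec.seed,
    }
    return table, truth


def block_planted_edges(
    n_otus: int, n_blocks: int, block_size: int, offset: int = 0
) -> tuple[IndexPair, ...]:
    """All within-block pairs for disjoint blocks of consecutive OTUs.

    Blocks of mutually correlated OTUs (ecological guilds) give a planted
    edge set whose uniform-``rho`` correlation matrix is positive definite
    for any rho in (0, 1), unlike an arbitrary random edge set.
    """
    if offset + n_blocks * block_size > n_otus:
        raise ValueError("blocks do not fit in the OTU range")
    edges = []
    for b in range(n_blocks):
        lo = offset + b * block_size
        members = range(lo, lo + block_size)
        edges.extend((i, j) for i in members for j in members if i < j)
    return tuple(edges)


def _relabel_edges(
    edges: Iterable[IndexPair], mapping: np.ndarray
) -> tuple[IndexPair, ...]:
    return tuple((int(mapping[i]), int(mapping[j])) for i, j in edges)


def study_scale_fixture(
    seed: int = 0,
    shared_fraction: float = 0.5,
    rho: float = 0.7,
    n_blocks: int = 9,
    block_size: int = 11,
    n_otus: int = 108,
    n_healthy: int = 30,
    n_gdm: int = 27,
    sequencing_depth: int = 50_000,
) -> tuple[dict[tuple[str, str], AbundanceTable], pd.DataFrame, dict]:
    """Four synthetic cohorts at the scale of a two-group, two-timepoint study.

    30 healthy + 27 affected subjects sampled at W0 and W2 over 108 shared
    OTUs.  The healthy cohorts share one planted block structure (495
    within-block pairs) at both timepoints; the affected (gdm) W0 cohort
    shares a fraction ``shared_fraction`` of the healthy blocks and its W2
    cohort is additionally rewired relative to its own W0 structure,
    emulating a perturbation between the two samplings.

    Returns (tables keyed by (group, timepoint), metadata, ground truth).
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(8) % (2**31)
    rng = np.random.default_rng(child[0])
    healthy_edges = block_planted_edges(n_otus, n_blocks, block_size)

    def _rewire(edges: tuple[IndexPair, ...], keep_blocks: int) -> tuple[IndexPair, ...]:
        """Keep the first ``keep_blocks`` blocks, rewire the rest onto a
        permuted OTU labelling so their edges are elsewhere."""
        kept = tuple(e for e in edges if e[0] < keep_blocks * block_size)
        to_move = tuple(e for e in edges if e[0] >= keep_blocks * block_size)
        mapping = np.arange(n_otus)
        movable = np.arange(keep_blocks * block_size, n_otus)
        mapping[movable] = rng.permutation(movable)
        return kept + _relabel_edges(to_move, mapping)

    keep = int(round(shared_fraction * n_blocks))
    gdm_w0_edges = _rewire(healthy_edges, keep)
    # W2 rewiring of the affected group keeps only half of its own blocks
    gdm_w2_edges = _rewire(gdm_w0_edges, max(keep // 2, 0))

    cohort_edges = {
        ("healthy", "W0"): healthy_edges,
        ("healthy", "W2"): healthy_edges,
        ("gdm", "W0"): gdm_w0_edges,
        ("gdm", "W2"): gdm_w2_edges,
    }
    sizes = {"healthy": n_healthy, "gdm": n_gdm}
    prefixes = {"healthy": "h", "gdm": "g"}

    tables: dict[tuple[str, str], AbundanceTable] = {}
    truth: dict = {"seed": seed, "shared_fraction": shared_fraction, "cohorts": {}}
    meta_rows = []
    for c, ((group, tp), edges) in enumerate(cohort_edges.items()):
        spec = SyntheticCommunitySpec(
            n_samples=sizes[group],
            n_otus=n_otus,
            planted_edges=edges,
            rho=rho,
            sequencing_depth=sequencing_depth,
            seed=int(child[c + 1]),
            sample_prefix=f"{prefixes[group]}{tp}_",
        )
        table, cohort_truth = generate_cohort(spec)
        tables[(group, tp)] = table
        truth["cohorts"][(group, tp)] = cohort_truth
        meta_rows.extend(
            {"sample_id": s, "group": group, "timepoint": tp}
            for s in table.sample_ids
        )
    metadata = pd.DataFrame(meta_rows)
    return tables, metadata, truth


def merge_cohorts(
    tables: dict[tuple[str, str], AbundanceTable]
) -> AbundanceTable:
    """Stack cohort tables (shared OTU list) into one counts table."""
    frames = [t.data for t in tables.values()]
    merged = pd.concat(frames, axis=0)
    return AbundanceTable(
        data=merged, is_relative=next(iter(tables.values())).is_relative
    )


def edge_recovery(
    network: CoAbundanceNetwork, planted: frozenset[Pair]
) -> dict[str, float]:
    """Precision/recall of a reconstructed edge set against planted pairs."""
    if not planted:
        raise ValueError("no planted edges to score against")
    hits = len(network.edges & planted)
    return {
        "precision": hits / len(network.edges) if network.edges else 0.0,
        "recall": hits / len(planted),
        "n_hits": float(hits),
    }
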