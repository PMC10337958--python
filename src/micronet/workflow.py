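"""End-to-end pipeline: filter -> normalize -> split -> networks -> reports.

``run_full_workflow`` ties the stages together: OTU filtering and
normalisation, cohort splitting, per-cohort network reconstruction, all
pairwise cohort comparisons against shuffled-network nulls, leave-one-out
impact profiles for a designated cohort against a reference, and the
rJSD/PCoA community baseline.  Every artifact embeds the master seed and
a hash of the parameters so a run can be reproduced from its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, community, compare, impact

from .network import NetworkParams, reconstruct_network

__all__ = ["RunConfig", "run_full_workflow"]

log = logging.getLogger("micronet")


@dataclass(frozen=True)
class RunConfig:
    table_path: str
    metadata_path: str
    out_dir: str
    orientation: str = "otus_as_rows"
    min_total_count: float = 10
    min_prevalence_fraction: float = 0.10
    n_edges: int = 500
    w_threshold: float = 1.0
    n_shuffles: int = 1000
    null_realizations: int = 1000
    bootstrap_replicates: int = 0  # 0 disables the bootstrap similarity step
    impact_cohort: str | None = "gdm:W0"
    impact_reference: str | None = "healthy:W0"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_edges", "n_shuffles", "null_realizations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_total_count < 0 or not 0 <= self.min_prevalence_fraction <= 1:
            raise ValueError("invalid filter thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def params_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def network_params(self) -> NetworkParams:
        return NetworkParams(
            n_edges=self.n_edges,
            w_threshold=self.w_threshold,
            n_shuffles=self.n_shuffles,
            rng_seed=self.seed,
        )


def _parse_cohort(label: str) -> tuple[str, str]:
    group, sep, tp = label.partition(":")
    if not sep or not group or not tp:
        raise ValueError(f"cohort label {label!r} must be group:timepoint")
    return group, tp


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def run_full_workflow(config: RunConfig) -> dict:
    """Execute the whole pipeline and write a report bundle to disk.

    Returns a summary dict (also written as ``report.json``).  Any stage
    error aborts with a stage-tagged message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": config.seed, "params_hash": config.params_hash(),
                  "config": asdict(config)}
    summary: dict = {"provenance": provenance, "stages": {}}
    timings: dict[str, float] = {}

    def run_stage(name, fn):
        t0 = _stage(name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-tag with stage name
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    # -- load, filter, normalise, split ---------------------------------
    def load():
        table = abundance.read_abundance_table(
            config.table_path, orientation=config.orientation
        )
        meta = abundance.read_metadata(config.metadata_path)
        return table, meta

    table, meta = run_stage("load", load)
    filtered = run_stage(
        "filter",
        lambda: abundance.filter_otus(
            table, config.min_total_count, config.min_prevalence_fraction
        ),
    )
    rel = run_stage("normalize", lambda: abundance.normalize_relative(filtered))
    cohorts = run_stage("split", lambda: abundance.split_groups(rel, meta))
    cohorts = {k: v for k, v in cohorts.items() if v.n_samples > 0}
    summary["stages"]["preprocess"] = {
        "n_samples": table.n_samples,
        "n_otus_raw": table.n_otus,
        "n_otus_filtered": filtered.n_otus,
        "cohorts": {f"{g}:{t}": c.n_samples for (g, t), c in cohorts.items()},
    }

    # -- per-cohort networks ---------------------------------------------
    params = config.network_params()

    def build_networks():
        nets = {}
        for (group, tp), cohort in cohorts.items():
            if cohort.n_samples < 3:
                log.warning("skipping %s:%s (<3 samples)", group, tp)
                continue
            net = reconstruct_network(
                cohort, n_edges=params.n_edges, w_threshold=params.w_threshold,
                n_shuffles=params.n_shuffles, rng_seed=params.rng_seed,
            )
            net.to_tsv(out / f"network_{group}_{tp}.tsv")
            nets[(group, tp)] = net
        return nets

    networks = run_stage("networks", build_networks)
    summary["stages"]["networks"] = {
        f"{g}:{t}": {"n_edges": n.n_edges, "shortfall": n.shortfall}
        for (g, t), n in networks.items()
    }

    # -- pairwise comparisons with shuffled-network nulls ----------------
    def compare_all():
        results = {}
        keys = sorted(networks)
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                ka, kb = keys[a], keys[b]
                cmp_ = compare.compare_with_null(
                    networks[ka], networks[kb],
                    n_realizations=config.null_realizations,
                    rng_seed=config.seed,
                )
                results[f"{ka[0]}:{ka[1]}|{kb[0]}:{kb[1]}"] = {
                    "jaccard": cmp_.jaccard,
                    "null_mean": cmp_.null_mean,
                    "null_std": cmp_.null_std,
                    "p_empirical": cmp_.p_empirical,
                    "p_label": cmp_.p_label,
                }
        return results

    summary["stages"]["comparisons"] = run_stage("compare", compare_all)

    # -- leave-one-out impact profile ------------------------------------
    if config.impact_cohort:
        cohort_key = _parse_cohort(config.impact_cohort)
        ref_key = (
            _parse_cohort(config.impact_reference)
            if config.impact_reference
            else None
        )

        def impact_stage():
            cohort = cohorts[cohort_key]
            reference = cohorts.get(ref_key) if ref_key else None
            profile = impact.impact_profile(
                cohort, reference, params,
                cohort_id=f"{cohort_key[0]}:{cohort_key[1]}",
            )
            profile.to_tsv(out / "impact_profile.tsv")
            return {
                "cohort": config.impact_cohort,
                "reference": config.impact_reference,
                "max_direct_impact_sample": str(profile.direct.idxmax()),
                "max_direct_impact": float(profile.direct.max()),
            }

        summary["stages"]["impact"] = run_stage("impact", impact_stage)

    # -- community baseline ----------------------------------------------
    def community_stage():
        dm = community.distance_matrix(rel)
        dm.to_frame().to_csv(out / "rjsd_distance_matrix.tsv", sep="\t")
        ord_ = community.pcoa(dm, n_axes=2)
        coords = ord_.coordinates.copy()
        coords.rename_axis("sample_id").to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        beta = {}
        for (group, tp), cohort in cohorts.items():
            if cohort.n_samples >= 2:
                vals = community.within_group_beta(rel, meta, group, tp)
                beta[f"{group}:{tp}"] = {
                    "n_pairs": len(vals),
                    "mean": float(np.mean(vals)),
                }
        pd.DataFrame(beta).T.rename_axis("cohort").to_csv(
            out / "beta_diversity.tsv", sep="\t"
        )
        return {
            "pcoa_explained": [float(v) for v in ord_.explained_fraction],
            "beta_diversity": beta,
        }

    summary["stages"]["community"] = run_stage("community", community_stage)

    summary["timings_s"] = timings
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("report written to %s", out / "report.json")
    return summary
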