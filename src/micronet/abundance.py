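"""Reading, validating, filtering and partitioning OTU abundance tables.

An :class:`AbundanceTable` stores a samples x OTUs matrix (counts or
relative abundances) together with sample and OTU identifiers.  Sample
metadata (group label and timepoint) lives in a plain pandas DataFrame so
it can be read from / written to TSV with the usual tools.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "GROUPS",
    "TIMEPOINTS",
    "read_abundance_table",
    "read_metadata",
    "filter_otus",
    "normalize_relative",
    "split_groups",
]

#: Recognised cohort labels.  ``gdm`` = gestational diabetes mellitus
#: patients, ``healthy`` = healthy pregnant controls.
GROUPS = ("healthy", "gdm")
#: Sampling timepoints: before (W0) and after (W2) the two-week interval.
TIMEPOINTS = ("W0", "W2")

_REL_TOL = 1e-9


class AbundanceValidationError(ValueError):
    """Raised when a table or metadata violates a structural invariant."""


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x OTUs abundance matrix with identifiers.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one column per OTU id.
        Entries must be non-negative and numeric.
    is_relative
        True once each row has been normalised to sum to 1.
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise AbundanceValidationError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise AbundanceValidationError(f"duplicate OTU ids: {dupes}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise AbundanceValidationError("non-numeric entries in abundance table")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise AbundanceValidationError(
                f"negative abundance at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
            )
        if self.is_relative and len(df):
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                bad = df.index[np.argmax(np.abs(sums - 1.0))]
                raise AbundanceValidationError(
                    f"relative table row {bad!r} sums to {sums.max():.6g}, not 1"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def otu_ids(self) -> list[str]:
        return [str(o) for o in self.data.columns]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise KeyError(f"samples not in table: {sorted(missing)}")
        return replace(self, data=self.data.loc[ids])

    def drop_sample(self, sample_id: str) -> "AbundanceTable":
        if sample_id not in self.data.index:
            raise KeyError(f"sample {sample_id!r} not in table")
        return replace(self, data=self.data.drop(index=sample_id))

    def to_tsv(self, path: str | Path, orientation: str = "otus_as_rows") -> None:
        df = self.data.T if orientation == "otus_as_rows" else self.data
        label = "otu_id" if orientation == "otus_as_rows" else "sample_id"
        df.rename_axis(label).to_csv(path, sep="\t")


def read_abundance_table(
    path: str | Path, orientation: str = "otus_as_rows"
) -> AbundanceTable:
    """Read a tab-separated count table.

    ``orientation='otus_as_rows'`` (the common amplicon-pipeline export:
    rows = OTUs, columns = samples) is transposed so the in-memory table is
    always samples x OTUs.  Counts are returned as given; ``is_relative``
    is False.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise AbundanceValidationError(f"empty abundance table: {path}") from exc
    if df.shape[1] == 0:
        raise AbundanceValidationError(f"no data columns in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = bad.index[0] if len(bad) else "?"
        raise AbundanceValidationError(
            f"non-numeric value in column {col!r}, row {where!r} of {path}"
        )
    if orientation == "otus_as_rows":
        df = df.T
    return AbundanceTable(data=df, is_relative=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, group, timepoint."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "timepoint"}
    missing = required - set(meta.columns)
    if missing:
        raise AbundanceValidationError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise AbundanceValidationError(f"duplicate metadata sample ids: {dupes}")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise AbundanceValidationError(
            f"unknown group labels {sorted(bad_group)}; expected {GROUPS}"
        )
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise AbundanceValidationError(
            f"unknown timepoints {sorted(bad_tp)}; expected {TIMEPOINTS}"
        )
    return meta


def filter_otus(
    table: AbundanceTable,
    min_total_count: float = 10,
    min_prevalence_fraction: float = 0.10,
) -> AbundanceTable:
    """Drop rare OTUs before network reconstruction.

    An OTU is kept iff its total count across all samples is at least
    ``min_total_count`` *and* it is detected (nonzero) in at least
    ``min_prevalence_fraction`` of the samples.  Operates on raw counts;
    OTU order is preserved and the sample set is unchanged.
    """
    if table.is_relative:
        raise AbundanceValidationError("filter_otus expects raw counts, not relative abundances")
    values = table.values
    totals = values.sum(axis=0)
    prevalence = (values > 0).mean(axis=0)
    keep = (totals >= min_total_count) & (prevalence >= min_prevalence_fraction)
    if not keep.any():
        raise AbundanceValidationError(
            "filtering removed all OTUs; lower min_total_count/min_prevalence_fraction"
        )
    return replace(table, data=table.data.loc[:, keep])


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample so its abundances sum to 1 (total-sum scaling)."""
    values = table.values
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        bad = table.data.index[int(np.argmax(sums <= 0))]
        raise AbundanceValidationError(f"sample {bad!r} has zero total abundance")
    rel = pd.DataFrame(
        values / sums[:, None], index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(data=rel, is_relative=True)


def split_groups(
    table: AbundanceTable, metadata: pd.DataFrame
) -> dict[tuple[str, str], AbundanceTable]:
    """Partition samples into the four (group, timepoint) cohorts.

    Every (group, timepoint) cell present in ``GROUPS`` x ``TIMEPOINTS``
    appears in the result (possibly with zero samples).  All outputs share
    the input's OTU list, so downstream group networks live on one node set.
    """
    meta = metadata.set_index("sample_id")
    missing = set(table.sample_ids) - set(meta.index)
    if missing:
        raise AbundanceValidationError(
            f"samples without metadata: {sorted(missing)}"
        )
    out: dict[tuple[str, str], AbundanceTable] = {}
    for group in GROUPS:
        for tp in TIMEPOINTS:
            ids = [
                s
                for s in table.sample_ids
                if meta.at[s, "group"] == group and meta.at[s, "timepoint"] == tp
            ]
            out[(group, tp)] = replace(table, data=table.data.loc[ids])
    return out
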