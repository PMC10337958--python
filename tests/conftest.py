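import itertools

import numpy as np
import pandas as pd
import pytest

from micronet.abundance import AbundanceTable
from micronet.network import CoAbundanceNetwork


@pytest.fixture
def toy_counts() -> AbundanceTable:
    """3 samples x 4 OTUs of integer counts."""
    data = pd.DataFrame(
        [[10, 0, 5, 1], [20, 3, 0, 2], [30, 6, 5, 3]],
        index=["s1", "s2", "s3"],
        columns=["otuA", "otuB", "otuC", "otuD"],
    )
    return AbundanceTable(data=data, is_relative=False)


@pytest.fixture
def toy_tsv(tmp_path, toy_counts):
    path = tmp_path / "counts.tsv"
    toy_counts.to_tsv(path, orientation="otus_as_rows")
    return path


@pytest.fixture
def four_group_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "group": ["healthy", "healthy", "gdm", "gdm"],
            "timepoint": ["W0", "W2", "W0", "W2"],
        }
    )


def make_relative(values, sample_prefix="s", otu_prefix="o") -> AbundanceTable:
    """Row-normalise a raw matrix into a relative AbundanceTable."""
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    n, p = values.shape
    data = pd.DataFrame(
        values,
        index=[f"{sample_prefix}{i}" for i in range(n)],
        columns=[f"{otu_prefix}{j}" for j in range(p)],
    )
    return AbundanceTable(data=data, is_relative=True)


def make_network(node_ids, edges, n_requested=None) -> CoAbundanceNetwork:
    """Build a network from explicit edges with placeholder attributes."""
    pairs = frozenset(tuple(sorted(e)) for e in edges)
    return CoAbundanceNetwork(
        node_ids=tuple(node_ids),
        edges=pairs,
        edge_attrs={p: (0.5, 2.0) for p in pairs},
        n_edges_requested=n_requested if n_requested is not None else max(len(pairs), 1),
    )


def all_edge_sets(node_ids):
    """Every subset of the possible edges on the given nodes."""
    pairs = list(itertools.combinations(sorted(node_ids), 2))
    for mask in range(1 << len(pairs)):
        yield frozenset(p for i, p in enumerate(pairs) if mask >> i & 1)
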