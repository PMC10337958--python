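import itertools

import numpy as np
import pandas as pd
import pytest

from micronet.abundance import AbundanceTable
from micronet.network import (
    network_size_sweep,
    pairwise_pearson,
    pairwise_statistics,
    read_edge_list,
    reconstruct_network,
    shuffle_null_for_pair,
    zscore,
)
from micronet.synthetic import (
    SyntheticCommunitySpec,
    block_planted_edges,
    edge_recovery,
    generate_cohort,
)

from conftest import make_relative


def _constant_first_otu_table():
    """o0 exactly constant across samples (no renormalization jitter)."""
    data = pd.DataFrame(
        [[0.2, 0.1, 0.7], [0.2, 0.3, 0.5], [0.2, 0.2, 0.6]],
        index=["s0", "s1", "s2"], columns=["o0", "o1", "o2"],
    )
    return AbundanceTable(data=data, is_relative=True)


class TestPairwisePearson:
    def test_perfect_correlation(self):
        table = make_relative([[0.1, 0.2], [0.2, 0.4], [0.3, 0.6]])
        r = pairwise_pearson(table)
        assert r[("o0", "o1")] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        # relative rows must sum to 1: embed the (0.1,0.2,0.3)/(0.3,0.2,0.1)
        # anti-correlated pair in a 3-OTU composition
        values = [[0.1, 0.3, 0.6], [0.2, 0.2, 0.6], [0.3, 0.1, 0.6]]
        table = make_relative(values)
        r = pairwise_pearson(table)
        assert r[("o0", "o1")] == pytest.approx(-1.0)

    def test_constant_otu_is_undefined(self):
        table = _constant_first_otu_table()
        r = pairwise_pearson(table)
        assert np.isnan(r[("o0", "o1")])
        assert np.isnan(r[("o0", "o2")])

    def test_too_few_samples(self):
        table = make_relative([[0.5, 0.5], [0.4, 0.6]])
        with pytest.raises(ValueError, match=">=3 samples"):
            pairwise_pearson(table)

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(1)
        table = make_relative(rng.random((8, 5)) + 0.01)
        r = pairwise_pearson(table)
        ref = np.corrcoef(table.values, rowvar=False)
        for (i, j) in itertools.combinations(range(5), 2):
            assert r[(f"o{i}", f"o{j}")] == pytest.approx(ref[i, j], abs=1e-12)


class TestShuffleNull:
    def test_exhaustive_permutation_oracle(self):
        """Monte-Carlo null moments match full enumeration on 5 samples."""
        x = np.array([0.1, 0.25, 0.05, 0.4, 0.2])
        y = np.array([0.3, 0.1, 0.2, 0.15, 0.25])
        # exhaustive: r over every relative arrangement of y against fixed x
        rs = [np.corrcoef(x, np.array(p))[0, 1]
              for p in itertools.permutations(y)]
        exact_mean, exact_std = np.mean(rs), np.std(rs)
        rows = np.column_stack([x, y, 1 - x - y])
        table = make_relative(rows)
        m, s = shuffle_null_for_pair(table, ("o0", "o1"), n_shuffles=4000,
                                     rng_seed=0)
        assert m == pytest.approx(exact_mean, abs=4 * exact_std / np.sqrt(4000))
        assert s == pytest.approx(exact_std, rel=0.05)

    def test_null_mean_near_zero_and_std_scaling(self):
        rng = np.random.default_rng(7)
        n = 30
        table = make_relative(rng.lognormal(0, 1, (n, 6)))
        m, s = shuffle_null_for_pair(table, ("o0", "o1"), n_shuffles=1000,
                                     rng_seed=3)
        assert abs(m) <= 3 * s / np.sqrt(1000)
        # classical permutation s.d. of Pearson r ~ 1/sqrt(n-1)
        assert s == pytest.approx(1 / np.sqrt(n - 1), rel=0.15)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        table = make_relative(rng.random((10, 4)) + 0.01)
        a = shuffle_null_for_pair(table, ("o1", "o2"), 200, rng_seed=9)
        b = shuffle_null_for_pair(table, ("o1", "o2"), 200, rng_seed=9)
        assert a == b

    def test_degenerate_pair_is_error(self):
        table = _constant_first_otu_table()
        with pytest.raises(ValueError, match="zero variance"):
            shuffle_null_for_pair(table, ("o0", "o1"), 100, 0)


class TestZscore:
    def test_arithmetic(self):
        assert zscore(0.8, 0.0, 0.2) == pytest.approx(4.0)
        assert zscore(0.3, 0.3, 0.1) == 0.0

    def test_zero_std_is_error(self):
        with pytest.raises(ValueError):
            zscore(0.5, 0.0, 0.0)


class TestReconstructNetwork:
    @pytest.fixture()
    def small_table(self):
        rng = np.random.default_rng(11)
        return make_relative(rng.lognormal(0, 1, (12, 8)))

    def test_combinatorial_ceiling_and_shortfall(self):
        rng = np.random.default_rng(5)
        table = make_relative(rng.lognormal(0, 1, (10, 3)))
        net = reconstruct_network(table, n_edges=500, w_threshold=-10,
                                  n_shuffles=100, rng_seed=0)
        assert net.n_edges <= 3
        assert net.shortfall == 500 - net.n_edges

    def test_deterministic_under_seed(self, small_table):
        a = reconstruct_network(small_table, 10, 1.0, 200, rng_seed=4)
        b = reconstruct_network(small_table, 10, 1.0, 200, rng_seed=4)
        assert a.edges == b.edges
        assert a.edge_attrs == b.edge_attrs

    def test_invariant_to_sample_and_otu_order(self, small_table):
        base = reconstruct_network(small_table, 10, 1.0, 300, rng_seed=8)
        rng = np.random.default_rng(0)
        data = small_table.data
        shuffled = data.iloc[rng.permutation(len(data)),
                             rng.permutation(data.shape[1])]
        table2 = AbundanceTable(data=shuffled, is_relative=True)
        perm = reconstruct_network(table2, 10, 1.0, 300, rng_seed=8)
        assert base.edges == perm.edges

    def test_edge_count_is_min_of_request_and_passing(self, small_table):
        stats = pairwise_statistics(small_table, 300, rng_seed=8)
        n_passing = int((stats["z_score"] >= 1.0).sum())
        for n_edges in (3, n_passing + 10):
            net = reconstruct_network(small_table, n_edges, 1.0, 300, rng_seed=8)
            assert net.n_edges == min(n_edges, n_passing)

    def test_w_filter_applied_before_ranking(self, small_table):
        net = reconstruct_network(small_table, 28, 1.0, 300, rng_seed=8)
        assert all(w >= 1.0 for _, w in net.edge_attrs.values())

    def test_planted_recovery_small(self):
        edges = block_planted_edges(20, 5, 2)
        spec = SyntheticCommunitySpec(n_samples=30, n_otus=20,
                                      planted_edges=edges, rho=0.9, seed=3)
        table, truth = generate_cohort(spec)
        rel = table.data.div(table.data.sum(axis=1), axis=0)
        rel_table = AbundanceTable(data=rel, is_relative=True)
        net = reconstruct_network(rel_table, n_edges=5, n_shuffles=300,
                                  rng_seed=21)
        assert edge_recovery(net, truth["planted_edges"])["recall"] >= 0.8

    def test_edge_list_roundtrip(self, small_table, tmp_path):
        net = reconstruct_network(small_table, 10, 1.0, 200, rng_seed=4)
        path = tmp_path / "edges.tsv"
        net.to_tsv(path)
        loaded = read_edge_list(path, node_ids=net.node_ids,
                                n_edges_requested=net.n_edges_requested)
        assert loaded.edges == net.edges

    def test_nonpositive_n_edges_is_error(self, small_table):
        with pytest.raises(ValueError):
            reconstruct_network(small_table, 0, 1.0, 100, 0)


class TestNetworkSizeSweep:
    def test_monotone_and_extremes(self):
        rng = np.random.default_rng(13)
        table = make_relative(rng.lognormal(0, 1, (15, 8)))
        counts = network_size_sweep(table, [-np.inf, 0.0, 1.0, 2.0, np.inf],
                                    n_shuffles=200, rng_seed=1)
        values = [counts[t] for t in sorted(counts)]
        assert values[0] == 28  # all defined pairs on 8 OTUs
        assert counts[np.inf] == 0
        assert all(a >= b for a, b in zip(values, values[1:]))


def test_w_calibration_on_balanced_compositions():
    """When the independence premise of the Z-score holds — near-symmetric
    abundances of comparable magnitude, so compositional closure is
    negligible — the W >= 2 tail matches the standard-normal mass 0.0228
    within binomial 99% bounds.  (Heavy-tailed, dominance-structured
    compositions genuinely violate the premise; see docs/methods.md.)"""
    from scipy import stats

    rng = np.random.default_rng(123)
    n, p = 30, 100
    values = np.abs(rng.normal(5, 1, (n, p)))
    table = make_relative(values, otu_prefix="O")
    statistics = pairwise_statistics(table, n_shuffles=1000, rng_seed=77)
    frac = float((statistics["z_score"] >= 2).mean())
    p0 = 1 - stats.norm.cdf(2)
    lo, hi = stats.binom.ppf([0.005, 0.995], len(statistics), p0) / len(statistics)
    assert lo <= frac <= hi
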