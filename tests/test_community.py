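import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micronet.community import (
    DistanceMatrix,
    bonferroni,
    differential_abundance,
    distance_matrix,
    mean_distance_to_reference,
    pcoa,
    rank_sum_test,
    rjsd,
    within_group_beta,
)

from conftest import make_relative


class TestRjsd:
    def test_identity(self):
        x = np.array([0.2, 0.3, 0.5])
        assert rjsd(x, x) == 0.0

    def test_hand_computed_value(self):
        # direct evaluation with base-2 logs: JSD = 0.048795, sqrt = 0.220897
        v = rjsd(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        assert v == pytest.approx(0.2208957688, abs=1e-6)

    def test_against_direct_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.dirichlet(np.ones(6))
            y = rng.dirichlet(np.ones(6))
            m = (x + y) / 2
            kl = lambda a, b: np.sum(a * np.log2(a / b))
            expected = np.sqrt((kl(x, m) + kl(y, m)) / 2)
            assert rjsd(x, y) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.dirichlet(np.ones(5))
        y = rng.dirichlet(np.ones(5))
        assert rjsd(x, y) == pytest.approx(rjsd(y, x), abs=1e-12)
        assert 0.0 <= rjsd(x, y) <= 1.0

    def test_shared_support_renormalization(self):
        # OTU 3 present only in x: shared support is the first two OTUs,
        # renormalised to (0.5, 0.5) vs (0.25, 0.75)
        x = np.array([0.25, 0.25, 0.5, 0.0])
        y = np.array([0.25, 0.75, 0.0, 0.0])
        assert rjsd(x, y) == pytest.approx(0.2208957688, abs=1e-6)

    def test_union_support_variant_differs(self):
        x = np.array([0.25, 0.25, 0.5])
        y = np.array([0.25, 0.75, 0.0])
        assert rjsd(x, y, shared_support=False) > rjsd(x, y)

    def test_empty_shared_support_is_error(self):
        with pytest.raises(ValueError, match="shared"):
            rjsd(np.array([1.0, 0.0]), np.array([0.0, 1.0]))


class TestDistanceMatrix:
    def test_matches_scalar_calls(self):
        rng = np.random.default_rng(1)
        table = make_relative(rng.lognormal(0, 1, (3, 5)))
        dm = distance_matrix(table)
        values = table.values
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else rjsd(values[i], values[j])
                assert dm.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_sample_has_zero_distance(self):
        values = np.array([[0.2, 0.8], [0.2, 0.8], [0.5, 0.5]])
        dm = distance_matrix(make_relative(values))
        assert dm.d[0, 1] == 0.0
        assert dm.d[0, 2] > 0.0

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=("a", "b"),
                           d=np.array([[0.0, 0.1], [0.2, 0.0]]))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        table = make_relative(rng.lognormal(0, 1, (5, 4)))
        dm = distance_matrix(table)
        perm = rng.permutation(5)
        from micronet.abundance import AbundanceTable

        shuffled = AbundanceTable(data=table.data.iloc[perm],
                                  is_relative=True)
        dm2 = distance_matrix(shuffled)
        np.testing.assert_allclose(dm2.d, dm.d[np.ix_(perm, perm)])


class TestGroupDistances:
    def test_within_group_count_and_values(self, four_group_metadata):
        rng = np.random.default_rng(3)
        meta = four_group_metadata.assign(group="healthy", timepoint="W0")
        table = make_relative(rng.lognormal(0, 1, (4, 5)), sample_prefix="s")
        table.data.index = ["s1", "s2", "s3", "s4"]
        vals = within_group_beta(table, meta, "healthy", "W0")
        assert len(vals) == 6  # C(4,2)

    def test_group_of_identical_samples(self, four_group_metadata):
        meta = four_group_metadata.assign(group="gdm", timepoint="W2")
        values = np.tile([0.1, 0.9], (4, 1))
        table = make_relative(values)
        table.data.index = ["s1", "s2", "s3", "s4"]
        assert within_group_beta(table, meta, "gdm", "W2") == [0.0] * 6

    def test_single_sample_group_is_error(self, four_group_metadata):
        table = make_relative(np.random.default_rng(0).random((4, 3)) + 0.1)
        table.data.index = ["s1", "s2", "s3", "s4"]
        with pytest.raises(ValueError, match="fewer than 2"):
            within_group_beta(table, four_group_metadata, "healthy", "W0")

    def test_mean_distance_to_reference(self):
        rng = np.random.default_rng(4)
        reference = make_relative(rng.lognormal(0, 1, (4, 5)))
        sample = reference.values[0]
        expected = np.mean([rjsd(sample, reference.values[i])
                            for i in range(4)])
        assert mean_distance_to_reference(sample, reference) == pytest.approx(
            expected)
        singleton = make_relative(reference.values[1][None, :])
        assert mean_distance_to_reference(
            sample, singleton) == pytest.approx(rjsd(sample,
                                                     reference.values[1]))


class TestPcoa:
    def test_three_equidistant_points(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(ids=("a", "b", "c"), d=d), n_axes=2)
        np.testing.assert_allclose(res.explained_fraction, [0.5, 0.5],
                                   atol=1e-12)

    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(ids=("a", "b", "c"), d=d), n_axes=1)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_euclidean_roundtrip(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(ids=tuple(f"s{i}" for i in range(6)), d=d)
        res = pcoa(dm, n_axes=3)
        coords = res.coordinates.to_numpy()
        rebuilt = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(rebuilt, d, atol=1e-8)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(6)
        table = make_relative(rng.lognormal(0, 1, (7, 5)))
        dm = distance_matrix(table)
        res = pcoa(dm, n_axes=2)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.d, ids=list(dm.ids))
        )
        for axis in range(2):
            mine = res.coordinates.iloc[:, axis].to_numpy()
            theirs = ref.samples.iloc[:, axis].to_numpy()
            sign = np.sign(mine @ theirs) or 1.0
            np.testing.assert_allclose(mine, sign * theirs, atol=1e-8)

    def test_excess_axes_warns_and_truncates(self):
        x = np.array([0.0, 1.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        with pytest.warns(RuntimeWarning, match="positive eigenvalues"):
            res = pcoa(DistanceMatrix(ids=("a", "b", "c"), d=d), n_axes=3)
        assert res.n_axes == 1


class TestRankTests:
    def test_identical_samples_large_p(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) > 0.9

    def test_fully_separated_small_p(self):
        a = list(range(10))
        b = list(range(100, 110))
        # exact rank-sum enumeration: p = 2 / C(20, 10)
        assert rank_sum_test(a, b, method="exact") == pytest.approx(
            2 / 184756, rel=1e-6)
        assert rank_sum_test(a, b) < 0.001

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        p1 = rank_sum_test(a, b)
        p2 = rank_sum_test(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_all_tied_gives_one(self):
        assert rank_sum_test([2, 2], [2, 2, 2]) == 1.0

    def test_bonferroni(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.4, 0.9]),
                                   [0.03, 1.0, 1.0])

    def test_differential_abundance_screen(self, four_group_metadata):
        rng = np.random.default_rng(8)
        values = rng.lognormal(0, 0.2, (4, 3))
        table = make_relative(values)
        table.data.index = ["s1", "s2", "s3", "s4"]
        res = differential_abundance(table, four_group_metadata,
                                     ("healthy", "W0"), ("gdm", "W0"))
        assert list(res.columns) == ["p_value", "p_bonferroni"]
        assert (res["p_bonferroni"] >= res["p_value"]).all()
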