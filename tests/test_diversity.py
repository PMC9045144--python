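import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from cstnet import diversity
from cstnet.io import AbundanceTable


def _table(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    ids = [f"{prefix}{i}" for i in range(values.shape[0])]
    cols = [f"sp{j}" for j in range(values.shape[1])]
    return AbundanceTable(pd.DataFrame(values, index=ids, columns=cols))


class TestSpeciesRichness:
    @pytest.mark.parametrize(
        "profile, threshold, expected",
        [
            ([0.6, 0.3, 0.004, 0.096], 0.005, 3),
            ([1, 0, 0], 0.005, 1),
            ([0.01] * 100, 0.005, 100),
        ],
    )
    def test_counts_species_strictly_above_threshold(self, profile, threshold, expected):
        assert diversity.species_richness(profile, threshold) == expected

    def test_threshold_must_be_a_fraction(self):
        with pytest.raises(ValueError):
            diversity.species_richness([1.0], threshold=1.5)

    def test_per_sample_richness_matches_scalar(self, tiny_table):
        per = diversity.richness_per_sample(tiny_table, 0.15)
        expected = [diversity.species_richness(row, 0.15) for row in tiny_table.values]
        assert list(per) == expected


class TestBrayCurtis:
    def test_identical_profiles_have_zero_dissimilarity(self):
        p = [0.2, 0.3, 0.5]
        assert diversity.bray_curtis(p, p) == pytest.approx(0.0)

    def test_disjoint_supports_have_dissimilarity_one(self):
        assert diversity.bray_curtis([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_half_overlap(self):
        assert diversity.bray_curtis([0.5, 0.5, 0], [0, 0.5, 0.5]) == pytest.approx(0.5)

    def test_mismatched_species_sets_rejected(self):
        with pytest.raises(ValueError):
            diversity.bray_curtis([0.5, 0.5], [0.2, 0.3, 0.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_properties_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(12))
        q = rng.dirichlet(np.ones(12))
        d_pq = diversity.bray_curtis(p, q)
        assert 0.0 <= d_pq <= 1.0
        assert d_pq == pytest.approx(diversity.bray_curtis(q, p))
        assert d_pq == pytest.approx(1.0 - np.minimum(p, q).sum())
        assert diversity.bray_curtis(p, p) == pytest.approx(0.0, abs=1e-12)


class TestDistanceMatrix:
    def test_identical_samples_have_zero_offdiagonal(self):
        table = _table([[0.3, 0.7], [0.3, 0.7]])
        for metric in ("bray_curtis", "pearson"):
            dm = diversity.distance_matrix(table, metric)
            assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_reach_pearson_distance_two(self):
        table = _table([[0.6, 0.3, 0.1], [0.1, 0.4, 0.5]])
        # second profile chosen anti-correlated with the first
        r = np.corrcoef(table.values)[0, 1]
        dm = diversity.distance_matrix(table, "pearson")
        assert dm.data[0, 1] == pytest.approx(1 - r)
        v0 = np.array([0.1, 0.3, 0.2])
        v1 = 1.0 - 2 * v0  # affine in v0 with negative slope: correlation exactly -1
        v = np.vstack([v0 / v0.sum(), v1 / v1.sum()])
        dm2 = diversity.distance_matrix(_table(v), "pearson")
        assert dm2.data[0, 1] == pytest.approx(2.0)

    def test_matrix_matches_per_pair_oracle(self):
        rng = np.random.default_rng(1)
        table = _table(rng.dirichlet(np.ones(8), size=3))
        dm = diversity.distance_matrix(table, "bray_curtis")
        for i, j in itertools.combinations(range(3), 2):
            expected = diversity.bray_curtis(table.values[i], table.values[j])
            assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_sample_rejected_under_pearson(self):
        table = _table([[0.5, 0.5], [0.3, 0.7]])
        with pytest.raises(ValueError, match="s0"):
            diversity.distance_matrix(table, "pearson")


class TestPcoa:
    def test_collinear_three_points(self):
        dm = DistanceMatrix(
            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float), ids=list("abc")
        )
        res = diversity.pcoa(dm, 1)
        assert res.eigenvalues[0] == pytest.approx(2.0)
        coords = res.coordinates.iloc[:, 0].to_numpy()
        assert np.allclose(np.abs(coords), [1, 0, 1], atol=1e-8)
        assert coords[0] * coords[2] < 0

    def test_all_zero_distances_give_zero_coordinates(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = diversity.pcoa(dm, 2)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_input_is_reconstructed(self):
        rng = np.random.default_rng(2)
        points = rng.random((6, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(points))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        res = diversity.pcoa(dm, 3)
        recon = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(recon - d).max() < 1e-8

    def test_axes_are_centered_and_match_skbio(self):
        rng = np.random.default_rng(3)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(rng.random((8, 4))))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(8)])
        res = diversity.pcoa(dm, 3)
        assert np.abs(res.coordinates.sum(axis=0)).max() < 1e-8
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(res.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :3]),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            res.eigenvalues, ref.eigvals.to_numpy()[:3], atol=1e-8
        )


def _clustered_distance(seed=4, n_per=4):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 1, (n_per, 2)), rng.normal(5, 1, (n_per, 2))])
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(2 * n_per)])


class TestPermanova:
    def test_statistic_matches_skbio(self):
        dm = _clustered_distance()
        labels = np.array(["a"] * 4 + ["b"] * 4)
        ours = diversity.permanova(dm, labels, n_perm=99, seed=0)
        ref = skbio_permanova(dm, labels.tolist(), permutations=99)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_all_equal_distances_give_high_p(self):
        n = 8
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(n)])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        res = diversity.permanova(dm, labels, n_perm=199, seed=0)
        assert res.p_value > 0.9

    def test_exhaustive_matches_independent_enumeration(self):
        dm = _clustered_distance(seed=5, n_per=3)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = diversity.permanova(dm, labels, method="exhaustive")

        def f_oracle(d, lab):
            n = len(lab)
            d2 = np.asarray(d) ** 2
            sst = d2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for g in set(lab):
                idx = [i for i in range(n) if lab[i] == g]
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            a = len(set(lab))
            return ((sst - ssw) / (a - 1)) / (ssw / (n - a))

        f_obs = f_oracle(dm.data, list(labels))
        fs = [f_oracle(dm.data, list(p)) for p in set(itertools.permutations(labels))]
        p_expected = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        assert res.pseudo_F == pytest.approx(f_obs)
        assert res.p_value == pytest.approx(p_expected)
        mc = diversity.permanova(dm, labels, n_perm=4999, seed=0)
        assert mc.p_value == pytest.approx(p_expected, abs=0.05)

    def test_small_group_rejected(self):
        dm = _clustered_distance()
        labels = np.array(["a"] * 7 + ["b"])
        with pytest.raises(ValueError):
            diversity.permanova(dm, labels, n_perm=9, seed=0)

    def test_reordering_equivariance(self):
        dm = _clustered_distance(seed=6)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        perm = np.random.default_rng(7).permutation(8)
        d_perm = np.asarray(dm.data)[np.ix_(perm, perm)]
        dm2 = DistanceMatrix(d_perm, ids=[str(i) for i in range(8)])
        r1 = diversity.permanova(dm, labels, n_perm=499, seed=11)
        r2 = diversity.permanova(dm2, labels[perm], n_perm=499, seed=11)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, rel=1e-10)
        # same seed-induced permutation set on relabeled indices: p within MC noise
        assert abs(r1.p_value - r2.p_value) < 0.05

    def test_stratified_permutation_stays_within_strata(self):
        dm = _clustered_distance(seed=8)
        labels = np.array(["a", "a", "b", "b"] * 2)
        strata = np.array(["x"] * 4 + ["y"] * 4)
        res = diversity.permanova(dm, labels, n_perm=99, seed=3, strata=strata)
        assert 0 < res.p_value <= 1
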