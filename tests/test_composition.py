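"""Assemblage distances, ordination, clustering, and the flight contrast."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from resintrap.composition import (
    DistanceMatrix,
    bhattacharyya_distance,
    classical_mds,
    contingency_test,
    distance_matrix,
    flying_contingency,
    hierarchical_cluster,
    normalize_profiles,
)
from resintrap.data_model import TaxonCountMatrix, ValidationError


def dmat(ids, d):
    return DistanceMatrix(ids=ids, d=np.asarray(d, float), metric_name="test")


class TestProfiles:
    @pytest.mark.parametrize("counts,pc,expected", [
        ([3, 1], 0.0, [0.75, 0.25]),
        ([0, 0], 0.5, [0.5, 0.5]),
        ([9, 1], 0.5, [9.5 / 11, 1.5 / 11]),
    ])
    def test_normalization_with_pseudocount(self, counts, pc, expected):
        m = TaxonCountMatrix(["s"], [f"t{i}" for i in range(len(counts))], np.array([counts]))
        np.testing.assert_allclose(normalize_profiles(m, pseudocount=pc)[0], expected, rtol=1e-12)

    def test_rows_sum_to_one(self, tiny_matrix):
        prof = normalize_profiles(tiny_matrix)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_taxon_set_rejected(self):
        m = TaxonCountMatrix(["s"], [], np.zeros((1, 0)))
        with pytest.raises(ValidationError):
            normalize_profiles(m)


class TestBhattacharyya:
    def test_hand_computed_example(self):
        """BC = sqrt(0.45) + sqrt(0.05) -> D = -ln BC = 0.111572."""
        d = bhattacharyya_distance([0.5, 0.5], [0.9, 0.1])
        assert d == pytest.approx(0.111572, abs=1e-6)

    def test_identity_and_symmetry(self):
        p = np.array([0.2, 0.3, 0.5])
        q = np.array([0.6, 0.1, 0.3])
        assert bhattacharyya_distance(p, p) == pytest.approx(0.0, abs=1e-12)
        assert bhattacharyya_distance(p, q) == bhattacharyya_distance(q, p) > 0

    def test_disjoint_supports_capped(self):
        assert bhattacharyya_distance([1.0, 0.0], [0.0, 1.0]) == 50.0

    def test_mismatched_taxon_sets_rejected(self):
        with pytest.raises(ValidationError):
            bhattacharyya_distance([0.5, 0.5], [1.0])


class TestDistanceMatrix:
    def test_identical_samples_give_zero_matrix(self):
        m = TaxonCountMatrix(["a", "b"], ["t1", "t2"], np.array([[3, 1], [3, 1]]))
        D = distance_matrix(m, metric="bhattacharyya")
        np.testing.assert_allclose(D.d, 0.0, atol=1e-12)

    def test_pairwise_entries_recomputable_independently(self, tiny_matrix):
        m = TaxonCountMatrix(
            ["a", "b", "c"], ["t1", "t2", "t3"],
            np.array([[3, 1, 0], [0, 2, 4], [1, 1, 1]]),
        )
        D = distance_matrix(m, metric="bhattacharyya", pseudocount=0.5)
        prof = normalize_profiles(m, pseudocount=0.5)
        for i in range(3):
            for j in range(3):
                expect = 0.0 if i == j else bhattacharyya_distance(prof[i], prof[j])
                assert D.d[i, j] == pytest.approx(expect, abs=1e-12)

    def test_reversed_ranks_give_spearman_distance_two(self):
        m = TaxonCountMatrix(["a", "b"], list("vwxyz"),
                             np.array([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]]))
        D = distance_matrix(m, metric="one_minus_spearman")
        assert D.d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_spearman_invariant_under_monotone_rescaling(self):
        base = np.array([3, 7, 1, 9, 5])
        m = TaxonCountMatrix(["a", "b"], list("vwxyz"), np.array([base, base * 10]))
        D = distance_matrix(m, metric="one_minus_spearman")
        assert D.d[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestClassicalMDS:
    def test_equilateral_triangle(self):
        """Unit triangle: embedded distances 1.0, variance split (1/2, 1/2)."""
        D = dmat(list("ABC"), [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        res = classical_mds(D, k=2)
        np.testing.assert_allclose(pdist(res.coordinates), 1.0, atol=1e-9)
        np.testing.assert_allclose(res.variance_explained, [0.5, 0.5], atol=1e-12)

    def test_collinear_points_have_one_positive_axis(self):
        n = 4
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        res = classical_mds(dmat(list("ABCD"), d), k=2)
        assert res.axes_truncated
        np.testing.assert_allclose(res.variance_explained, [1.0], atol=1e-9)
        np.testing.assert_allclose(pdist(res.coordinates), pdist(res.coordinates[:, :1]), atol=1e-9)

    def test_all_zero_distances_give_zero_coordinates(self):
        res = classical_mds(dmat(list("ABC"), np.zeros((3, 3))), k=2)
        np.testing.assert_allclose(res.coordinates, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_euclidean_configuration_recovered_up_to_rotation(self):
        """True 3-D point distances: reproduced within 1e-9 and recoverable
        by orthogonal Procrustes."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 3))
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        res = classical_mds(dmat([str(i) for i in range(7)], d), k=3)
        np.testing.assert_allclose(pdist(res.coordinates), pdist(X), atol=1e-9)
        Xc = X - X.mean(0)
        from scipy.linalg import orthogonal_procrustes

        R, _ = orthogonal_procrustes(res.coordinates, Xc)
        assert np.abs(res.coordinates @ R - Xc).max() < 1e-8

    def test_agrees_with_reference_pcoa(self):
        """Independent cross-check against scikit-bio's principal
        coordinate analysis on a non-Euclidean assemblage distance matrix."""
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix as SkbioDM

        m = TaxonCountMatrix(
            [f"s{i}" for i in range(5)], [f"t{j}" for j in range(4)],
            np.array([[5, 1, 0, 2], [4, 2, 1, 1], [0, 6, 3, 0], [1, 5, 2, 1], [2, 2, 2, 2]]),
        )
        D = distance_matrix(m, metric="bhattacharyya")
        ours = classical_mds(D, k=2)
        ref = skbio_pcoa(SkbioDM(D.d, ids=D.ids), number_of_dimensions=2)
        np.testing.assert_allclose(
            np.abs(ours.coordinates), np.abs(ref.samples.to_numpy()), atol=1e-8
        )
        np.testing.assert_allclose(ours.eigenvalues[:2], ref.eigvals.to_numpy(), atol=1e-10)
        # skbio normalizes by the sum of all eigenvalues; our per-axis
        # variance uses positive eigenvalues only — same ordering either way
        assert ours.variance_explained[0] > ours.variance_explained[1]

    def test_k_out_of_range_rejected(self):
        D = dmat(list("AB"), [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            classical_mds(D, k=2)


class TestClustering:
    def test_three_point_worked_example(self):
        """d(A,B)=1, d(A,C)=d(B,C)=5: merge (A,B) at 1, then C at 5."""
        D = dmat(list("ABC"), [[0, 1, 5], [1, 0, 5], [5, 5, 0]])
        dend = hierarchical_cluster(D)
        assert dend.merges == [(0, 1, 1.0), (2, 3, 5.0)]
        assert dend.to_newick().endswith(";")
        assert "A" in dend.to_newick() and "C" in dend.to_newick()

    def test_two_samples_single_merge(self):
        dend = hierarchical_cluster(dmat(list("AB"), [[0, 3.5], [3.5, 0]]))
        assert dend.merges == [(0, 1, 3.5)]

    def test_duplicate_samples_merge_at_zero_first(self):
        D = dmat(list("ABC"), [[0, 0, 2], [0, 0, 2], [2, 2, 0]])
        dend = hierarchical_cluster(D)
        assert dend.merges[0][2] == 0.0

    def test_complete_linkage_heights_monotone(self):
        rng = np.random.default_rng(3)
        X = rng.random((8, 4))
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        dend = hierarchical_cluster(dmat([str(i) for i in range(8)], d))
        heights = [h for _, _, h in dend.merges]
        assert heights == sorted(heights)

    def test_complete_linkage_height_is_max_pairwise(self):
        D = dmat(list("ABC"), [[0, 1, 2], [1, 0, 4], [2, 4, 0]])
        dend = hierarchical_cluster(D)
        # (A,B) merge at 1; C joins at max(d(A,C), d(B,C)) = 4
        assert dend.merges[1][2] == pytest.approx(4.0)


class TestContingency:
    def test_hand_computed_chi_square(self):
        res = contingency_test([[10, 20], [20, 10]])
        assert res.chi2 == pytest.approx(20 / 3, abs=1e-9)
        assert res.df == 1
        np.testing.assert_allclose(
            res.std_residuals, (res.table - res.expected) / np.sqrt(res.expected)
        )

    def test_identical_rows_give_zero_statistic(self):
        res = contingency_test([[5, 5], [5, 5]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_invariant_under_row_and_column_swaps(self):
        t = np.array([[10, 20, 5], [20, 10, 5]])
        base = contingency_test(t).chi2
        assert contingency_test(t[::-1]).chi2 == pytest.approx(base)
        assert contingency_test(t[:, ::-1]).chi2 == pytest.approx(base)

    def test_monte_carlo_p_agrees_with_asymptotic(self):
        res = contingency_test([[30, 60], [60, 30]], monte_carlo=2000, seed=1)
        assert res.p_value_mc == pytest.approx(res.p_value, abs=0.02)

    def test_flying_aggregation_and_exclusions(self):
        m = TaxonCountMatrix(
            ["resin", "sticky"],
            ["Diptera", "Formicidae", "Acari", "Collembola"],
            np.array([[2, 10, 30, 8], [40, 2, 5, 1]]),
        )
        res = flying_contingency(m)
        # Acari excluded; flying = Diptera, non-flying = Formicidae + Collembola
        np.testing.assert_array_equal(res.table, [[2, 18], [40, 3]])

    def test_unclassified_taxon_is_configuration_error(self):
        m = TaxonCountMatrix(["a", "b"], ["Mystery"], np.array([[1], [2]]))
        with pytest.raises(KeyError):
            flying_contingency(m)
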