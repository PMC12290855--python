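"""Similarity matrices, hierarchical clustering, matching, stability."""
import itertools

import numpy as np
import pytest

from cordmap import parcellation as parc
from cordmap.errors import ContractError
from cordmap.types import LabelMap
from tests.conftest import make_bold


def _random_similarity(n, rng):
    A = rng.normal(size=(n, n + 4))
    S = np.corrcoef(A)
    np.fill_diagonal(S, 1.0)
    return parc.SimilarityMatrix(S)


class TestFeatureMatrix:
    def test_identical_series_hits_clamp_ceiling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        cord = make_bold(x.reshape(1, 1, 1, 40), organ="cord")
        brain = make_bold(np.stack([x, rng.normal(size=40)]).reshape(2, 1, 1, 40))
        fm = parc.fc_feature_matrix(cord, brain, np.ones((1, 1, 1), bool),
                                    np.ones((2, 1, 1), bool))
        assert fm.Z[0, 0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_shape_contract(self):
        rng = np.random.default_rng(1)
        cord = make_bold(rng.normal(size=(2, 2, 1, 30)), organ="cord")
        brain = make_bold(rng.normal(size=(3, 2, 1, 30)))
        cmask = np.zeros((2, 2, 1), bool)
        cmask[:, 0, 0] = True
        smask = np.ones((3, 2, 1), bool)
        fm = parc.fc_feature_matrix(cord, brain, cmask, smask)
        assert fm.Z.shape == (2, 6)

    def test_independent_series_near_zero_mean(self):
        rng = np.random.default_rng(2)
        n = 230
        cord = make_bold(rng.normal(size=(5, 4, 1, n)), organ="cord")
        brain = make_bold(rng.normal(size=(10, 10, 1, n)))
        fm = parc.fc_feature_matrix(cord, brain, np.ones((5, 4, 1), bool),
                                    np.ones((10, 10, 1), bool))
        assert abs(fm.Z.mean()) < 0.02


class TestSimilarity:
    def test_identical_rows_give_one(self):
        Z = np.tile(np.random.default_rng(0).normal(size=8), (2, 1))
        S = parc.similarity_from_features(Z)
        assert S.S[0, 1] == pytest.approx(1.0)

    def test_negated_row_gives_minus_one(self):
        row = np.random.default_rng(1).normal(size=8)
        S = parc.similarity_from_features(np.vstack([row, -row]))
        assert S.S[0, 1] == pytest.approx(-1.0)

    def test_matches_naive_double_loop_pearson(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(10, 6))
        S = parc.similarity_from_features(Z).S
        expected = np.eye(10)
        for i, k in itertools.combinations(range(10), 2):
            zi, zk = Z[i] - Z[i].mean(), Z[k] - Z[k].mean()
            r = (zi @ zk) / np.sqrt((zi**2).sum() * (zk**2).sum())
            expected[i, k] = expected[k, i] = r
        assert np.abs(S - expected).max() <= 1e-12

    def test_invariant_to_common_affine_rescaling_of_columns(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(7, 9))
        S1 = parc.similarity_from_features(Z).S
        S2 = parc.similarity_from_features(3.5 * Z + 2.0).S
        np.testing.assert_allclose(S1, S2, atol=1e-12)

    def test_zero_variance_row_flagged(self):
        Z = np.vstack([np.zeros(5), np.random.default_rng(4).normal(size=5)])
        S = parc.similarity_from_features(Z)
        assert 0 in S.degenerate_rows
        assert S.S[0, 1] == 0.0


class TestGroupMeanSimilarity:
    def test_single_subject_identity(self):
        S = _random_similarity(6, np.random.default_rng(0))
        out = parc.group_mean_similarity([S])
        np.testing.assert_allclose(out.S, S.S, atol=1e-12)

    def test_permutation_invariance_and_range(self):
        rng = np.random.default_rng(1)
        mats = [_random_similarity(6, rng) for _ in range(4)]
        a = parc.group_mean_similarity(mats).S
        b = parc.group_mean_similarity(mats[::-1]).S
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert a.max() <= 1.0 + 1e-12 and a.min() >= -1.0 - 1e-12


def _naive_average_linkage(D):
    """O(n^3) agglomeration oracle: merge the closest pair under average
    linkage, lexicographic tie-break; returns merge heights and the
    partition sequence."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    partitions = [dict(clusters)]
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
        partitions.append({k: list(v) for k, v in clusters.items()})
    return heights, partitions


def _labels_from_partition(partition, n):
    labels = np.empty(n, int)
    for new, key in enumerate(sorted(partition), start=1):
        labels[partition[key]] = new
    return labels


class TestHierarchicalCluster:
    def test_two_planted_blocks_recovered(self):
        n = 12
        S = np.full((n, n), 0.1)
        S[:6, :6] = 0.9
        S[6:, 6:] = 0.9
        np.fill_diagonal(S, 1.0)
        sol = parc.hierarchical_cluster(parc.SimilarityMatrix(S), (2,))
        labels = sol.labels[2]
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_k_equals_n_gives_singletons(self):
        S = _random_similarity(5, np.random.default_rng(0))
        sol = parc.hierarchical_cluster(S, (5,))
        assert sorted(sol.labels[5]) == [1, 2, 3, 4, 5]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_agglomeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        S = _random_similarity(8, rng)
        D = 1.0 - S.S
        np.fill_diagonal(D, 0.0)
        heights, partitions = _naive_average_linkage(D)
        sol = parc.hierarchical_cluster(S, tuple(range(1, 9)))
        np.testing.assert_allclose(sorted(sol.linkage_matrix[:, 2]),
                                   sorted(heights), atol=1e-12)
        for k in range(1, 9):
            oracle = _labels_from_partition(partitions[8 - k], 8)
            mine = sol.labels[k]
            # compare partitions up to relabelling
            assert len(set(zip(oracle, mine))) == k

    def test_k_out_of_range(self):
        S = _random_similarity(4, np.random.default_rng(1))
        with pytest.raises(ContractError):
            parc.hierarchical_cluster(S, (5,))


class TestDice:
    def test_arithmetic_cases(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4] = True
        b[1:7] = True  # |a|=4, |b|=6, overlap 3
        assert parc.dice(a, b) == pytest.approx(0.6)
        assert parc.dice(a, a) == 1.0
        assert parc.dice(a, ~a) == 0.0
        assert parc.dice(np.zeros(5, bool), np.zeros(5, bool)) == 0.0

    def test_symmetric_and_identity_iff_equal(self):
        rng = np.random.default_rng(2)
        a = rng.random(30) > 0.5
        b = rng.random(30) > 0.5
        assert parc.dice(a, b) == parc.dice(b, a)
        if not np.array_equal(a, b):
            assert parc.dice(a, b) < 1.0


class TestMaxWeightMatching:
    def test_identity_when_equal(self):
        labels = np.random.default_rng(0).integers(1, 5, size=(6, 6, 1))
        lm = LabelMap(labels)
        report = parc.match_labels_max_weight(lm, lm)
        assert all(k == v for k, v in report.mapping.items())
        assert report.mean_dice == 1.0 and report.sd_dice == 0.0

    def test_recovers_permutation(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 6, size=(8, 8, 1))
        perm = {1: 3, 2: 5, 3: 1, 4: 2, 5: 4}
        inverse = {v: k for k, v in perm.items()}
        permuted = np.vectorize(perm.get)(labels)
        report = parc.match_labels_max_weight(LabelMap(permuted), LabelMap(labels))
        assert report.mapping == inverse
        assert report.mean_dice == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search(self, seed):
        # oracle: all 7! injective assignments of random weights
        rng = np.random.default_rng(seed)
        W = rng.random((7, 7))
        best = max(
            (sum(W[i, p[i]] for i in range(7)), p)
            for p in itertools.permutations(range(7))
        )
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-W)
        assert W[rows, cols].sum() == pytest.approx(best[0], abs=1e-12)

    def test_total_weight_at_least_identity(self):
        rng = np.random.default_rng(3)
        a = LabelMap(rng.integers(1, 8, size=(10, 10, 1)))
        b = LabelMap(rng.integers(1, 8, size=(10, 10, 1)))
        report = parc.match_labels_max_weight(a, b)
        identity = sum(parc.dice(a.data == k, b.data == k) for k in range(1, 8))
        assert report.total_weight >= identity - 1e-12


class TestStability:
    def test_identical_subjects_give_unit_stability(self):
        S = _random_similarity(8, np.random.default_rng(0))
        stability, grand = parc.intersubject_profile_stability([S, S, S])
        np.testing.assert_allclose(stability, 1.0, atol=1e-10)
        assert grand == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(1)
        mats = [_random_similarity(40, rng) for _ in range(6)]
        _, grand = parc.intersubject_profile_stability(mats)
        assert abs(grand) < 0.1

    def test_two_subjects_symmetric_in_order(self):
        rng = np.random.default_rng(2)
        a, b = _random_similarity(6, rng), _random_similarity(6, rng)
        s1, _ = parc.intersubject_profile_stability([a, b])
        s2, _ = parc.intersubject_profile_stability([b, a])
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_single_subject_rejected(self):
        with pytest.raises(ContractError):
            parc.intersubject_profile_stability(
                [_random_similarity(4, np.random.default_rng(0))])


class TestSubjectGroupAlignment:
    def test_identity_alignment(self):
        labels = np.random.default_rng(0).integers(1, 5, size=(5, 5, 1))
        aligned, _, mapping = parc.subject_group_alignment(labels, labels)
        assert np.array_equal(aligned, labels)
        assert all(k == v for k, v in mapping.items())

    def test_recovers_permuted_labels(self):
        labels = np.random.default_rng(1).integers(1, 5, size=(6, 6, 1))
        perm = {1: 4, 2: 3, 3: 1, 4: 2}
        permuted = np.vectorize(perm.get)(labels)
        aligned, _, mapping = parc.subject_group_alignment(permuted, labels)
        assert mapping == {v: k for k, v in perm.items()}
        assert np.array_equal(aligned, labels)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_contingencies(self, seed):
        rng = np.random.default_rng(seed)
        ind = rng.integers(1, 6, size=(7, 7, 1))
        grp = rng.integers(1, 6, size=(7, 7, 1))
        _, Cn, mapping = parc.subject_group_alignment(ind, grp)
        i_labels = np.unique(ind)
        g_labels = np.unique(grp)
        best = max(
            (sum(Cn[i, p[i]] for i in range(len(i_labels))), p)
            for p in itertools.permutations(range(len(g_labels)))
        )
        achieved = sum(Cn[list(i_labels - 1).index(k - 1),
                          list(g_labels - 1).index(v - 1)]
                       for k, v in mapping.items())
        assert achieved == pytest.approx(best[0], abs=1e-12)

    def test_heatmaps_count_subjects(self):
        labels = np.random.default_rng(2).integers(1, 4, size=(4, 4, 1))
        heat = parc.group_label_heatmaps([labels, labels, labels], labels)
        for g, h in heat.items():
            assert np.array_equal(h == 3, labels == g)


class TestFingerprints:
    def test_k_one_equals_whole_cord_mean(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(10, 6))
        fm = parc.FCFeatureMatrix(Z, np.ones((10, 1, 1), bool),
                                  np.ones((6, 1, 1), bool))
        fp = parc.cluster_fingerprints(np.ones(10, int), [fm])
        np.testing.assert_allclose(fp[0], Z.mean(axis=0), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(12, 5))
        fm = parc.FCFeatureMatrix(Z, np.ones((12, 1, 1), bool),
                                  np.ones((5, 1, 1), bool))
        labels = rng.integers(1, 4, size=12)
        fp1 = parc.cluster_fingerprints(labels, [fm])
        perm = {1: 2, 2: 3, 3: 1}
        relabeled = np.vectorize(perm.get)(labels)
        fp2 = parc.cluster_fingerprints(relabeled, [fm])
        for old in (1, 2, 3):
            np.testing.assert_allclose(fp1[old - 1], fp2[perm[old] - 1],
                                       atol=1e-12)
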