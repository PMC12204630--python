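"""Shape similarity, distances, average-linkage clustering, comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

import merspike as m
from merspike.core import frame_samples, pre_samples

from conftest import make_unit

RATE = 44000.0
P = pre_samples(RATE)
L = frame_samples(RATE)


class TestNormalizeShape:
    def test_zero_mean_unit_norm(self, templates):
        out = m.normalize_shape(templates[0].samples)
        assert abs(out.mean()) < 1e-12
        assert abs(np.linalg.norm(out) - 1.0) < 1e-12

    def test_scale_invariance(self, templates):
        a = m.normalize_shape(templates[0].samples)
        b = m.normalize_shape(10.0 * templates[0].samples)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_sign_equivariance(self, templates):
        a = m.normalize_shape(templates[0].samples)
        b = m.normalize_shape(-templates[0].samples)
        np.testing.assert_allclose(b, -a, atol=1e-12)

    def test_constant_waveform_degenerate(self):
        with pytest.raises(m.DegenerateInputError):
            m.normalize_shape(np.full(50, 2.0))


class TestSimilarity:
    def test_self_similarity_is_one(self, templates):
        u = make_unit(templates[0].samples, -8, 20)
        assert m.similarity(u, u) == pytest.approx(1.0, abs=1e-12)

    def test_inverted_copy_is_minus_one(self, templates):
        w = templates[0].samples
        a = make_unit(w, -8, 20)
        b = make_unit(-w, -8, 20, unit_id=1)
        assert m.similarity(a, b) == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_after_centering_is_zero(self):
        # construct two zero-mean waveforms over the comparison window whose
        # inner product is exactly zero (Gram-Schmidt)
        rng = np.random.default_rng(7)
        wa = rng.normal(size=L)
        wb = rng.normal(size=L)
        sl = slice(P - 10, P + 10)
        a_c = wa[sl] - wa[sl].mean()
        b_c = wb[sl] - wb[sl].mean()
        b_c -= (a_c @ b_c) / (a_c @ a_c) * a_c
        wa[sl], wb[sl] = a_c, b_c
        a = make_unit(wa, -10, 10)
        b = make_unit(wb, -10, 10, unit_id=1)
        assert abs(m.similarity(a, b)) < 1e-12

    def test_union_window_used(self, templates):
        a = make_unit(templates[0].samples, -4, 10)
        b = make_unit(templates[1].samples, -12, 30, unit_id=1)
        sl = slice(P - 12, P + 30)
        expected = float(m.normalize_shape(templates[0].samples[sl])
                         @ m.normalize_shape(templates[1].samples[sl]))
        assert m.similarity(a, b) == pytest.approx(expected, rel=1e-12)


class TestSimilarityMatrix:
    def test_identical_units_all_ones(self, templates):
        us = [make_unit(templates[0].samples, -8, 20, unit_id=i)
              for i in range(3)]
        S = m.similarity_matrix(us)
        np.testing.assert_allclose(S.values, np.ones((3, 3)), atol=1e-12)

    def test_matches_pairwise_oracle_and_permutation(self, three_templates):
        us = [make_unit(t.samples, -10, 25, unit_id=i)
              for i, t in enumerate(three_templates)]
        S = m.similarity_matrix(us)
        for i in range(3):
            for j in range(3):
                exp = 1.0 if i == j else m.similarity(us[i], us[j])
                assert S.values[i, j] == pytest.approx(exp, abs=1e-12)
        perm = [2, 0, 1]
        S2 = m.similarity_matrix([us[i] for i in perm])
        np.testing.assert_allclose(S2.values,
                                   S.values[np.ix_(perm, perm)], atol=1e-12)

    def test_needs_two_units(self, templates):
        with pytest.raises(m.InvalidParameterError):
            m.similarity_matrix([make_unit(templates[0].samples, -8, 20)])


class TestDistance:
    @pytest.mark.parametrize("s,expected", [
        (1.0, 0.0), (-0.8, 1.0), (0.25, 0.75), (0.0, 1.0)])
    def test_clamped_distance(self, s, expected):
        sim = m.SimilarityMatrix([0, 1],
                                 np.array([[1.0, s], [s, 1.0]]))
        d = m.distance_matrix(sim)
        assert d[0, 1] == pytest.approx(expected)
        assert d[0, 0] == 0.0


_waveform = arrays(np.float64, L,
                   elements=st.floats(-5, 5, allow_nan=False,
                                      width=32)).filter(
    lambda w: np.ptp(w[P - 10:P + 30]) > 1e-3)


class TestSimilarityProperties:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(_waveform, _waveform, st.floats(0.01, 100.0))
    def test_bounds_symmetry_scale_invariance(self, wa, wb, scale):
        a = make_unit(wa, -10, 30)
        b = make_unit(wb, -10, 30, unit_id=1)
        s = m.similarity(a, b)
        assert -1.0 - 1e-9 <= s <= 1.0 + 1e-9       # Cauchy-Schwarz
        assert m.similarity(b, a) == pytest.approx(s, abs=1e-12)
        b_scaled = make_unit(scale * wb, -10, 30, unit_id=1)
        assert m.similarity(a, b_scaled) == pytest.approx(s, rel=1e-6,
                                                          abs=1e-9)
        sim = m.SimilarityMatrix([0, 1], np.array([[1.0, s], [s, 1.0]]))
        d = m.distance_matrix(sim)
        assert 0.0 <= d[0, 1] <= 1.0
        assert d[0, 0] == d[1, 1] == 0.0


def brute_force_average_linkage(D):
    """O(n^3) UPGMA oracle: repeatedly merge the closest pair of clusters,
    inter-cluster distance = mean over all member pairs."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((sorted(clusters[a] + clusters[b]), d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestHierarchicalClustering:
    def test_two_perfect_groups(self):
        D = np.ones((4, 4))
        D[0, 1] = D[1, 0] = D[2, 3] = D[3, 2] = 0.0
        np.fill_diagonal(D, 0.0)
        Z = m.hierarchical_cluster(D)
        heights = sorted(Z[:, 2])
        assert heights[0] == heights[1] == 0.0
        assert heights[2] == pytest.approx(1.0)

    def test_all_zero_distances(self):
        D = np.zeros((5, 5))
        Z = m.hierarchical_cluster(D)
        assert np.all(Z[:, 2] == 0.0)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0.05, 1.0, (8, 8))
            D = (X + X.T) / 2
            np.fill_diagonal(D, 0.0)
            Z = m.hierarchical_cluster(D)
            oracle = brute_force_average_linkage(D)
            np.testing.assert_allclose(sorted(Z[:, 2]),
                                       sorted(h for _, h in oracle),
                                       rtol=1e-12)
            # partitions agree at every cut level
            for k in range(1, 9):
                labels = fcluster(Z, t=k, criterion="maxclust")
                # oracle partition at k clusters
                parts = {i: {i} for i in range(8)}
                for members, _ in oracle[:8 - k]:
                    merged = set(members)
                    for key in [key for key, v in parts.items()
                                if v & merged]:
                        merged |= parts.pop(key)
                    parts[min(merged)] = merged
                oracle_labels = np.empty(8, int)
                for lab, (_, members) in enumerate(sorted(parts.items())):
                    oracle_labels[list(members)] = lab
                assert adjusted_rand_score(labels, oracle_labels) == 1.0

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(42)
        X = rng.uniform(0, 1, (10, 10))
        D = (X + X.T) / 2
        np.fill_diagonal(D, 0)
        Z = m.hierarchical_cluster(D)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)


class TestElbowAndCut:
    def _grouped_units(self, three_templates, per_group=5):
        rng = np.random.default_rng(0)
        units = []
        for i in range(per_group * 3):
            tpl = three_templates[i % 3]
            w = tpl.samples + rng.normal(0, 0.01, L)
            units.append(make_unit(w, -12, 30, unit_id=i))
        return units

    def test_three_well_separated_groups(self, three_templates):
        units = self._grouped_units(three_templates)
        S = m.similarity_matrix(units)
        D = m.distance_matrix(S)
        Z = m.hierarchical_cluster(D)
        assert m.select_k_elbow(Z, D) == 3

    def test_identical_units_give_one_cluster(self, templates):
        units = [make_unit(templates[0].samples, -8, 20, unit_id=i)
                 for i in range(6)]
        D = m.distance_matrix(m.similarity_matrix(units))
        Z = m.hierarchical_cluster(D)
        assert m.select_k_elbow(Z, D) == 1

    def test_manual_override_honored(self, three_templates):
        units = self._grouped_units(three_templates, per_group=4)
        D = m.distance_matrix(m.similarity_matrix(units))
        Z = m.hierarchical_cluster(D)
        res = m.cluster_shapes(units, Z, k=6, distances=D)
        assert res.k == 6
        assert len(np.unique(res.labels)) == 6

    def test_k_equals_n_trivial_cut(self, three_templates):
        units = self._grouped_units(three_templates, per_group=2)
        D = m.distance_matrix(m.similarity_matrix(units))
        Z = m.hierarchical_cluster(D)
        res = m.cluster_shapes(units, Z, k=len(units))
        assert len(np.unique(res.labels)) == len(units)

    def test_invalid_k(self, three_templates):
        units = self._grouped_units(three_templates, per_group=2)
        D = m.distance_matrix(m.similarity_matrix(units))
        Z = m.hierarchical_cluster(D)
        with pytest.raises(m.InvalidParameterError):
            m.cluster_shapes(units, Z, k=0)


class TestDepthProfile:
    def test_rates_and_isis(self, templates):
        w = templates[0].samples
        # 300 spikes in 30 s at regular 100 ms ISIs
        times = (np.arange(300) * 0.1 * RATE).astype(int)
        units = [make_unit(w, -8, 20, unit_id=0, spike_times=times),
                 make_unit(w, -8, 20, unit_id=1,
                           spike_times=np.array([100]))]
        res = m.ClusterResult(np.empty((0, 4)), 1,
                              np.array([1, 1]), {}, {})
        per_unit, per_cluster = m.depth_profile(res, units, [5.0, None],
                                                duration_s=30.0)
        row = per_unit[per_unit.unit_id == 0].iloc[0]
        assert row.firing_rate_hz == pytest.approx(10.0)
        assert row.mean_isi_s == pytest.approx(0.1)
        single = per_unit[per_unit.unit_id == 1].iloc[0]
        assert single.mean_isi_s is None or np.isnan(single.mean_isi_s)
        assert per_cluster.iloc[0].n_units == 2


def exhaustive_overlap(a, b, k):
    """Brute-force best label matching by enumerating all permutations."""
    best = 0
    for perm in itertools.permutations(range(k)):
        agree = np.sum(np.array([perm[x] for x in a]) == b)
        best = max(best, agree)
    return 100.0 * best / len(a)


class TestHungarianAndPca:
    def test_permuted_labels_full_overlap(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 6, 50)
        perm = rng.permutation(6)
        assert m.hungarian_overlap(a, perm[a]) == 100.0

    def test_random_labels_match_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        ours, oracle = [], []
        for _ in range(200):
            a = rng.integers(0, 6, 50)
            b = rng.integers(0, 6, 50)
            ours.append(m.hungarian_overlap(a, b))
            oracle.append(exhaustive_overlap(a, b, 6))
        np.testing.assert_allclose(ours, oracle)

    def test_amplitude_confound_directionality(self, three_templates):
        # same shapes, bimodal amplitudes: raw-waveform clustering is
        # amplitude-dominated, normalized clustering recovers shape
        rng = np.random.default_rng(3)
        units = []
        for i in range(30):
            tpl = three_templates[i % 3]
            amp = 0.3 if i % 2 == 0 else 3.0
            w = amp * (tpl.samples + rng.normal(0, 0.01, L))
            units.append(make_unit(w, -12, 30, unit_id=i))
        D = m.distance_matrix(m.similarity_matrix(units))
        Z = m.hierarchical_cluster(D)
        hier = m.cluster_shapes(units, Z, k=3).labels
        _, ov_raw = m.compare_pca_kmeans(units, hier, 3, normalize=False,
                                         seed=0)
        _, ov_norm = m.compare_pca_kmeans(units, hier, 3, normalize=True,
                                          seed=0)
        assert ov_raw < ov_norm

    def test_k_exceeding_n_rejected(self, templates):
        units = [make_unit(templates[0].samples, -8, 20, unit_id=i)
                 for i in range(3)]
        with pytest.raises(m.InvalidParameterError):
            m.compare_pca_kmeans(units, np.zeros(3), k=5)
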