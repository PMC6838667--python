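"""Synthetic generators: planted gradient, cluster, hub, multi-subject noise."""

import numpy as np
import pytest

import connspace as cs
from connspace.similarity import cosine_similarity_matrix


class TestGradedProfiles:
    def test_bit_identical_regeneration(self):
        a, ta = cs.generate_graded_profiles(30, 300, noise_sd=0.1, rng_seed=5)
        b, tb = cs.generate_graded_profiles(30, 300, noise_sd=0.1, rng_seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(ta.latent_coordinate, tb.latent_coordinate)

    def test_different_seed_differs(self):
        a, _ = cs.generate_graded_profiles(30, 300, noise_sd=0.1, rng_seed=5)
        b, _ = cs.generate_graded_profiles(30, 300, noise_sd=0.1, rng_seed=6)
        assert not np.array_equal(a.values, b.values)

    def test_non_negative(self):
        p, _ = cs.generate_graded_profiles(40, 400, noise_sd=0.5, rng_seed=2)
        assert p.values.min() >= 0

    def test_endpoints_equal_extremes(self):
        p, t = cs.generate_graded_profiles(2, 100, noise_sd=0.0, rng_seed=0)
        np.testing.assert_array_equal(p.values[0], t.extremes[0])
        np.testing.assert_array_equal(p.values[1], t.extremes[1])

    def test_midpoint_is_equal_mixture(self):
        p, t = cs.generate_graded_profiles(3, 100, noise_sd=0.0, rng_seed=0)
        assert t.latent_coordinate[1] == 0.5
        np.testing.assert_allclose(p.values[1],
                                   0.5 * t.extremes[0] + 0.5 * t.extremes[1])

    def test_similarity_strictly_decreases_with_latent_distance(self):
        """Exhaustive check: noiseless two-extreme similarity is a strictly
        decreasing function of |t_i - t_j| (up to float ties)."""
        p, t = cs.generate_graded_profiles(12, 240, noise_sd=0.0, rng_seed=0)
        A = cosine_similarity_matrix(p).A
        tc = t.latent_coordinate
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    if abs(tc[i] - tc[j]) < abs(tc[i] - tc[k]) - 1e-12:
                        assert A[i, j] > A[i, k]

    def test_three_extreme_gradient_decays_monotonically_along_axis(self):
        """With more than two extremes, similarity still falls strictly as a
        seed's neighbour moves further away on the same side."""
        p, t = cs.generate_graded_profiles(12, 240, n_extremes=3,
                                           noise_sd=0.0, rng_seed=0)
        A = cosine_similarity_matrix(p).A
        tc = t.latent_coordinate
        for i in range(12):
            for a in range(12):
                for b in range(12):
                    same_side = (tc[a] - tc[i]) * (tc[b] - tc[i]) > 0
                    if same_side and abs(tc[a] - tc[i]) < abs(tc[b] - tc[i]) - 1e-12:
                        assert A[i, a] > A[i, b]

    @pytest.mark.parametrize("kwargs", [
        dict(n_seeds=0, m_targets=10),
        dict(n_seeds=5, m_targets=0),
        dict(n_seeds=2, m_targets=100, n_extremes=3),   # n_seeds < n_extremes
        dict(n_seeds=50, m_targets=10),                  # m_targets < n_seeds
        dict(n_seeds=5, m_targets=100, noise_sd=-0.1),
    ])
    def test_sizing_errors(self, kwargs):
        with pytest.raises(ValueError):
            cs.generate_graded_profiles(**kwargs)

    def test_truth_invariants_enforced(self):
        with pytest.raises(ValueError, match="hub_mask"):
            cs.SyntheticTruth(latent_coordinate=np.array([0.0]),
                              population_label=np.array(["gradient"], object),
                              hub_mask=np.array([True]))


class TestClusterProfiles:
    def test_zero_overlap_is_orthogonal(self, small_gradient):
        p, t = cs.generate_cluster_profiles(*small_gradient, n_cluster=10,
                                            overlap=0.0, rng_seed=3)
        A = cosine_similarity_matrix(p).A
        grad = t.population_label == "gradient"
        clus = t.population_label == "cluster"
        assert np.abs(A[np.ix_(clus, grad)]).max() == 0.0

    def test_zero_overlap_gives_two_components(self, small_gradient):
        p, _ = cs.generate_cluster_profiles(*small_gradient, n_cluster=10,
                                            overlap=0.0, rng_seed=3)
        res = cs.ConnectivityGradientModel(p).fit()
        assert res.diagnostics["n_components"] == 2

    def test_within_exceeds_cross_similarity(self, small_gradient_noisy):
        p, t = cs.generate_cluster_profiles(*small_gradient_noisy,
                                            n_cluster=12, overlap=0.2,
                                            rng_seed=4)
        A = cosine_similarity_matrix(p).A
        clus = t.population_label == "cluster"
        within = A[np.ix_(clus, clus)]
        cross = A[np.ix_(clus, ~clus)]
        assert within.mean() > cross.mean()

    def test_overlap_out_of_range_rejected(self, small_gradient):
        with pytest.raises(ValueError, match="overlap"):
            cs.generate_cluster_profiles(*small_gradient, n_cluster=5,
                                         overlap=1.2, rng_seed=0)

    def test_truth_labels_extended(self, small_gradient):
        p, t = cs.generate_cluster_profiles(*small_gradient, n_cluster=7,
                                            overlap=0.1, rng_seed=0)
        assert p.n_seeds == 67
        assert (t.population_label == "cluster").sum() == 7
        assert np.isnan(t.latent_coordinate[-7:]).all()


class TestHubProfiles:
    def test_noiseless_hub_equals_midpoint_profile(self, small_gradient):
        p, t = cs.generate_hub_profiles(*small_gradient, n_hub=3, rng_seed=0)
        expected = 0.5 * t.extremes[0] + 0.5 * t.extremes[1]
        np.testing.assert_allclose(p.values[-1], expected)

    def test_hub_has_maximal_mean_similarity(self, small_gradient):
        """Brute-force ranking: the noise-free hub tops mean similarity."""
        p, t = cs.generate_hub_profiles(*small_gradient, n_hub=1, rng_seed=0)
        A = cosine_similarity_matrix(p).A
        np.fill_diagonal(A, np.nan)
        mean_sim = np.nanmean(A, axis=1)
        hub_idx = int(np.flatnonzero(t.hub_mask)[0])
        assert mean_sim[hub_idx] >= mean_sim.max() - 1e-12

    def test_hub_mask_and_labels(self, small_gradient):
        p, t = cs.generate_hub_profiles(*small_gradient, n_hub=4, rng_seed=1)
        assert t.hub_mask.sum() == 4
        assert np.all(t.population_label[t.hub_mask] == "hub")

    def test_requires_gradient_base(self, small_gradient):
        profiles, truth = small_gradient
        bare = cs.SyntheticTruth(
            latent_coordinate=truth.latent_coordinate,
            population_label=truth.population_label,
            hub_mask=truth.hub_mask)
        with pytest.raises(ValueError, match="extremes"):
            cs.generate_hub_profiles(profiles, bare, n_hub=2, rng_seed=0)


class TestMultiSubject:
    def test_zero_noise_copies_template(self, small_gradient):
        template, _ = small_gradient
        subs = cs.generate_multisubject(template, 3, subject_noise_sd=0.0,
                                        rng_seed=0)
        for s in subs:
            np.testing.assert_array_equal(s.values, template.values)

    def test_single_subject_mean_is_that_subject(self, small_gradient):
        template, _ = small_gradient
        (s,) = cs.generate_multisubject(template, 1, subject_noise_sd=0.2,
                                        rng_seed=1)
        avg = cs.group_average([s])
        np.testing.assert_array_equal(avg.values, s.values)

    def test_averaging_reduces_rmse(self, small_gradient):
        template, _ = small_gradient
        subs = cs.generate_multisubject(template, 24, subject_noise_sd=0.1,
                                        rng_seed=3)
        group = cs.group_average(subs)
        single_rmse = np.sqrt(((subs[0].values - template.values) ** 2).mean())
        group_rmse = np.sqrt(((group.values - template.values) ** 2).mean())
        assert group_rmse < single_rmse

    def test_subjects_are_independent(self, small_gradient):
        template, _ = small_gradient
        subs = cs.generate_multisubject(template, 2, subject_noise_sd=0.1,
                                        rng_seed=5)
        assert not np.array_equal(subs[0].values, subs[1].values)
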