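"""Hubs, regions, entropy, spatial correlation, diffusion profiles,
multi-sample integration."""

import numpy as np
import pytest

from spotdecon.core_io import SignatureSet, SpotDataset
from spotdecon.downstream import (HubAssignment, classify_hub_regions,
                                  diffused_expression_profile, identify_hubs,
                                  integrate_samples, mixing_entropy,
                                  spatial_cross_correlation)


def _blob_proportions(seed=0):
    """Two tight clusters in proportion space."""
    rng = np.random.default_rng(seed)
    a = rng.dirichlet([50, 2, 2], size=40)
    b = rng.dirichlet([2, 50, 2], size=40)
    return np.vstack([a, b])


class TestHubs:
    def test_two_separated_blobs_give_two_hubs(self):
        c = _blob_proportions()
        hubs = identify_hubs(c, k_neighbors=30, seed=0)
        assert hubs.n_hubs == 2
        # blobs map to distinct labels
        assert len(set(hubs.hub_label[:40])) == 1
        assert len(set(hubs.hub_label[40:])) == 1

    def test_identical_rows_form_single_hub(self):
        c = np.tile([0.5, 0.3, 0.2], (40, 1))
        hubs = identify_hubs(c, k_neighbors=30, seed=0)
        assert hubs.n_hubs == 1

    def test_same_seed_is_deterministic(self):
        c = _blob_proportions(3)
        a = identify_hubs(c, k_neighbors=10, seed=4)
        b = identify_hubs(c, k_neighbors=10, seed=4)
        np.testing.assert_array_equal(a.hub_label, b.hub_label)

    def test_labels_ordered_by_descending_size(self):
        rng = np.random.default_rng(1)
        big = rng.dirichlet([60, 2], size=50)
        small = rng.dirichlet([2, 60], size=20)
        hubs = identify_hubs(np.vstack([big, small]), k_neighbors=8, seed=0)
        sizes = np.bincount(hubs.hub_label)
        assert np.all(np.diff(sizes) <= 0)

    def test_partition_stable_under_spot_permutation(self):
        c = _blob_proportions(5)
        perm = np.random.default_rng(0).permutation(len(c))
        a = identify_hubs(c, k_neighbors=30, seed=1)
        b = identify_hubs(c[perm], k_neighbors=30, seed=1)
        np.testing.assert_array_equal(a.hub_label[perm], b.hub_label)

    def test_too_many_neighbors_rejected(self):
        with pytest.raises(ValueError):
            identify_hubs(np.ones((5, 2)) / 2, k_neighbors=5)


class TestRegions:
    def _hubs(self, labels):
        return HubAssignment(hub_label=np.asarray(labels), k_neighbors=3,
                             resolution=1.0, seed=0)

    def test_threshold_is_strict(self):
        labels = [0] * 4 + [1] * 4
        c = np.zeros((8, 2))
        c[:4, 0] = 0.21   # intratumoral (mean 0.21 > 0.2)
        c[4:, 0] = 0.20   # exactly at threshold -> not intratumoral
        c[:, 1] = 1 - c[:, 0]
        coords = np.column_stack([np.arange(8), np.zeros(8)])
        region = classify_hub_regions(self._hubs(labels), c, [0], coords,
                                      boundary_rank=1)
        assert region[0] == "intratumoral"
        assert region[1] != "intratumoral"

    def test_distance_ranking_splits_peri_and_stromal(self):
        # hub 0 tumor; hub 1 adjacent; hub 2 far away
        labels = [0, 0, 1, 1, 2, 2]
        c = np.array([[0.9], [0.8], [0.05], [0.05], [0.05], [0.05]])
        c = np.hstack([c, 1 - c])
        coords = np.array([[0, 0], [1, 0], [2, 0], [3, 0], [50, 0], [60, 0]],
                          dtype=float)
        region = classify_hub_regions(self._hubs(labels), c, [0], coords,
                                      boundary_rank=1)
        assert region == {0: "intratumoral", 1: "peritumoral", 2: "stromal"}

    def test_no_tumor_hub_warns_and_labels_stromal(self):
        labels = [0, 0, 1, 1]
        c = np.full((4, 2), 0.05)
        c[:, 1] = 0.95
        coords = np.zeros((4, 2))
        with pytest.warns(UserWarning, match="no intratumoral"):
            region = classify_hub_regions(self._hubs(labels), c, [0], coords)
        assert set(region.values()) == {"stromal"}

    def test_invariant_to_hub_label_permutation(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        c = np.array([[0.9], [0.8], [0.1], [0.1], [0.02], [0.02]])
        c = np.hstack([c, 1 - c])
        coords = np.array([[0, 0], [1, 0], [3, 0], [4, 0], [30, 0], [31, 0]],
                          dtype=float)
        r1 = classify_hub_regions(self._hubs(labels), c, [0], coords,
                                  boundary_rank=1)
        swap = {0: 2, 1: 0, 2: 1}
        labels2 = np.vectorize(swap.get)(labels)
        r2 = classify_hub_regions(self._hubs(labels2), c, [0], coords,
                                  boundary_rank=1)
        assert all(r1[h] == r2[swap[h]] for h in r1)


class TestEntropy:
    def test_single_sample_neighborhood_is_zero(self):
        z = np.random.default_rng(0).standard_normal((20, 3))
        H = mixing_entropy(z, ["only"] * 20, k_neighbors=5)
        np.testing.assert_allclose(H, 0.0)

    def test_uniform_fourteen_samples_reach_log_fourteen(self):
        # a center spot ringed by 14 equidistant spots, one per sample: its
        # 14 nearest neighbors cover every sample exactly once
        M = 14
        angles = 2 * np.pi * np.arange(M) / M
        ring = np.column_stack([np.cos(angles), np.sin(angles)])
        far = np.column_stack([1000.0 + np.arange(20), np.zeros(20)])
        z = np.vstack([[[0.0, 0.0]], ring, far])
        labels = [0] + list(range(M)) + [0] * 20
        H = mixing_entropy(z, labels, k_neighbors=M)
        assert abs(H[0] - np.log(M)) < 1e-12

    def test_matches_brute_force_knn_counts(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((50, 4))
        labels = rng.integers(0, 3, size=50)
        k = 7
        H = mixing_entropy(z, labels, k_neighbors=k)
        for i in range(50):
            d = np.linalg.norm(z - z[i], axis=1)
            order = np.argsort(d, kind="stable")
            neigh = [j for j in order if j != i][:k]
            frac = np.bincount(labels[neigh], minlength=3) / k
            frac = frac[frac > 0]
            np.testing.assert_allclose(H[i], -(frac * np.log(frac)).sum())

    def test_bounds(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((60, 2))
        labels = rng.integers(0, 4, size=60)
        H = mixing_entropy(z, labels, k_neighbors=10)
        assert np.all(H >= 0) and np.all(H <= np.log(4) + 1e-12)


class TestSCI:
    def _random_instance(self, seed, S=50):
        rng = np.random.default_rng(seed)
        coords = rng.integers(0, 10, size=(S, 2)).astype(float)
        x = rng.standard_normal(S)
        y = rng.standard_normal(S)
        return x, y, coords

    def test_symmetry(self):
        x, y, coords = self._random_instance(0)
        a = spatial_cross_correlation(x, y, coords)
        b = spatial_cross_correlation(y, x, coords)
        assert abs(a - b) < 1e-10

    def test_positive_affine_invariance(self):
        x, y, coords = self._random_instance(1)
        a = spatial_cross_correlation(x, y, coords)
        b = spatial_cross_correlation(3.2 * x + 7.0, y, coords)
        assert abs(a - b) < 1e-10

    def test_four_spot_example_matches_double_sum(self):
        coords = np.array([[0, 0], [0, 1], [1, 0], [5, 5]], dtype=float)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        thr = np.sqrt(3)
        # term-by-term oracle
        xc, yc = x - x.mean(), y - y.mean()
        num, tau_sum = 0.0, 0.0
        for i in range(4):
            for j in range(4):
                if i != j and np.linalg.norm(coords[i] - coords[j]) < thr:
                    num += xc[i] * yc[j]
                    tau_sum += 1
        ref = 4 / (2 * tau_sum) * num / (np.sqrt((xc ** 2).sum())
                                         * np.sqrt((yc ** 2).sum()))
        got = spatial_cross_correlation(x, y, coords)
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_all_pairs_weights_recover_scaled_pearson(self):
        # with every distinct pair adjacent, the double sum collapses to
        # -sum(xc*yc), i.e. SCI is proportional to the Pearson correlation
        x, y, coords = self._random_instance(2, S=30)
        got = spatial_cross_correlation(x, y, coords, dist_threshold=1e9)
        xc, yc = x - x.mean(), y - y.mean()
        pearson = (xc @ yc) / (np.linalg.norm(xc) * np.linalg.norm(yc))
        ref = 30 / (2 * 30 * 29) * (-pearson)
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spatial_cross_correlation(np.ones(5), np.arange(5.0),
                                      np.zeros((5, 2)))


class TestDiffusedProfile:
    def _grid(self, side=10):
        return np.array([[i, j] for i in range(side) for j in range(side)],
                        dtype=float)

    def test_constant_expression_gives_flat_profile(self):
        coords = self._grid()
        bins, mean, sd = diffused_expression_profile(
            np.full(100, 3.0), coords, [0], window=7, smooth_sigma=1.5)
        np.testing.assert_allclose(mean, 3.0, atol=1e-9)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_distance_valued_expression_is_identity_before_smoothing(self):
        coords = self._grid()
        from scipy.spatial import cKDTree
        dist = cKDTree(coords[[0]]).query(coords)[0]
        expr = np.round(dist)
        bins, mean, _ = diffused_expression_profile(
            expr, coords, [0], window=1, smooth_sigma=0.0)
        np.testing.assert_allclose(mean, bins, atol=1e-9)

    def test_binning_matches_brute_force_nearest_source(self):
        rng = np.random.default_rng(0)
        coords = self._grid()
        expr = rng.standard_normal(100)
        sources = [5, 42, 77]
        bins, mean, _ = diffused_expression_profile(
            expr, coords, sources, window=1, smooth_sigma=0.0)
        d = np.array([min(np.linalg.norm(c - coords[s]) for s in sources)
                      for c in coords])
        binned = np.round(d).astype(int)
        for b in range(binned.max() + 1):
            if np.any(binned == b):
                np.testing.assert_allclose(mean[b], expr[binned == b].mean())

    def test_empty_sources_rejected(self):
        with pytest.raises(ValueError):
            diffused_expression_profile(np.ones(4), self._grid(2), [])


class TestIntegration:
    def _sample(self, seed, genes=None):
        rng = np.random.default_rng(seed)
        genes = genes or [f"G{i}" for i in range(30)]
        S = 25
        return SpotDataset(
            counts=rng.poisson(5.0, size=(S, len(genes))),
            gene_names=list(genes),
            spot_ids=[f"s{seed}_{i}" for i in range(S)],
            array_coords=np.column_stack([np.arange(S) // 5, np.arange(S) % 5]),
        )

    def test_identical_samples_keep_single_sample_markers(self):
        d = self._sample(0)
        sigs = SignatureSet(["A", "B"], {"A": ["G0", "G1"], "B": ["G5", "G6"]})
        merged, bundles, joint = integrate_samples([d, d], sigs, refine=False)
        assert joint.markers == sigs.markers
        assert merged.n_spots == 50
        assert len(set(merged.sample_labels)) == 2

    def test_marker_unique_to_one_sample_propagates(self):
        g1 = [f"G{i}" for i in range(30)]
        d1, d2 = self._sample(1, g1), self._sample(2, g1)
        s1 = SignatureSet(["A"], {"A": ["G0"]})
        # simulate per-sample refinement outcome by unioning manually:
        # sample 2's extra marker must enter sample 1's recomputed prior
        sigs = SignatureSet(["A"], {"A": ["G0", "G9"]})
        merged, bundles, joint = integrate_samples([d1, d2], sigs,
                                                   refine=False)
        assert "G9" in joint.markers["A"]
        # both bundles were scored with the joint marker list
        assert bundles[0].state_names == bundles[1].state_names == ["A"]
        del s1

    def test_library_priors_never_mix_samples(self):
        from spotdecon.priors import library_size_prior
        d1, d2 = self._sample(3), self._sample(4)
        sigs = SignatureSet(["A"], {"A": ["G0", "G1"]})
        merged, bundles, _ = integrate_samples([d1, d2], sigs, refine=False)
        np.testing.assert_allclose(bundles[0].lib_prior,
                                   library_size_prior(d1, 3))
        np.testing.assert_allclose(bundles[1].lib_prior,
                                   library_size_prior(d2, 3))

    def test_disjoint_gene_namespaces_rejected(self):
        d1 = self._sample(5, [f"A{i}" for i in range(30)])
        d2 = self._sample(6, [f"B{i}" for i in range(30)])
        sigs = SignatureSet(["A"], {"A": ["A0"]})
        with pytest.raises(ValueError, match="share no genes"):
            integrate_samples([d1, d2], sigs, refine=False)
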