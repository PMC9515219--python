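"""Generator determinism, geometry and planted-structure recovery."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import transgrad as tg


class TestParcellation:
    def test_single_region_hemispheres_are_mirror_images(self):
        meta = tg.make_parcellation(tg.SimulationConfig(n_regions_per_hemisphere=1))
        assert meta.n_regions == 2
        left, right = meta.centroid
        np.testing.assert_allclose(left * [-1, 1, 1], right, atol=1e-12)

    def test_min_pairwise_angular_separation_positive(self, meta68):
        gram = np.clip(meta68.centroid @ meta68.centroid.T, -1, 1)
        theta = np.arccos(gram)
        np.fill_diagonal(theta, np.inf)
        assert theta.min() > 1e-3  # brute-force over all pairs

    def test_deterministic(self):
        cfg = tg.SimulationConfig(seed=5)
        assert tg.make_parcellation(cfg) == tg.make_parcellation(cfg)

    def test_label_sets(self, meta68):
        assert set(meta68.community) <= set(tg.synthetic.COMMUNITY_NAMES)
        assert set(meta68.hierarchy) <= set(tg.synthetic.HIERARCHY_NAMES)
        assert len(set(meta68.community)) == 7
        assert len(set(meta68.hierarchy)) == 4

    def test_homotopic_regions_share_labels(self, meta68):
        n = meta68.n_regions // 2
        assert meta68.community[:n] == meta68.community[n:]

    def test_zero_regions_rejected(self):
        with pytest.raises(ValueError):
            tg.SimulationConfig(n_regions_per_hemisphere=0)


class TestSmoothMap:
    def test_deterministic(self, meta68):
        a = tg.simulate_smooth_map(meta68, 0.6, 7)
        b = tg.simulate_smooth_map(meta68, 0.6, 7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_standardized(self, meta68, smooth_map68):
        assert abs(smooth_map68.values.mean()) < 1e-12
        assert abs(smooth_map68.values.std() - 1) < 1e-12

    @staticmethod
    def _neighbor_pairs(meta):
        gram = np.clip(meta.centroid @ meta.centroid.T, -1, 1)
        theta = np.arccos(gram)
        np.fill_diagonal(theta, np.inf)
        return np.argmin(theta, axis=1)

    def test_tiny_lengthscale_decorrelates_neighbors(self, meta68):
        nn = self._neighbor_pairs(meta68)
        xs, ys = [], []
        for seed in range(200):
            m = tg.simulate_smooth_map(meta68, 0.02, seed).values
            xs.append(m)
            ys.append(m[nn])
        r = np.corrcoef(np.concatenate(xs), np.concatenate(ys))[0, 1]
        assert abs(r) < 0.2

    def test_large_lengthscale_correlates_neighbors(self, meta68):
        nn = self._neighbor_pairs(meta68)
        rs = []
        for seed in range(200):
            m = tg.simulate_smooth_map(meta68, 0.6, seed).values
            rs.append(np.corrcoef(m, m[nn])[0, 1])
        assert np.mean(rs) > 0.5

    def test_nonpositive_lengthscale_rejected(self, meta68):
        with pytest.raises(ValueError):
            tg.simulate_smooth_map(meta68, 0.0, 1)


class TestEffectMatrix:
    def test_zero_noise_is_rank_one(self, meta68, smooth_map68):
        cfg = tg.SimulationConfig(noise_sd=0.0)
        eff = tg.simulate_effect_matrix(meta68, smooth_map68, cfg)
        s = np.linalg.svd(eff.values, compute_uv=False)
        assert s[1] / s[0] < 1e-12

    def test_zero_noise_columns_proportional(self, meta68, smooth_map68):
        cfg = tg.SimulationConfig(noise_sd=0.0)
        eff = tg.simulate_effect_matrix(meta68, smooth_map68, cfg)
        for j, loading in enumerate(cfg.shared_loadings):
            np.testing.assert_allclose(
                eff.values[:, j], loading * smooth_map68.values, atol=1e-12
            )

    def test_moderate_noise_pc1_recovers_planted(self, meta68, smooth_map68):
        cfg = tg.SimulationConfig(seed=2, noise_sd=0.3)
        eff = tg.simulate_effect_matrix(meta68, smooth_map68, cfg)
        # oracle: direct SVD of the centered matrix
        x = eff.values - eff.values.mean(axis=0)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        r = np.corrcoef(u[:, 0], smooth_map68.values)[0, 1]
        assert abs(r) > 0.95
        res = tg.fit_shared_dimension(eff)
        np.testing.assert_allclose(
            np.abs(res.scores[:, 0]), np.abs(u[:, 0] * s[0]), atol=1e-8
        )

    def test_loading_mismatch_rejected(self, meta68, smooth_map68):
        with pytest.raises(ValueError):
            tg.SimulationConfig(shared_loadings=(1.0, 1.0), condition_names=("a", "b", "c"))


class TestProfiles:
    def _maps(self, meta, peak):
        ones = tg.ParcelMap(np.ones(meta.n_regions), meta)
        return tg.ParcelMap(np.full(meta.n_regions, peak), meta), ones

    def test_peak_location_matches_plant(self, meta68):
        peaks, amps = self._maps(meta68, 0.2)
        prof = tg.simulate_profiles(meta68, peaks, amps, 14, 1, noise_sd=0.0)
        argmax_depth = prof.depth_fractions[np.argmax(prof.intensities, axis=1)]
        step = prof.depth_fractions[1] - prof.depth_fractions[0]
        assert np.all(np.abs(argmax_depth - 0.2) <= step)

    def test_zero_amplitude_flat(self, meta68):
        peaks = tg.ParcelMap(np.full(meta68.n_regions, 0.5), meta68)
        amps = tg.ParcelMap(np.zeros(meta68.n_regions), meta68)
        prof = tg.simulate_profiles(meta68, peaks, amps, 14, 1, noise_sd=0.01)
        assert np.all(prof.intensities.std(axis=1) <= 0.05)

    def test_ep_anticorrelates_with_planted_depth(self, meta68):
        rng = np.random.default_rng(4)
        peaks = tg.ParcelMap(rng.uniform(0.05, 0.95, meta68.n_regions), meta68)
        amps = tg.ParcelMap(np.ones(meta68.n_regions), meta68)
        prof = tg.simulate_profiles(meta68, peaks, amps, 18, 1, noise_sd=0.0)
        ep = tg.externopyramidization(prof)
        rho = spearmanr(ep.values, peaks.values).statistic
        assert rho < -0.9

    def test_too_few_depths_rejected(self, meta68):
        peaks, amps = self._maps(meta68, 0.2)
        with pytest.raises(ValueError):
            tg.simulate_profiles(meta68, peaks, amps, 3, 1)


class TestConnectivity:
    def test_two_valued_axis_gives_two_blocks(self, meta20):
        axis = tg.ParcelMap(np.repeat([0.0, 4.0], 10), meta20)
        conn = tg.simulate_connectivity(meta20, axis, noise=0.0, kernel_scale=1.0)
        same = conn.values[:10, :10]
        cross = conn.values[:10, 10:]
        assert np.all(same == 1.0)
        np.testing.assert_allclose(cross, np.exp(-8.0), atol=1e-12)

    def test_symmetric(self, meta68, smooth_map68):
        conn = tg.simulate_connectivity(meta68, smooth_map68, noise=0.1, seed=3)
        assert np.max(np.abs(conn.values - conn.values.T)) == 0

    def test_gradient_recovers_axis_order(self, meta68, smooth_map68):
        conn = tg.simulate_connectivity(meta68, smooth_map68, noise=0.0)
        res = tg.diffusion_map_embedding(conn, n_components=3)
        rho = spearmanr(res.gradients[:, 0], smooth_map68.values).statistic
        assert abs(rho) > 0.95


class TestFeaturePanel:
    def test_noiseless_informative_column_is_target(self, meta68, smooth_map68):
        cfg = tg.SimulationConfig(seed=1)
        panel = tg.simulate_feature_panel(meta68, smooth_map68, cfg, feature_noise_sd=0.0)
        for j in cfg.informative_features:
            r = np.corrcoef(panel.values[:, j], smooth_map68.values)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_shape_and_support_record(self, meta68, smooth_map68):
        cfg = tg.SimulationConfig(seed=1)
        panel = tg.simulate_feature_panel(meta68, smooth_map68, cfg)
        assert panel.values.shape == (68, 17)
        informative = [
            j for j, p in enumerate(panel.provenance) if p == "informative"
        ]
        assert informative == sorted(cfg.informative_features)

    def test_deterministic(self, meta68, smooth_map68):
        cfg = tg.SimulationConfig(seed=9)
        a = tg.simulate_feature_panel(meta68, smooth_map68, cfg)
        b = tg.simulate_feature_panel(meta68, smooth_map68, cfg)
        np.testing.assert_array_equal(a.values, b.values)
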