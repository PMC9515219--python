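"""Similarity matrices and diffusion-map gradients against dense oracles."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import transgrad as tg
from transgrad.gradients import (
    build_mpc,
    diffusion_map_embedding,
    fisher_z_matrix,
    normalized_angle_affinity,
    sparsify_rows,
)


def _random_affinity(meta, seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.1, 1.0, (meta.n_regions, meta.n_regions))
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 1.0)
    return tg.ConnectivityMatrix(a, meta, kind="affinity")


class TestMPC:
    def _profiles(self, meta, seed=0, n_depths=12):
        rng = np.random.default_rng(seed)
        rows = rng.uniform(1, 3, (meta.n_regions, n_depths))
        return tg.ProfileSet(rows, np.linspace(0, 1, n_depths), meta)

    def test_matches_regression_residual_oracle(self):
        meta = tg.make_parcellation(tg.SimulationConfig(n_regions_per_hemisphere=3))
        prof = self._profiles(meta, seed=1)  # 6 regions is enough for the oracle
        x = prof.intensities
        mean_profile = x.mean(axis=0)
        resid = []
        for row in x:  # brute force: residual of each profile on the mean profile
            design = np.column_stack([np.ones_like(mean_profile), mean_profile])
            beta = np.linalg.lstsq(design, row, rcond=None)[0]
            resid.append(row - design @ beta)
        resid = np.array(resid)
        expected = np.corrcoef(resid)
        mpc = build_mpc(prof)
        n = meta.n_regions
        for i in range(n):
            for j in range(i + 1, n):
                r = expected[i, j]
                want = np.log(r / (1 - r)) if r > 0 else 0.0
                assert mpc.values[i, j] == pytest.approx(want, abs=1e-10)

    def test_identical_residuals_hit_finite_cap(self, meta20):
        x = self._profiles(meta20, seed=2).intensities.copy()
        x[1] = x[0]  # identical profiles -> partial correlation 1
        prof = tg.ProfileSet(x, np.linspace(0, 1, x.shape[1]), meta20)
        mpc = build_mpc(prof)
        cap = np.log((1 - 1e-9) / 1e-9)
        assert mpc.values[0, 1] == pytest.approx(cap, rel=1e-6)
        assert np.isfinite(mpc.values).all()

    def test_symmetric_zero_diagonal_thresholded(self, meta68):
        prof = self._profiles(meta68, seed=3)
        mpc = build_mpc(prof)
        assert mpc.is_symmetric(1e-12)
        assert np.all(np.diag(mpc.values) == 0)
        # negative partial correlations are zeroed before the log transform,
        # so every nonzero entry is the log-odds of a positive correlation
        x = prof.intensities
        mean_profile = x.mean(axis=0)
        design = np.column_stack([np.ones_like(mean_profile), mean_profile])
        beta = np.linalg.lstsq(design, x.T, rcond=None)[0]
        r = np.corrcoef((x.T - design @ beta).T)
        assert np.all(mpc.values[r <= 0] == 0)

    def test_too_few_regions_rejected(self):
        meta = tg.make_parcellation(tg.SimulationConfig(n_regions_per_hemisphere=1))
        with pytest.raises(ValueError):
            build_mpc(self._profiles(meta))


class TestFisherZ:
    def test_fixed_point_and_oracle(self, meta20):
        r = np.zeros((20, 20))
        r[0, 1] = r[1, 0] = 0.5
        z = fisher_z_matrix(tg.ConnectivityMatrix(r, meta20))
        assert z.values[0, 1] == pytest.approx(0.5493061443340549, abs=1e-12)
        assert z.values[2, 3] == 0.0

    def test_odd_function(self, meta20):
        rng = np.random.default_rng(0)
        r = np.clip(rng.uniform(-0.99, 0.99, (20, 20)), -1, 1)
        r = 0.5 * (r + r.T)
        z_pos = fisher_z_matrix(tg.ConnectivityMatrix(r, meta20))
        z_neg = fisher_z_matrix(tg.ConnectivityMatrix(-r, meta20))
        np.testing.assert_allclose(z_neg.values, -z_pos.values, atol=1e-12)

    def test_out_of_range_rejected(self, meta20):
        r = np.zeros((20, 20))
        r[0, 1] = 1.5
        with pytest.raises(ValueError):
            fisher_z_matrix(tg.ConnectivityMatrix(r, meta20))


class TestSparsify:
    def test_count_per_row(self, meta20):
        mat = _random_affinity(meta20, 1)
        half = meta20.subset(meta20.region_id[:10])
        small = tg.ConnectivityMatrix(mat.values[:10, :10], half)
        out = sparsify_rows(small, 0.1)
        assert np.all((out.values != 0).sum(axis=1) == 1)

    def test_survivors_match_sort_oracle(self, meta20):
        mat = _random_affinity(meta20, 2)
        out = sparsify_rows(mat, 0.3)
        k = int(np.ceil(0.3 * 20))
        for i in range(20):
            off = [(mat.values[i, j], j) for j in range(20) if j != i]
            keep = {j for _, j in sorted(off, key=lambda t: (-t[0], t[1]))[:k]}
            assert set(np.flatnonzero(out.values[i])) == keep

    def test_full_density_is_identity_off_diagonal(self, meta20):
        mat = _random_affinity(meta20, 3)
        out = sparsify_rows(mat, 1.0)
        off = ~np.eye(20, dtype=bool)
        np.testing.assert_array_equal(out.values[off], mat.values[off])

    def test_ties_break_to_lower_column(self, meta20):
        a = np.ones((20, 20))
        out = sparsify_rows(tg.ConnectivityMatrix(a, meta20), 0.1)
        assert set(np.flatnonzero(out.values[0])) == {1, 2}
        assert set(np.flatnonzero(out.values[5])) == {0, 1}


class TestAffinity:
    def test_row_geometry_cases(self, meta20):
        a = np.zeros((20, 20))
        a[0] = a[1] = [1.0] * 20  # identical
        a[2, :10] = 1.0  # orthogonal to row 3
        a[3, 10:] = 1.0
        a[4] = 1.0
        a[5] = -a[4]  # opposite
        a[6:] = np.random.default_rng(0).uniform(0.1, 1, (14, 20))
        aff = normalized_angle_affinity(tg.ConnectivityMatrix(a, meta20))
        # arccos loses ~sqrt(eps) precision at the endpoints
        assert aff.values[0, 1] == pytest.approx(1.0, abs=1e-7)
        assert aff.values[2, 3] == pytest.approx(0.5, abs=1e-12)
        assert aff.values[4, 5] == pytest.approx(0.0, abs=1e-7)

    def test_zero_row_names_region(self, meta20):
        a = np.ones((20, 20))
        a[7] = 0.0
        with pytest.raises(ValueError, match=meta20.region_id[7]):
            normalized_angle_affinity(tg.ConnectivityMatrix(a, meta20))


class TestEmbedding:
    def test_two_block_bipartition(self, meta20):
        half = meta20.subset(meta20.region_id[:10])
        w = np.zeros((10, 10))
        w[:5, :5] = 0.9
        w[5:, 5:] = 0.9
        w += 0.001  # weak bridge keeps the graph connected
        np.fill_diagonal(w, 1.0)
        res = diffusion_map_embedding(
            tg.ConnectivityMatrix(w, half), n_components=2
        )
        g1 = res.gradients[:, 0]
        assert len(set(np.sign(g1[:5]))) == 1
        assert np.sign(g1[0]) != np.sign(g1[5])

    def test_matches_dense_eigensolver_oracle(self, meta20):
        """Embedding equals eig() of the same density-normalized transition
        operator (up to sign), including the lambda/(1-lambda) scaling."""
        for seed in range(5):
            aff = _random_affinity(meta20, seed + 10)
            res = diffusion_map_embedding(aff, alpha=0.5, n_components=4)
            w = aff.values
            d = w.sum(axis=1) ** -0.5
            w1 = w * np.outer(d, d)
            p = w1 / w1.sum(axis=1, keepdims=True)
            evals, evecs = np.linalg.eig(p)
            order = np.argsort(evals.real)[::-1]
            evals, evecs = evals.real[order], evecs.real[:, order]
            for j in range(4):
                lam = evals[j + 1]
                vec = evecs[:, j + 1] / np.linalg.norm(evecs[:, j + 1])
                vec = vec * lam / (1 - lam)
                got = res.gradients[:, j]
                assert min(
                    np.max(np.abs(got - vec)), np.max(np.abs(got + vec))
                ) < 1e-8
            np.testing.assert_allclose(res.eigenvalues, evals[1:5], atol=1e-10)

    def test_eigenvalues_in_unit_interval(self, meta20):
        res = diffusion_map_embedding(_random_affinity(meta20, 3), n_components=5)
        assert np.all(res.eigenvalues <= 1.0 + 1e-12)
        assert np.all(res.eigenvalues > -1.0)
        assert np.all(np.diff(np.abs(res.eigenvalues)) <= 1e-12)

    def test_relabeling_invariance(self, meta20):
        aff = _random_affinity(meta20, 4)
        res = diffusion_map_embedding(aff, n_components=3)
        rng = np.random.default_rng(1)
        perm = rng.permutation(20)
        meta_p = tg.ParcellationMeta(
            [meta20.region_id[i] for i in perm],
            [meta20.hemisphere[i] for i in perm],
            meta20.centroid[perm],
            [meta20.community[i] for i in perm],
            [meta20.hierarchy[i] for i in perm],
        )
        aff_p = tg.ConnectivityMatrix(aff.values[np.ix_(perm, perm)], meta_p)
        res_p = diffusion_map_embedding(aff_p, n_components=3)
        for j in range(3):
            a, b = res.gradients[perm, j], res_p.gradients[:, j]
            assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-8

    def test_disconnected_graph_lists_components(self, meta20):
        w = np.zeros((20, 20))
        w[:10, :10] = 1.0
        w[10:, 10:] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_map_embedding(tg.ConnectivityMatrix(w, meta20), n_components=2)

    def test_asymmetric_input_rejected(self, meta20):
        w = np.ones((20, 20))
        w[0, 1] = 2.0
        with pytest.raises(ValueError, match="symmetric"):
            diffusion_map_embedding(tg.ConnectivityMatrix(w, meta20), n_components=2)

    def test_pipeline_deterministic(self, meta68, smooth_map68):
        conn = tg.simulate_connectivity(meta68, smooth_map68, noise=0.05, seed=1)
        a = tg.connectivity_gradients(conn, n_components=3)
        b = tg.connectivity_gradients(conn, n_components=3)
        np.testing.assert_array_equal(a.gradients, b.gradients)
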