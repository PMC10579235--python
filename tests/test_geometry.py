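"""Soft-normalized PCA, signal-dimension estimation, projection, bootstrap."""

import numpy as np
import pytest

from popdyn.geometry import (
    bootstrap_trajectories,
    estimate_signal_dims,
    fit_pca,
    fit_pca_tensor,
    project,
    soft_normalize_stack,
)
from popdyn.rates import PerTrialRates, RateTensor


def _tensor(values, time_axis=None):
    T = values.shape[0]
    return RateTensor(
        values=values,
        time_axis=np.arange(T, dtype=float) if time_axis is None else time_axis,
        condition_labels=list(range(values.shape[2])),
        unit_ids=[f"u{i}" for i in range(values.shape[1])],
    )


class TestSoftNormalize:
    def test_constant_unit_becomes_zero_column(self):
        vals = np.random.default_rng(0).gamma(2.0, 5.0, size=(50, 3, 2, 2))
        vals[:, 1] = 7.5  # constant-rate unit
        mat, means, norm, _ = soft_normalize_stack(_tensor(vals))
        np.testing.assert_allclose(mat[:, 1], 0.0, atol=1e-12)

    def test_divisor_is_sqrt_p99(self):
        vals = np.zeros((200, 1, 1, 2))
        vals[:, 0, 0, 0] = np.linspace(0, 25.0 / 0.99, 200)  # 99th pct = 25
        vals[:, 0, 0, 1] = vals[:, 0, 0, 0]
        _, _, norm, _ = soft_normalize_stack(_tensor(vals))
        assert norm[0] == pytest.approx(5.0, rel=1e-2)

    def test_sqrt_normalizer_equivariance(self):
        # scaling a unit's rates by a scales its normalized column by
        # sqrt(a): the sqrt-of-p99 divisor halves, not cancels, a 4x gain
        rng = np.random.default_rng(1)
        base = rng.gamma(2.0, 5.0, size=(60, 1, 2, 2))
        vals = np.concatenate([base, 4.0 * base], axis=1)
        mat, _, _, _ = soft_normalize_stack(_tensor(vals))
        np.testing.assert_allclose(2.0 * mat[:, 0], mat[:, 1], atol=1e-10)

    def test_left_stacked_above_right(self):
        vals = np.zeros((10, 1, 1, 2))
        vals[:, 0, 0, 0] = 1.0  # left
        vals[:, 0, 0, 1] = 3.0  # right
        mat, means, norm, blocks = soft_normalize_stack(_tensor(vals))
        # rows 0..9 from left block, rows 10..19 from right block
        assert mat[0, 0] < mat[-1, 0]


class TestFitPCA:
    def test_rank2_eigenvalue_cutoff(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(100, 2)) @ rng.normal(size=(2, 8))
        mat -= mat.mean(axis=0)
        pcs = fit_pca(mat)
        assert np.all(pcs.eigenvalues[2:] < 1e-10)
        assert np.all(np.diff(pcs.eigenvalues) <= 1e-12)

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(80, 6))
        mat -= mat.mean(axis=0)
        pcs = fit_pca(mat)
        np.testing.assert_allclose(
            pcs.loadings.T @ pcs.loadings, np.eye(6), atol=1e-10
        )
        for k in range(6):
            col = pcs.loadings[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_isotropic_variance_flat(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(20000, 10))
        mat -= mat.mean(axis=0)
        pcs = fit_pca(mat)
        ratios = pcs.explained_variance_ratio
        assert ratios.max() / ratios.min() < 1.2

    def test_nonfinite_rejected(self):
        mat = np.ones((10, 3))
        mat[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_pca(mat)


class TestProject:
    def test_projection_reproduces_scores(self):
        rng = np.random.default_rng(5)
        vals = rng.gamma(2.0, 5.0, size=(40, 6, 2, 2))
        tensor = _tensor(vals)
        mat, means, norm, _ = soft_normalize_stack(tensor)
        pcs = fit_pca(mat, normalizers=norm, column_means=means)
        trajset = project(tensor, pcs, n_dims=6)
        scores = mat @ pcs.loadings
        stacked = np.vstack(trajset.trajectories)
        np.testing.assert_allclose(stacked, scores, atol=1e-10)

    def test_rank1_reconstruction(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 1, 30)
        vals = np.zeros((30, 4, 1, 2))
        w = rng.uniform(1, 2, size=4)
        for k in range(2):
            vals[:, :, 0, k] = np.outer(t + k, w)
        tensor = _tensor(vals)
        mat, means, norm, _ = soft_normalize_stack(tensor)
        pcs = fit_pca(mat, normalizers=norm, column_means=means)
        trajset = project(tensor, pcs, n_dims=1)
        recon = np.vstack(trajset.trajectories) @ pcs.loadings[:, :1].T
        np.testing.assert_allclose(recon, mat, atol=1e-10)

    def test_full_reconstruction_exact(self):
        rng = np.random.default_rng(7)
        vals = rng.gamma(2.0, 5.0, size=(25, 5, 2, 2))
        tensor = _tensor(vals)
        mat, means, norm, _ = soft_normalize_stack(tensor)
        pcs = fit_pca(mat, normalizers=norm, column_means=means)
        recon = (mat @ pcs.loadings) @ pcs.loadings.T
        np.testing.assert_allclose(recon, mat, atol=1e-8)

    def test_dim_and_unit_mismatch(self):
        rng = np.random.default_rng(8)
        vals = rng.gamma(2.0, 5.0, size=(25, 5, 1, 2))
        tensor = _tensor(vals)
        pcs = fit_pca_tensor(tensor)
        with pytest.raises(ValueError):
            project(tensor, pcs, n_dims=9)
        other = _tensor(rng.gamma(2.0, 5.0, size=(25, 4, 1, 2)))
        with pytest.raises(ValueError):
            project(other, pcs, n_dims=2)


class TestSignalDims:
    def _planted(self, rank, noise_scale, rng, T=100, N=40, M=60, n_cond=2):
        U = rng.normal(size=(rank, N))
        scales = np.linspace(4.0, 1.5, rank)
        out = {}
        for c in range(n_cond):
            lat = rng.normal(size=(T, rank)) * scales
            out[c] = (lat @ U)[None] + rng.normal(
                scale=noise_scale, size=(M, T, N)
            ) + 10.0
        return out

    def test_duplicate_trials_zero_noise(self):
        rng = np.random.default_rng(0)
        arr = self._planted(3, 1.0, rng)[0][:1].repeat(8, axis=0)
        est = estimate_signal_dims({0: arr}, n_boot=5, rng=0)
        assert est.noise_eigs.max() == pytest.approx(0.0, abs=1e-20)
        assert est.n_signal_dims == est.signal_plus_noise_eigs.shape[0]

    def test_planted_rank4_recovered(self):
        rng = np.random.default_rng(1)
        est = estimate_signal_dims(self._planted(4, 1.0, rng), n_boot=30, rng=2)
        assert est.n_signal_dims == 4

    def test_planted_rank_majority_over_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            est = estimate_signal_dims(self._planted(4, 1.0, rng), n_boot=20, rng=seed)
            hits += est.n_signal_dims == 4
        assert hits >= 7

    def test_pure_noise_zero_dims(self):
        rng = np.random.default_rng(3)
        data = {c: rng.normal(size=(60, 100, 40)) + 10.0 for c in range(2)}
        est = estimate_signal_dims(data, n_boot=20, rng=4)
        assert est.n_signal_dims == 0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_signal_dims({0: np.zeros((1, 10, 4))})


class TestBootstrapTrajectories:
    def _per_trial(self, rng, n_trials=12, T=60, n_units=5):
        trials = []
        from popdyn.session import TrialRecord

        per = {}
        for i in range(n_trials):
            trials.append(
                TrialRecord(i, 13.6, "left" if i % 2 == 0 else "right", True,
                            500.0, 700.0, 1200.0)
            )
        for u in range(n_units):
            rates = rng.gamma(2.0, 5.0, size=(n_trials, T))
            per[f"u{u}"] = PerTrialRates(
                rates=rates, time_axis=np.arange(-30.0, 30.0), event="checkerboard"
            )
        return per, trials

    def test_identity_resampling_equals_point_estimate(self):
        rng = np.random.default_rng(9)
        per, trials = self._per_trial(rng)
        boots = bootstrap_trajectories(
            per, trials, grouping="coherence", n_dims=2, n_boot=1, seed=0,
            resample=False,
        )
        from popdyn.rates import condition_average

        tensor = condition_average(per, trials, grouping="coherence")
        pcs = fit_pca_tensor(tensor)
        point = project(tensor, pcs, n_dims=2)
        for a, b in zip(boots[0].trajectories, point.trajectories):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(10)
        per, trials = self._per_trial(rng)
        b1 = bootstrap_trajectories(per, trials, "coherence", n_dims=2, n_boot=3, seed=5)
        b2 = bootstrap_trajectories(per, trials, "coherence", n_dims=2, n_boot=3, seed=5)
        for s1, s2 in zip(b1, b2):
            for a, b in zip(s1.trajectories, s2.trajectories):
                np.testing.assert_array_equal(a, b)

    def test_sem_shrinks_with_trial_count(self):
        # quadrupling trials should roughly halve the bootstrap SEM of a
        # trajectory coordinate (CLT scaling)
        sems = []
        for n_trials in (16, 64):
            rng = np.random.default_rng(11)
            per, trials = self._per_trial(rng, n_trials=n_trials)
            boots = bootstrap_trajectories(
                per, trials, "coherence", n_dims=1, n_boot=25, seed=7
            )
            coord = np.array([b.trajectories[0][5, 0] for b in boots])
            sems.append(coord.std(ddof=1))
        ratio = sems[0] / sems[1]
        assert 1.3 < ratio < 3.2
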