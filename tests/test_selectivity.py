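"""Choice-selectivity curve, piecewise latency fit, initial-condition axis,
partial correlations."""

import numpy as np
import pytest

from popdyn.selectivity import (
    ChoiceSelectivityCurve,
    cs_curve,
    fit_piecewise_cs,
    initial_condition_axis,
    partial_corr,
)


class TestCSCurve:
    def test_identical_trajectories_zero(self):
        traj = np.random.default_rng(0).normal(size=(50, 6))
        out = cs_curve(traj, traj.copy())
        np.testing.assert_allclose(out.cs, 0.0, atol=1e-12)

    def test_constant_offset(self):
        rng = np.random.default_rng(1)
        left = rng.normal(size=(40, 6))
        offset = np.zeros(6)
        offset[2] = 2.0
        out = cs_curve(left, left + offset)
        np.testing.assert_allclose(out.cs, 2.0, atol=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        left = rng.normal(size=(40, 6))
        right = rng.normal(size=(40, 6))
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        a = cs_curve(left, right).cs
        b = cs_curve(left @ Q, right @ Q).cs
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cs_curve(np.zeros((10, 6)), np.zeros((10, 5)))

    def test_sim1_flat_prestim_rising_postcue(self, sim1_session):
        from popdyn import geometry
        from popdyn.rates import compute_rate_tensor

        tensor = compute_rate_tensor(
            sim1_session, grouping="rt", window=(-400.0, 600.0),
            units=range(0, 350, 5),
        )
        pcs = geometry.fit_pca_tensor(tensor)
        ts = geometry.project(tensor, pcs, n_dims=6)
        lab = tensor.condition_labels[5]
        li = ts.labels.index(("left", lab))
        ri = ts.labels.index(("right", lab))
        curve = cs_curve(ts.trajectories[li], ts.trajectories[ri], ts.times[li])
        pre = curve.cs[curve.times < -50.0]
        post = curve.cs[curve.times > 300.0]
        assert np.mean(post) > 3.0 * np.mean(pre)


def _piecewise(times, b, m, tl):
    y = np.full_like(times, b, dtype=float)
    post = times > tl
    y[post] = m * (times[post] - tl) ** 2
    return y


class TestPiecewiseFit:
    def test_noiseless_recovery(self):
        times = np.arange(-200.0, 400.0, 5.0)
        y = _piecewise(times, b=1.0, m=1e-4, tl=150.0)
        fit = fit_piecewise_cs(ChoiceSelectivityCurve(times, y))
        assert fit.t_latency == pytest.approx(150.0)
        assert fit.b == pytest.approx(1.0, abs=1e-12)
        assert fit.m == pytest.approx(1e-4, rel=1e-9)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)

    def test_constant_curve_flat_flag(self):
        times = np.arange(0.0, 100.0, 2.0)
        fit = fit_piecewise_cs(ChoiceSelectivityCurve(times, np.full_like(times, 3.3)))
        assert fit.flat
        assert fit.m == pytest.approx(0.0, abs=1e-8)
        assert fit.t_latency == pytest.approx(times[-1])

    def test_noisy_latency_bias_below_grid_step(self):
        # 5%-of-plateau noise: mean latency error under one grid step
        rng = np.random.default_rng(3)
        times = np.arange(-200.0, 400.0, 5.0)
        b, tl = 1.0, 150.0
        m = 4.0 * b / (times[-1] - tl) ** 2  # plateau 4b at window end
        clean = _piecewise(times, b, m, tl)
        plateau = clean.max()
        errs = []
        for _ in range(100):
            y = clean + rng.normal(scale=0.05 * plateau, size=len(times))
            fit = fit_piecewise_cs(ChoiceSelectivityCurve(times, y))
            errs.append(fit.t_latency - tl)
        assert abs(np.mean(errs)) < 5.0

    def test_random_parameter_recovery(self):
        rng = np.random.default_rng(4)
        times = np.arange(-200.0, 400.0, 5.0)
        for _ in range(20):
            b = rng.uniform(0.5, 2.0)
            tl = times[rng.integers(20, 90)]
            m = rng.uniform(2.0, 6.0) * b / (times[-1] - tl) ** 2
            clean = _piecewise(times, b, m, tl)
            y = clean + rng.normal(scale=0.1 * clean.max(), size=len(times))
            fit = fit_piecewise_cs(ChoiceSelectivityCurve(times, y))
            assert abs(fit.t_latency - tl) <= 50.0

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            fit_piecewise_cs(
                ChoiceSelectivityCurve(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
            )


class TestInitialConditionAxis:
    def test_identical_cells_zero_scores(self):
        cells = {(c, r): np.ones(12) for c in range(7) for r in range(11)}
        ica = initial_condition_axis(cells)
        np.testing.assert_allclose(ica.scores, 0.0, atol=1e-12)

    def test_planted_line_order_recovered(self):
        rng = np.random.default_rng(5)
        direction = rng.normal(size=12)
        direction /= np.linalg.norm(direction)
        cells = {}
        centers = {}
        for c in range(7):
            for r in range(11):
                pos = -(r + 0.1 * c)  # decreasing along RT bins
                cells[(c, r)] = pos * direction
                centers[r] = float(r)
        ica = initial_condition_axis(cells, rt_bin_centers=centers)
        assert len(ica.scores) == 77
        assert np.linalg.norm(ica.axis) == pytest.approx(1.0)
        # scores reproduce the planted ordering within each coherence
        labs = ica.cell_labels
        for c in range(7):
            s = [ica.scores[labs.index((c, r))] for r in range(11)]
            assert np.all(np.diff(s) < 0)

    def test_missing_cells_listed(self):
        cells = {(0, 0): np.ones(12), (0, 1): np.full(12, np.nan)}
        with pytest.raises(ValueError, match="missing"):
            initial_condition_axis(cells)

    def test_sim3_ic_scores_track_rt(self, sim3_trajectories):
        # prestimulus mean state per RT bin correlates with RT-bin center
        # (sign convention: negative with RT)
        from scipy.stats import spearmanr

        from popdyn.session import make_rt_bins

        ts = sim3_trajectories
        bins = make_rt_bins("overlapping")
        cells, centers = {}, {}
        for bi, lab in enumerate([l for ch, l in ts.labels if ch == "left"]):
            parts = []
            for choice in ("left", "right"):
                i = ts.labels.index((choice, lab))
                tax = ts.times[i]
                sel = (tax >= -400.0) & (tax <= -100.0)
                parts.append(ts.trajectories[i][sel].mean(axis=0))
            cells[(0, bi)] = np.concatenate(parts)
            centers[bi] = bins.centers[bi]
        ica = initial_condition_axis(cells, rt_bin_centers=centers)
        order = [ica.scores[ica.cell_labels.index((0, b))] for b in range(11)]
        rho = spearmanr(order, [centers[b] for b in range(11)]).statistic
        assert rho < -0.9


class TestPartialCorr:
    def test_exact_dependence(self):
        rng = np.random.default_rng(6)
        x1 = rng.normal(size=60)
        x2 = rng.normal(size=60)
        r1, r2 = partial_corr(x1, x1, x2)
        assert r1 == pytest.approx(1.0, abs=1e-10)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=4000)
        x1 = rng.normal(size=4000)
        x2 = rng.normal(size=4000)
        r1, r2 = partial_corr(y, x1, x2)
        assert abs(r1) < 0.06 and abs(r2) < 0.06

    def test_symmetric_orthogonal_sum(self):
        # y = x1 + x2 with orthogonal regressors: equal positive partials
        n = 400
        t = np.arange(n)
        x1 = np.cos(2 * np.pi * t / n)
        x2 = np.sin(2 * np.pi * t / n)
        y = x1 + x2
        r1, r2 = partial_corr(y, x1, x2)
        assert r1 == pytest.approx(1.0, abs=1e-8)
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError):
            partial_corr([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"y": rng.normal(size=50), "x1": rng.normal(size=50), "x2": rng.normal(size=50)}
        )
        df["y"] += 0.5 * df["x1"] - 0.3 * df["x2"]
        r1, r2 = partial_corr(df["y"], df["x1"], df["x2"])
        ref1 = pingouin.partial_corr(df, x="x1", y="y", covar="x2")["r"].iloc[0]
        ref2 = pingouin.partial_corr(df, x="x2", y="y", covar="x1")["r"].iloc[0]
        assert r1 == pytest.approx(ref1, abs=1e-8)
        assert r2 == pytest.approx(ref2, abs=1e-8)
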