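"""Choice selectivity and initial-condition analyses.

The choice-selectivity signal CS(t) is the Euclidean distance between the
left-choice and right-choice trajectories in the leading PCs.  Its onset is
characterized by a discontinuous piecewise fit: CS(t) = b (baseline) up to
a latency, then a quadratic rise m*(t - t_latency)^2.  The *initial
condition* of a (coherence x RT-bin) cell is its average prestimulus
(-400 to -100 ms) six-dimensional state for both choices concatenated into
a 12-vector; the top principal component of the cell x coordinate matrix
scores each cell's initial condition, oriented so scores correlate
negatively with RT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ChoiceSelectivityCurve",
    "PiecewiseFit",
    "InitialConditionAxis",
    "cs_curve",
    "fit_piecewise_cs",
    "initial_condition_axis",
    "partial_corr",
]


@dataclass
class ChoiceSelectivityCurve:
    times: np.ndarray
    cs: np.ndarray  # Euclidean distance, normalized-rate units


@dataclass
class PiecewiseFit:
    b: float
    m: float
    t_latency: float
    sse: float
    flat: bool = False  # set when the curve never rises above baseline


@dataclass
class InitialConditionAxis:
    axis: np.ndarray  # unit-norm loading over the concatenated coordinates
    scores: np.ndarray  # one IC scalar per cell
    cell_labels: list  # (coherence, rt_bin) per row


def cs_curve(left_traj: np.ndarray, right_traj: np.ndarray,
             times: np.ndarray | None = None) -> ChoiceSelectivityCurve:
    """CS(t) = ||Omega_L(t) - Omega_R(t)||_2 on the shared time axis."""
    L = np.asarray(left_traj, dtype=float)
    R = np.asarray(right_traj, dtype=float)
    if L.ndim != 2 or R.ndim != 2 or L.shape[1] != R.shape[1]:
        raise ValueError("trajectories must be 2-D with equal dimensionality")
    n = min(L.shape[0], R.shape[0])
    cs = np.linalg.norm(L[:n] - R[:n], axis=1)
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, dtype=float)[:n]
    return ChoiceSelectivityCurve(times=t, cs=cs)


def fit_piecewise_cs(
    curve: ChoiceSelectivityCurve, window: tuple[float, float] | None = None
) -> PiecewiseFit:
    """Fit CS(t) = b for t <= t_latency, m*(t-t_latency)^2 after.

    The latency is found by grid search over the curve's timepoints; at
    each candidate, b (mean of the pre segment) and m (closed-form
    least-squares on the post segment) are optimal, and the global SSE
    minimizer wins (earliest on ties).  The model is discontinuous at the
    latency by construction.
    """
    t = curve.times
    y = curve.cs
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, y = t[sel], y[sel]
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints in the fitting window")

    best = (np.inf, None, None, None)
    # candidate latencies leave >=1 pre point and >=2 post points
    for k in range(1, len(t) - 2):
        tl = t[k]
        pre, post = y[: k + 1], y[k + 1 :]
        dt2 = (t[k + 1 :] - tl) ** 2
        b = pre.mean()
        denom = np.sum(dt2**2)
        m = np.sum(post * dt2) / denom if denom > 0 else 0.0
        sse = np.sum((pre - b) ** 2) + np.sum((post - m * dt2) ** 2)
        if sse < best[0] - 1e-12:
            best = (sse, b, m, tl)
    sse, b, m, tl = best
    # a constant model doing as well as the best piecewise fit means the
    # curve never rises: report the window end with a flatness flag
    sse_const = float(np.sum((y - y.mean()) ** 2))
    flat = sse_const <= sse + 1e-12
    if flat:
        tl = float(t[-1])
        b = float(y.mean())
        sse = sse_const
        m = 0.0
    return PiecewiseFit(b=float(b), m=float(m), t_latency=float(tl), sse=float(sse), flat=flat)


def initial_condition_axis(
    cell_states: Mapping[tuple, np.ndarray],
    rt_bin_centers: Mapping | None = None,
) -> InitialConditionAxis:
    """Initial-condition axis from prestimulus states per (coherence, RT-bin).

    ``cell_states`` maps (coherence, rt_bin) -> concatenated per-choice
    prestimulus mean state (e.g. 12 values: 6 PCs x 2 choices).  Rows are
    centered and the top principal component's scores are returned as the
    IC values; the axis sign is chosen so that scores correlate negatively
    with the RT-bin centers (``rt_bin_centers`` maps rt_bin label ->
    center; defaults to the label itself).
    """
    labels = sorted(cell_states)
    X = np.vstack([np.asarray(cell_states[k], dtype=float).ravel() for k in labels])
    if not np.all(np.isfinite(X)):
        bad = [labels[i] for i in np.flatnonzero(~np.all(np.isfinite(X), axis=1))]
        raise ValueError(f"missing cells: {bad}")
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    axis = vt[0]
    scores = Xc @ axis
    if rt_bin_centers is not None:
        centers = np.array([rt_bin_centers[k[1]] for k in labels], dtype=float)
    else:
        centers = np.array([float(k[1]) for k in labels])
    if np.std(centers) > 0 and np.std(scores) > 0:
        r = np.corrcoef(scores, centers)[0, 1]
        if r > 0:
            axis = -axis
            scores = -scores
    return InitialConditionAxis(axis=axis, scores=scores, cell_labels=labels)


def partial_corr(
    y: Sequence[float], x1: Sequence[float], x2: Sequence[float]
) -> tuple[float, float]:
    """Partial Pearson correlations (r_{y,x1|x2}, r_{y,x2|x1}).

    Each is the correlation between OLS residuals after regressing out the
    other covariate from both sides.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    for name, v in (("x1", x1), ("x2", x2)):
        if np.std(v) == 0:
            raise ValueError(f"constant regressor {name}: partial correlation undefined")

    def _resid(a, b):
        X = np.column_stack([np.ones_like(b), b])
        beta, *_ = np.linalg.lstsq(X, a, rcond=None)
        return a - X @ beta

    def _corr(a, b):
        sa, sb = np.std(a), np.std(b)
        if sa < 1e-300 or sb < 1e-300:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    r1 = _corr(_resid(y, x2), _resid(x1, x2))
    r2 = _corr(_resid(y, x1), _resid(x2, x1))
    return r1, r2
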