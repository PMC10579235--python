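"""Single-trial dynamical-system fits.

Two complementary models of how population activity evolves:

* **Autonomous linear dynamical system (LDS).**  Single-trial activity is
  binned at 50 ms, projected onto its top principal components, and the
  change in activity over a 100 ms horizon is modeled as a fixed linear
  flow field: ``Xdot(:, :, m) ~ X(:, :, m) J`` for every trial m.  J is the
  joint closed-form least-squares solution over training trials, and fit
  quality is the leave-one-trial-out cross-validated R^2 (1 minus the
  normalized held-out error).
* **Reduced-rank regression (RRR).**  Activity at time t is predicted from
  activity at t0 plus task covariates; the OLS coefficient matrix is
  truncated to rank s via the SVD of the fitted values (optimal by the
  Eckart-Young theorem), and the rank is chosen on a held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LDSFit",
    "RRRFit",
    "latents_from_counts",
    "fit_lds",
    "lds_rt_regression",
    "fit_rrr",
]


@dataclass
class LDSFit:
    J: np.ndarray
    latent_dim: int
    cv_r2: float
    epoch: str
    train_r2: float = np.nan


@dataclass
class RRRFit:
    beta: np.ndarray  # (q, p) rank-constrained coefficients
    rank: int
    candidate_ranks: list
    val_mse: np.ndarray
    cv_r2: float
    beta_ols: np.ndarray | None = None


def latents_from_counts(counts: np.ndarray, latent_dim: int) -> np.ndarray:
    """Project (trials, time, units) single-trial counts onto top PCs.

    PCA is fit on the pooled (trial*time, units) matrix; returns
    (trials, time, latent_dim) scores.
    """
    m, t, n = counts.shape
    flat = counts.reshape(m * t, n)
    mu = flat.mean(axis=0)
    _, _, vt = np.linalg.svd(flat - mu, full_matrices=False)
    if latent_dim > vt.shape[0]:
        raise ValueError(f"latent_dim={latent_dim} exceeds available components")
    return ((flat - mu) @ vt[:latent_dim].T).reshape(m, t, latent_dim)


def _pairs(latents: np.ndarray, horizon_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack (state, forward-difference) pairs across a trial."""
    X = latents[:, :-horizon_bins, :]
    Xdot = latents[:, horizon_bins:, :] - X
    return X, Xdot


def fit_lds(
    latents: np.ndarray,
    epoch: str = "prestimulus",
    bin_ms: float = 50.0,
    horizon_ms: float = 100.0,
) -> LDSFit:
    """Fit the dynamics matrix J of an autonomous LDS to latent trajectories.

    ``latents`` has shape (trials, time_bins, latent_dim); the derivative is
    the forward difference at the ``horizon_ms`` horizon (2 bins at the
    default 50 ms binning).  J minimizes the pooled normalized Frobenius
    error over all training trials; ``cv_r2`` is leave-one-trial-out.
    """
    if latents.ndim != 3:
        raise ValueError("latents must be (trials, time, dim)")
    m, t, d = latents.shape
    if m < 3:
        raise ValueError("need at least 3 trials")
    horizon_bins = max(int(round(horizon_ms / bin_ms)), 1)
    if t <= horizon_bins:
        raise ValueError("too few time bins for the requested horizon")

    X, Xdot = _pairs(latents, horizon_bins)
    Xf = X.reshape(-1, d)
    Df = Xdot.reshape(-1, d)
    J, *_ = np.linalg.lstsq(Xf, Df, rcond=None)
    denom = np.sum(Df**2)
    train_r2 = 1.0 - np.sum((Df - Xf @ J) ** 2) / denom if denom > 0 else np.nan

    cv = []
    for mtest in range(m):
        train = np.ones(m, dtype=bool)
        train[mtest] = False
        Xt = X[train].reshape(-1, d)
        Dt = Xdot[train].reshape(-1, d)
        Jt, *_ = np.linalg.lstsq(Xt, Dt, rcond=None)
        Xh, Dh = X[mtest], Xdot[mtest]
        den = np.sum(Dh**2)
        if den > 0:
            cv.append(1.0 - np.sum((Dh - Xh @ Jt) ** 2) / den)
    return LDSFit(
        J=J,
        latent_dim=d,
        cv_r2=float(np.mean(cv)) if cv else np.nan,
        epoch=epoch,
        train_r2=float(train_r2),
    )


def lds_rt_regression(
    latents: np.ndarray, fit: LDSFit, rts: Sequence[float],
    horizon_bins: int = 2,
) -> np.ndarray:
    """Per-time-bin R^2 of OLS regression of RT on LDS-predicted latents.

    The model's one-step prediction ``X(t) + X(t) J`` replaces the observed
    activity at t + horizon; each predicted bin is regressed against RT.
    """
    rt = np.asarray(rts, dtype=float)
    pred = latents[:, :-horizon_bins, :] + latents[:, :-horizon_bins, :] @ fit.J
    m, t, d = pred.shape
    out = np.zeros(t)
    sst = np.sum((rt - rt.mean()) ** 2)
    for b in range(t):
        Xb = np.column_stack([np.ones(m), pred[:, b, :]])
        beta, *_ = np.linalg.lstsq(Xb, rt, rcond=None)
        out[b] = 1.0 - np.sum((rt - Xb @ beta) ** 2) / sst
    return out


def fit_rrr(
    X: np.ndarray,
    Y: np.ndarray,
    ranks: Sequence[int] | None = None,
    val_fraction: float = 0.2,
    rng=None,
    ridge: float = 0.0,
) -> RRRFit:
    """Reduced-rank regression of Y (n x p) on X (n x q).

    Fits OLS on a training split, truncates the coefficient matrix to each
    candidate rank via the SVD of the fitted values (Eckart-Young), picks
    the rank minimizing validation MSE, and reports the chosen rank's
    validation R^2.  A singular X'X is ridge-stabilized with a warning.
    """
    import warnings

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, q = X.shape
    p = Y.shape[1]
    max_rank = min(q, p)
    ranks = list(ranks) if ranks is not None else list(range(1, max_rank + 1))
    if max(ranks) > max_rank:
        raise ValueError(f"candidate ranks must be <= min(q, p) = {max_rank}")

    perm = rng.permutation(n)
    n_val = max(int(round(val_fraction * n)), 1)
    val, train = perm[:n_val], perm[n_val:]

    def _ols(Xt, Yt):
        G = Xt.T @ Xt
        if ridge > 0:
            G = G + ridge * np.eye(q)
        try:
            cond = np.linalg.cond(G)
        except np.linalg.LinAlgError:
            cond = np.inf
        if cond > 1e12 and ridge == 0:
            warnings.warn("singular X'X: using ridge-stabilized inverse")
            G = G + 1e-8 * np.trace(G) / q * np.eye(q)
        return np.linalg.solve(G, Xt.T @ Yt)

    beta_tr = _ols(X[train], Y[train])
    Yhat_tr = X[train] @ beta_tr
    _, _, vt = np.linalg.svd(Yhat_tr, full_matrices=False)

    val_mse = np.zeros(len(ranks))
    for i, s in enumerate(ranks):
        V = vt[:s].T
        beta_s = beta_tr @ V @ V.T
        val_mse[i] = np.mean((Y[val] - X[val] @ beta_s) ** 2)
    best = int(np.argmin(val_mse))
    s_best = ranks[best]

    V = vt[:s_best].T
    beta_best = beta_tr @ V @ V.T
    resid = Y[val] - X[val] @ beta_best
    sst = np.sum((Y[val] - Y[val].mean(axis=0)) ** 2)
    cv_r2 = float(1.0 - np.sum(resid**2) / sst) if sst > 0 else np.nan

    # refit on all data at the chosen rank for the reported coefficients
    beta_all = _ols(X, Y)
    Yhat = X @ beta_all
    _, _, vt_all = np.linalg.svd(Yhat, full_matrices=False)
    Va = vt_all[:s_best].T
    return RRRFit(
        beta=beta_all @ Va @ Va.T,
        rank=s_best,
        candidate_ranks=ranks,
        val_mse=val_mse,
        cv_r2=cv_r2,
        beta_ols=beta_all,
    )
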