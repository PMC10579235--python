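"""Population decoders and per-neuron regressions on binned spike counts.

Three families of analyses, all bin-by-bin across the trial:

* **RT regression** -- ordinary least squares of reaction time on all
  units' spike counts in a bin plus unsigned coherence, with R^2 assessed
  against a 500-shuffle null (trial labels permuted against the spike
  matrix) at its 99th percentile.
* **Choice / previous-outcome decoding** -- L2-regularized logistic
  regression with the ridge penalty lambda = 1/(in-fold observations),
  classes balanced by random subsampling, 5-fold cross-validation, and
  accuracy = 1 - mean fold loss; the same shuffle-null machinery applies.
* **Per-neuron regression** -- unit-wise OLS of binned firing rate on
  choice or RT with 99% confidence intervals; the reported fraction of
  significant units is benchmarked against the 1% expected by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .rates import Kernel, align_and_rate
from .session import SessionData

__all__ = [
    "RTRegressionResult",
    "ChoiceDecoderResult",
    "NeuronRegressionResult",
    "bin_spike_counts",
    "rt_decoder",
    "choice_decoder",
    "outcome_decoder",
    "per_neuron_regression",
]


@dataclass
class RTRegressionResult:
    bin_starts: np.ndarray
    r2: np.ndarray
    null_p99: np.ndarray
    null_p01: np.ndarray
    coherence_only_r2: float
    rank_deficient: bool = False


@dataclass
class ChoiceDecoderResult:
    bin_starts: np.ndarray
    accuracy: np.ndarray
    null_p99: np.ndarray
    null_p01: np.ndarray
    n_per_class: int


@dataclass
class NeuronRegressionResult:
    bin_starts: np.ndarray
    beta: np.ndarray  # (units, bins)
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # bool (units, bins)
    fraction_significant: np.ndarray  # (bins,)
    n_skipped: int = 0
    chance_level: float = 0.01


def bin_spike_counts(
    session: SessionData,
    bin_ms: float = 20.0,
    window: tuple[float, float] = (-600.0, 1200.0),
    step_ms: float | None = None,
    event: str = "checkerboard",
    units=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts per (trial, bin, unit) aligned to an event.

    Bins of width ``bin_ms`` start every ``step_ms`` (default: nonoverlapping).
    Returns ``(counts, bin_starts)``.
    """
    step = bin_ms if step_ms is None else step_ms
    lo, hi = window
    starts = np.arange(lo, hi - bin_ms + 1e-9, step)
    unit_idx = range(session.n_units) if units is None else list(units)
    counts = np.zeros((session.n_trials, len(starts), len(unit_idx)))
    for uj, u in enumerate(unit_idx):
        unit = session.units[u]
        for ti, trial in enumerate(session.trials):
            t0 = trial.checkerboard_onset if event == "checkerboard" else trial.movement_onset
            rel = unit.spike_times[ti] - t0
            if rel.size == 0:
                continue
            left = np.searchsorted(rel, starts, side="left")
            right = np.searchsorted(rel, starts + bin_ms, side="left")
            counts[ti, :, uj] = right - left
    return counts, starts


def _r2_from_fit(y: np.ndarray, pred: np.ndarray) -> float:
    sst = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum((y - pred) ** 2) / sst) if sst > 0 else np.nan


def rt_decoder(
    session: SessionData,
    bin_ms: float = 20.0,
    window: tuple[float, float] = (-600.0, 1200.0),
    n_shuffles: int = 500,
    rng=None,
    units=None,
) -> RTRegressionResult:
    """Bin-wise OLS of RT on spike counts + unsigned coherence, with a
    trial-shuffle null.

    Shuffling permutes the trial correspondence between the spike matrix
    and the (RT, coherence) pair, which preserves the RT-coherence
    relationship while destroying any spiking-RT relationship.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts, starts = bin_spike_counts(session, bin_ms, window, units=units)
    n, n_bins, p = counts.shape
    if p < 2:
        raise ValueError("need at least 2 units")
    y = session.rts()
    c = np.array([abs(t.signed_coherence) for t in session.trials])
    rank_deficient = n < p + 2

    # coherence-only baseline
    Xc = np.column_stack([np.ones(n), c])
    beta_c, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    coh_r2 = _r2_from_fit(y, Xc @ beta_c)

    # permuting spikes against (RT, coherence) == permuting (RT, coherence)
    # jointly against spikes; precompute the permuted target/covariate stack
    perms = np.stack([rng.permutation(n) for _ in range(n_shuffles)])
    sst = np.sum((y - y.mean()) ** 2)

    r2 = np.zeros(n_bins)
    null = np.zeros((n_bins, n_shuffles))
    ones = np.ones(n)
    for b in range(n_bins):
        X = counts[:, b, :]
        G11 = X.T @ X
        g1 = X.T @ ones
        yy = float(y @ y)
        cc = float(c @ c)
        sy = float(ones @ y)
        sc = float(ones @ c)
        cy = float(c @ y)

        def solve_r2(xc: np.ndarray, xy: np.ndarray) -> float:
            # Gram system for design [1, X, c] with permuted (y, c)
            A = np.zeros((p + 2, p + 2))
            A[0, 0] = n
            A[0, 1 : p + 1] = g1
            A[1 : p + 1, 0] = g1
            A[1 : p + 1, 1 : p + 1] = G11
            A[0, p + 1] = sc
            A[p + 1, 0] = sc
            A[1 : p + 1, p + 1] = xc
            A[p + 1, 1 : p + 1] = xc
            A[p + 1, p + 1] = cc
            bvec = np.concatenate([[sy], xy, [cy]])
            beta = np.linalg.pinv(A, rcond=1e-10) @ bvec
            sse = yy - 2 * beta @ bvec + beta @ A @ beta
            return 1.0 - sse / sst

        r2[b] = solve_r2(X.T @ c, X.T @ y)
        Yp = y[perms].T  # (n, S)
        Cp = c[perms].T
        XtY = X.T @ Yp
        XtC = X.T @ Cp
        for s in range(n_shuffles):
            null[b, s] = solve_r2(XtC[:, s], XtY[:, s])

    return RTRegressionResult(
        bin_starts=starts,
        r2=r2,
        null_p99=np.percentile(null, 99, axis=1),
        null_p01=np.percentile(null, 1, axis=1),
        coherence_only_r2=coh_r2,
        rank_deficient=rank_deficient,
    )


def _cv_accuracy(X: np.ndarray, labels: np.ndarray, rng, n_folds: int = 5) -> float:
    """Balanced, per-fold standardized, L2-logistic 5-fold CV accuracy."""
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    idx0 = np.flatnonzero(labels == classes[0])
    idx1 = np.flatnonzero(labels == classes[1])
    m = min(len(idx0), len(idx1))
    take = np.concatenate(
        [rng.choice(idx0, m, replace=False), rng.choice(idx1, m, replace=False)]
    )
    Xb, yb = X[take], (labels[take] == classes[1]).astype(int)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    losses = []
    for train, test in skf.split(Xb, yb):
        mu = Xb[train].mean(axis=0)
        sd = Xb[train].std(axis=0)
        sd[sd < 1e-12] = 1.0
        Xtr = (Xb[train] - mu) / sd
        Xte = (Xb[test] - mu) / sd
        # ridge penalty lambda = 1/n_infold  <=>  sklearn C = n_infold
        clf = LogisticRegression(C=float(len(train)), solver="lbfgs", max_iter=1000, tol=1e-6)
        clf.fit(Xtr, yb[train])
        pred = clf.predict_proba(Xte)[:, 1] > 0.5
        losses.append(np.mean(pred != yb[test]))
    return float(1.0 - np.mean(losses))


def _decode_labels(
    session: SessionData,
    labels: np.ndarray,
    bin_ms: float,
    window: tuple[float, float],
    step_ms: float | None,
    n_shuffles: int,
    rng,
    units,
) -> ChoiceDecoderResult:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    keep = np.flatnonzero(labels != "none")
    labels = labels[keep]
    classes, counts_per = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    counts, starts = bin_spike_counts(session, bin_ms, window, step_ms=step_ms, units=units)
    counts = counts[keep]

    acc = np.zeros(len(starts))
    null = np.zeros((len(starts), n_shuffles))
    for b in range(len(starts)):
        X = counts[:, b, :]
        acc[b] = _cv_accuracy(X, labels, rng)
        for s in range(n_shuffles):
            null[b, s] = _cv_accuracy(X, rng.permutation(labels), rng)
    return ChoiceDecoderResult(
        bin_starts=starts,
        accuracy=acc,
        null_p99=np.percentile(null, 99, axis=1) if n_shuffles else np.full(len(starts), np.nan),
        null_p01=np.percentile(null, 1, axis=1) if n_shuffles else np.full(len(starts), np.nan),
        n_per_class=int(counts_per.min()),
    )


def choice_decoder(
    session: SessionData,
    bin_ms: float = 20.0,
    window: tuple[float, float] = (-600.0, 1200.0),
    step_ms: float | None = None,
    n_shuffles: int = 500,
    rng=None,
    units=None,
) -> ChoiceDecoderResult:
    """Bin-wise cross-validated choice (left vs right) decoding accuracy."""
    labels = session.choices()
    return _decode_labels(session, labels, bin_ms, window, step_ms, n_shuffles, rng, units)


def outcome_decoder(
    session: SessionData,
    bin_ms: float = 50.0,
    window: tuple[float, float] = (-600.0, 1200.0),
    step_ms: float | None = 25.0,
    n_shuffles: int = 500,
    rng=None,
    units=None,
) -> ChoiceDecoderResult:
    """Bin-wise decoding of the previous trial's outcome (overlapping bins)."""
    labels = np.array([t.previous_outcome for t in session.trials])
    return _decode_labels(session, labels, bin_ms, window, step_ms, n_shuffles, rng, units)


def per_neuron_regression(
    session: SessionData,
    target: str = "choice",
    bin_ms: float = 50.0,
    step_ms: float = 1.0,
    window: tuple[float, float] = (-600.0, 1200.0),
    include_coherence: bool = False,
    kernel: Kernel | None = None,
    units=None,
    alpha: float = 0.01,
) -> NeuronRegressionResult:
    """Unit-wise OLS of binned firing rate on choice or RT with 99% CIs.

    Firing rates are the kernel-smoothed instantaneous estimates averaged
    within each sliding bin.  A unit-bin with zero rate variance is
    skipped and counted.  ``fraction_significant`` per bin is the share of
    units whose CI excludes zero; with a 99% CI, 1% is expected by chance.
    """
    if target not in ("choice", "rt"):
        raise ValueError(f"unknown target {target!r}")
    if session.n_trials < 20:
        raise ValueError("need at least 20 trials")
    unit_idx = list(range(session.n_units)) if units is None else list(units)

    x = (
        (session.choices() == "right").astype(float)
        if target == "choice"
        else session.rts()
    )
    regs = [np.ones(session.n_trials), x]
    if include_coherence:
        regs.append(np.array([abs(t.signed_coherence) for t in session.trials]))
    X = np.column_stack(regs)
    n, k = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    hat = XtX_inv @ X.T
    target_col = 1
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - k)

    lo, hi = window
    starts = np.arange(lo, hi - bin_ms + 1e-9, step_ms)
    beta = np.full((len(unit_idx), len(starts)), np.nan)
    se = np.full_like(beta, np.nan)
    n_skipped = 0
    for uj, u in enumerate(unit_idx):
        ptr = align_and_rate(
            session.units[u], session.trials, event="checkerboard",
            window=(lo, hi), kernel=kernel,
        )
        # average smoothed rates within each sliding bin via cumulative sums
        r = np.nan_to_num(ptr.rates, nan=0.0)
        valid = np.isfinite(ptr.rates).astype(float)
        cr = np.concatenate([np.zeros((n, 1)), np.cumsum(r, axis=1)], axis=1)
        cv = np.concatenate([np.zeros((n, 1)), np.cumsum(valid, axis=1)], axis=1)
        i0 = np.searchsorted(ptr.time_axis, starts)
        i1 = np.searchsorted(ptr.time_axis, starts + bin_ms)
        num = cr[:, i1] - cr[:, i0]
        den = cv[:, i1] - cv[:, i0]
        with np.errstate(invalid="ignore", divide="ignore"):
            fr = num / den  # (trials, bins)
        ok_trials = den > 0
        for b in range(len(starts)):
            yb = fr[:, b]
            sel = ok_trials[:, b]
            if sel.sum() < k + 2 or np.var(yb[sel]) < 1e-20:
                n_skipped += 1
                continue
            if sel.all():
                bhat = hat @ yb
                resid = yb - X @ bhat
                sigma2 = resid @ resid / (n - k)
                beta[uj, b] = bhat[target_col]
                se[uj, b] = np.sqrt(sigma2 * XtX_inv[target_col, target_col])
            else:
                Xs = X[sel]
                inv = np.linalg.pinv(Xs.T @ Xs)
                bhat = inv @ Xs.T @ yb[sel]
                resid = yb[sel] - Xs @ bhat
                dof = max(sel.sum() - k, 1)
                sigma2 = resid @ resid / dof
                beta[uj, b] = bhat[target_col]
                se[uj, b] = np.sqrt(sigma2 * inv[target_col, target_col])

    ci_low = beta - tcrit * se
    ci_high = beta + tcrit * se
    significant = ((ci_low > 0) | (ci_high < 0)) & np.isfinite(beta)
    # population fraction: units without rate variance cannot show
    # modulation and count as non-significant
    frac = significant.sum(axis=0) / len(unit_idx)
    return NeuronRegressionResult(
        bin_starts=starts,
        beta=beta,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
        fraction_significant=frac,
        n_skipped=n_skipped,
        chance_level=alpha,
    )
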