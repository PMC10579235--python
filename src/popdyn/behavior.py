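"""Behavioral analyses: psychometric fit, chronometric regression, and
post-outcome reaction-time sequences.

The psychometric curve is a Weibull cumulative distribution function
``p(C) = 1 - 0.5*exp(-(C/alpha)^gamma)``: *alpha* is the discrimination
threshold (the coherence yielding 81.6% correct) and *gamma* the slope.
Chronometric structure is summarized by the R^2 of an ordinary
least-squares regression of RT on log10(coherence).  Post-outcome
adjustment compares RTs of the second trial in error->correct (EC)
sequences against correct->correct (CC) sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PsychometricFit",
    "OutcomeSequenceStats",
    "weibull_p",
    "fit_weibull",
    "rt_coherence_r2",
    "post_outcome_rt_comparison",
]


@dataclass
class PsychometricFit:
    alpha: float
    gamma_slope: float
    r2: float


@dataclass
class OutcomeSequenceStats:
    """RTs of second trials in EC vs matched CC sequences."""

    ec_rts: np.ndarray
    cc_rts: np.ndarray
    ec_median: float
    cc_median: float
    p_value: float | None  # two-sided rank-sum; None when either side has n < 2


def weibull_p(C, alpha: float, gamma_slope: float):
    """Probability correct at unsigned coherence ``C`` (percent)."""
    if alpha <= 0 or gamma_slope <= 0:
        raise ValueError("alpha and gamma_slope must be positive")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("coherence must be nonnegative")
    out = 1.0 - 0.5 * np.exp(-((C / alpha) ** gamma_slope))
    return out if out.ndim else float(out)


def fit_weibull(
    coherences: Sequence[float], p_correct: Sequence[float]
) -> PsychometricFit:
    """Least-squares Weibull fit of proportion correct vs coherence.

    Initialized at alpha = median coherence, gamma = 1; raises on
    degenerate input (fewer than 3 distinct coherences, or constant p).
    """
    C = np.asarray(coherences, dtype=float)
    p = np.asarray(p_correct, dtype=float)
    if len(np.unique(C)) < 3:
        raise ValueError("need at least 3 distinct coherence levels")
    if np.allclose(p, p[0]):
        raise RuntimeError("degenerate psychometric data: all proportions equal")

    def model(c, alpha, gamma):
        return 1.0 - 0.5 * np.exp(-((c / alpha) ** gamma))

    p0 = (float(np.median(C)), 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model, C, p, p0=p0, bounds=([1e-6, 1e-6], [np.inf, np.inf]), maxfev=10000
        )
    except RuntimeError as err:
        raise RuntimeError(f"Weibull fit failed: {err}") from err
    resid = p - model(C, *popt)
    sst = np.sum((p - p.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else np.nan
    return PsychometricFit(alpha=float(popt[0]), gamma_slope=float(popt[1]), r2=float(r2))


def rt_coherence_r2(rts: Sequence[float], C: Sequence[float]) -> float:
    """R^2 of OLS regression of RT on log10(unsigned coherence)."""
    rt = np.asarray(rts, dtype=float)
    c = np.asarray(C, dtype=float)
    if np.any(c <= 0):
        raise ValueError("coherence must be strictly positive for log10")
    x = np.log10(c)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, rt, rcond=None)
    pred = X @ beta
    sst = np.sum((rt - rt.mean()) ** 2)
    return float(1.0 - np.sum((rt - pred) ** 2) / sst)


def post_outcome_rt_comparison(trials) -> OutcomeSequenceStats:
    """Compare second-trial RTs of error->correct vs correct->correct pairs.

    Each EC pair is matched to the nearest CC pair by trial position
    (earlier preferred on ties); the matched CC RTs form the comparison
    sample.  Returns medians and a two-sided rank-sum p (suppressed when
    either sample has fewer than two entries).
    """
    outcomes = [bool(t.correct) for t in trials]
    rts = [float(t.rt) for t in trials]
    ec_pos, cc_pos = [], []
    for i in range(1, len(trials)):
        if outcomes[i]:  # second trial correct
            (cc_pos if outcomes[i - 1] else ec_pos).append(i)
    if not ec_pos:
        raise ValueError("no error->correct sequences present")
    if not cc_pos:
        raise ValueError("no correct->correct sequences present")

    cc_arr = np.asarray(cc_pos)
    matched = []
    for i in ec_pos:
        d = np.abs(cc_arr - i)
        matched.append(int(cc_arr[np.argmin(d)]))  # argmin takes earliest on ties

    ec_rts = np.array([rts[i] for i in ec_pos])
    cc_rts = np.array([rts[i] for i in matched])
    p = None
    if len(ec_rts) >= 2 and len(cc_rts) >= 2:
        p = float(stats.ranksums(ec_rts, cc_rts).pvalue)
    return OutcomeSequenceStats(
        ec_rts=ec_rts,
        cc_rts=cc_rts,
        ec_median=float(np.median(ec_rts)),
        cc_median=float(np.median(cc_rts)),
        p_value=p,
    )
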