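"""Peri-event firing rates: alignment, movement masking, kernel smoothing,
and condition averaging into :class:`RateTensor` objects.

Spike trains are binned at 1 ms aligned to checkerboard or movement onset.
For checkerboard alignment, all samples from 50 ms before movement onset to
the end of the trial are treated as missing so that movement-related
spiking cannot masquerade as pre-movement ramping.  Instantaneous rates are
estimated by kernel smoothing (Gaussian sigma = 30 ms by default; a 15 ms
Gaussian and a 50 ms causal boxcar are provided as robustness options).
Masked samples never enter the smoothing numerator: counts and a validity
mask are convolved separately and divided (occupancy normalization), so
mask edges do not bias rates downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .session import RTBinSet, SessionData, TrialRecord, UnitRecord, make_rt_bins

__all__ = [
    "Kernel",
    "PerTrialRates",
    "RateTensor",
    "align_and_rate",
    "condition_average",
    "compute_rate_tensor",
    "group_trials",
]

#: samples from (movement onset - 50 ms) onward are masked for cue alignment
MOVEMENT_MASK_LEAD_MS = 50.0
#: condition windows end this much before the earliest possible mask onset
WINDOW_GUARD_MS = 25.0

OUTCOME_LABELS = ("correct", "post_correct", "error", "post_error")


@dataclass(frozen=True)
class Kernel:
    """Smoothing kernel: ``gaussian`` (sigma ms) or ``causal_boxcar`` (width ms)."""

    kind: str = "gaussian"
    width_ms: float = 30.0

    def weights(self) -> tuple[np.ndarray, int]:
        """Kernel weights (sum 1) and the index of the 'current time' tap."""
        if self.width_ms <= 0:
            raise ValueError("kernel width must be > 0")
        if self.kind == "gaussian":
            half = int(np.ceil(4 * self.width_ms))
            x = np.arange(-half, half + 1, dtype=float)
            w = np.exp(-0.5 * (x / self.width_ms) ** 2)
            return w / w.sum(), half
        if self.kind == "causal_boxcar":
            n = int(round(self.width_ms))
            w = np.ones(n) / n
            return w, 0  # slice offset 0 so only past samples contribute
        raise ValueError(f"unknown kernel kind {self.kind!r}")


@dataclass
class PerTrialRates:
    """Smoothed per-trial rates (spikes/s) for one unit; NaN where masked."""

    rates: np.ndarray  # (n_trials, n_samples)
    time_axis: np.ndarray  # ms relative to alignment event, 1 ms spacing
    event: str
    n_skipped: int = 0


@dataclass
class RateTensor:
    """Trial-averaged rates: time x unit x condition x choice.

    ``values`` may contain NaN outside a condition's usable window; each
    condition's window runs from -400 ms to ``window_end_ms`` (median RT or
    RT-bin lower bound, minus a 25 ms guard).
    """

    values: np.ndarray  # (T, U, C, 2)
    time_axis: np.ndarray
    condition_labels: list
    choices: tuple = ("left", "right")
    unit_ids: list = field(default_factory=list)
    trial_counts: np.ndarray | None = None  # (C, 2)
    window_end_ms: np.ndarray | None = None  # (C, 2)
    event: str = "checkerboard"

    @property
    def n_conditions(self) -> int:
        return self.values.shape[2]


def _smooth(counts: np.ndarray, valid: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Occupancy-normalized smoothing of 1 ms counts -> rates in spikes/s."""
    w, origin = kernel.weights()
    n = counts.shape[-1]
    c = np.where(valid, counts, 0.0)
    num = fftconvolve(c, w[None, :], mode="full", axes=-1)
    den = fftconvolve(valid.astype(float), w[None, :], mode="full", axes=-1)
    # take the window where tap `origin` of the kernel sits on each sample
    num = num[..., origin : origin + n]
    den = den[..., origin : origin + n]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = 1000.0 * num / den
    rate[~valid] = np.nan
    rate[den < 1e-12] = np.nan
    return rate


def align_and_rate(
    unit: UnitRecord,
    trials: Sequence[TrialRecord],
    event: str = "checkerboard",
    window: tuple[float, float] = (-600.0, 1200.0),
    kernel: Kernel | None = None,
    trial_end_after_move_ms: float = 100.0,
) -> PerTrialRates:
    """Bin one unit's spikes at 1 ms around ``event`` and smooth to rates.

    Samples outside the recorded trial span are masked; for checkerboard
    alignment, samples from 50 ms before movement onset onward are masked
    as well.  Trials whose event time is missing are skipped (all-NaN row)
    and counted in ``n_skipped``.
    """
    if event not in ("checkerboard", "movement"):
        raise ValueError(f"unknown alignment event {event!r}")
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be increasing")
    kernel = kernel or Kernel()
    w, origin = kernel.weights()
    pad = len(w)

    time_axis = np.arange(lo, hi, 1.0)
    n_t = len(time_axis)
    L = len(w)
    ext_lo = lo - pad
    n_ext = n_t + 2 * pad
    rates = np.full((len(trials), n_t), np.nan)

    # cumulative kernel for the analytic occupancy denominator
    wcum = np.concatenate([[0.0], np.cumsum(w)])
    i_ext = np.arange(n_ext)

    n_skipped = 0
    for i, trial in enumerate(trials):
        t0 = trial.checkerboard_onset if event == "checkerboard" else trial.movement_onset
        if t0 is None or not np.isfinite(t0):
            n_skipped += 1
            continue
        spikes = unit.spike_times[i] - t0
        trial_lo = -t0  # trial clock starts at 0
        trial_hi = (trial.movement_onset - t0) + trial_end_after_move_ms
        if event == "checkerboard":
            mask_from = (trial.movement_onset - t0) - MOVEMENT_MASK_LEAD_MS
        else:
            mask_from = np.inf
        # contiguous valid sample interval [a, b) in extended-grid indices
        a = int(np.ceil(trial_lo - ext_lo))
        b = int(np.ceil(min(trial_hi, mask_from) - ext_lo))
        a, b = max(a, 0), min(b, n_ext)
        if b <= a:
            rates[i] = np.nan
            continue

        # numerator: stamp one kernel copy per spike (convolution of a
        # sparse spike train); num[t] = sum_k w[t + origin - k]
        num = np.zeros(n_ext)
        sel = spikes[(spikes >= ext_lo) & (spikes < ext_lo + n_ext)]
        idx = np.floor(sel - ext_lo).astype(int)
        idx = idx[(idx >= a) & (idx < b)]  # masked spikes never contribute
        for k in np.asarray(idx):
            j0 = k - origin
            w0, w1 = max(-j0, 0), min(n_ext - j0, L)
            num[j0 + w0 : j0 + w1] += w[w0:w1]

        # denominator: conv(valid, w)[t] = W(t+origin-a+1) - W(t+origin-b+1)
        hi_idx = np.clip(i_ext + origin - a + 1, 0, L)
        lo_idx = np.clip(i_ext + origin - b + 1, 0, L)
        den = wcum[hi_idx] - wcum[lo_idx]

        with np.errstate(invalid="ignore", divide="ignore"):
            r = 1000.0 * num / den
        r[den < 1e-12] = np.nan
        r[:a] = np.nan
        r[b:] = np.nan
        rates[i] = r[pad : pad + n_t]

    return PerTrialRates(rates=rates, time_axis=time_axis, event=event, n_skipped=n_skipped)


def group_trials(
    trials: Sequence[TrialRecord],
    grouping: str,
    rt_bins: RTBinSet | None = None,
) -> tuple[list, list[np.ndarray], np.ndarray]:
    """Map trials into (condition x choice) groups.

    Returns ``(condition_labels, member_lists, window_end_ms)`` where
    ``member_lists`` is a flat list ordered condition-major within choice
    (left conditions first) of trial-index arrays, and ``window_end_ms``
    the matching usable-window ends.
    """
    rts = np.array([t.rt for t in trials])
    choices = np.array([t.choice for t in trials])

    if grouping == "rt":
        bins = rt_bins or make_rt_bins("overlapping")
        labels = list(range(len(bins)))
        in_range = (rts >= bins.bins[0][0]) & (rts <= bins.bins[-1][1])
        members, ends = [], []
        for choice in ("left", "right"):
            for bi, (blo, bhi) in enumerate(bins.bins):
                sel = np.flatnonzero(
                    (choices == choice) & in_range & (rts >= blo) & (rts <= bhi)
                )
                members.append(sel)
                ends.append(blo - WINDOW_GUARD_MS)
        return labels, members, np.array(ends)

    if grouping == "coherence":
        cohs = np.array([abs(t.signed_coherence) for t in trials])
        labels = sorted(set(cohs.tolist()))
        members, ends = [], []
        for choice in ("left", "right"):
            for c in labels:
                sel = np.flatnonzero((choices == choice) & (cohs == c))
                end = (np.median(rts[sel]) - WINDOW_GUARD_MS) if sel.size else np.nan
                members.append(sel)
                ends.append(end)
        return labels, members, np.array(ends)

    if grouping == "outcome":
        correct = np.array([t.correct for t in trials])
        prev = np.array([t.previous_outcome for t in trials])
        sel_by_label = {
            "correct": correct,
            "post_correct": correct & (prev == "correct"),
            "error": ~correct,
            "post_error": correct & (prev == "error"),
        }
        labels = list(OUTCOME_LABELS)
        members, ends = [], []
        for choice in ("left", "right"):
            for lab in labels:
                sel = np.flatnonzero((choices == choice) & sel_by_label[lab])
                end = (np.median(rts[sel]) - WINDOW_GUARD_MS) if sel.size else np.nan
                members.append(sel)
                ends.append(end)
        return labels, members, np.array(ends)

    raise ValueError(f"unknown grouping {grouping!r}")


def condition_average(
    per_trial: Mapping[str, PerTrialRates],
    trials: Sequence[TrialRecord],
    grouping: str = "rt",
    rt_bins: RTBinSet | None = None,
    truncate: bool = True,
) -> RateTensor:
    """Average per-trial rates within (condition x choice) groups.

    ``per_trial`` maps unit_id -> :class:`PerTrialRates` on a shared time
    axis.  Masked (NaN) samples never contribute; samples after a group's
    usable window end are set to NaN when ``truncate``.  An empty group
    raises an error naming it.
    """
    unit_ids = list(per_trial)
    first = per_trial[unit_ids[0]]
    time_axis = first.time_axis
    labels, members, ends = group_trials(trials, grouping, rt_bins)
    n_c = len(labels)
    for k, sel in enumerate(members):
        if sel.size == 0:
            choice = "left" if k < n_c else "right"
            raise ValueError(
                f"empty group: grouping={grouping!r} condition={labels[k % n_c]!r} "
                f"choice={choice}"
            )

    values = np.full((len(time_axis), len(unit_ids), n_c, 2), np.nan)
    counts = np.zeros((n_c, 2), dtype=int)
    end_arr = np.full((n_c, 2), np.nan)
    for u, uid in enumerate(unit_ids):
        rates = per_trial[uid].rates
        for k, sel in enumerate(members):
            ci, ki = k % n_c, k // n_c
            grp = rates[sel]
            occ = np.sum(np.isfinite(grp), axis=0)
            with np.errstate(invalid="ignore"):
                avg = np.nansum(grp, axis=0) / np.where(occ > 0, occ, 1)
            avg[occ == 0] = np.nan
            if truncate and np.isfinite(ends[k]):
                avg[time_axis > ends[k]] = np.nan
            values[:, u, ci, ki] = avg
            if u == 0:
                counts[ci, ki] = sel.size
                end_arr[ci, ki] = ends[k]

    return RateTensor(
        values=values,
        time_axis=time_axis,
        condition_labels=labels,
        unit_ids=unit_ids,
        trial_counts=counts,
        window_end_ms=end_arr,
        event=first.event,
    )


def compute_rate_tensor(
    session: SessionData,
    grouping: str = "rt",
    event: str = "checkerboard",
    window: tuple[float, float] = (-600.0, 1200.0),
    kernel: Kernel | None = None,
    rt_bins: RTBinSet | None = None,
    units: Sequence[int] | None = None,
) -> RateTensor:
    """Session -> :class:`RateTensor` convenience wrapper."""
    idx = range(session.n_units) if units is None else units
    per_trial = {
        session.units[u].unit_id: align_and_rate(
            session.units[u], session.trials, event=event, window=window, kernel=kernel
        )
        for u in idx
    }
    return condition_average(per_trial, session.trials, grouping, rt_bins=rt_bins)
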