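"""Kinematic analysis of neural trajectories (KiNeT).

Given an ordered family of low-dimensional trajectories (one per condition
level, e.g. RT bin) and a designated reference trajectory, KiNeT measures,
at each reference timepoint: when each other trajectory comes closest to
the reference state (*time to reference*, an indirect speed measure), how
far away that closest state is (*signed distance*, with sign set by
whether the trajectory lies on the first-condition or last-condition side
of the reference), the angles between adjacent inter-trajectory difference
vectors, and how the mean inter-trajectory vector rotates over the trial
relative to its initial orientation (*subspace angle*).  All measures are
computed within each choice and then averaged across choices at matched
reference timepoints.  Scalar state-space speed and the one-tailed
bootstrap p-value rule used throughout the analyses live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import TrajectorySet

__all__ = [
    "KinetResult",
    "SpeedProfile",
    "kinet_analyze",
    "scalar_speed",
    "bootstrap_p",
]


@dataclass
class KinetResult:
    """Per-choice-averaged KiNeT measures on a common reference time axis."""

    ref_times: np.ndarray  # (J,) reference timepoints (from the first choice)
    t_ref: np.ndarray  # (n_traj, J) time at closest approach; NaN for reference
    signed_distance: np.ndarray  # (n_traj, J)
    adjacent_angles: np.ndarray | None  # (n_traj-1-1, J) degrees, or None
    subspace_angle: np.ndarray | None  # (J,) degrees
    per_choice: dict | None = None


@dataclass
class SpeedProfile:
    """Prestimulus scalar speed per condition (choice-averaged)."""

    condition_labels: list
    speeds: np.ndarray  # (n_conditions, n_steps) instantaneous l2 speed
    step_times: np.ndarray
    prestim_mean: np.ndarray  # (n_conditions,)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-300 or nv < 1e-300:
        return np.nan
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _closest_states(
    trajs: list[np.ndarray], ref_idx: int
) -> tuple[np.ndarray, np.ndarray]:
    """For each trajectory i and reference timepoint j, the closest state
    s_i[j] and its timepoint index tau_i[j] (earliest on ties)."""
    ref = trajs[ref_idx]
    J = ref.shape[0]
    n = len(trajs)
    d = ref.shape[1]
    states = np.zeros((n, J, d))
    tau = np.zeros((n, J), dtype=int)
    for i, traj in enumerate(trajs):
        if i == ref_idx:
            states[i] = ref
            tau[i] = np.arange(J)
            continue
        # pairwise distances (T_i x J); argmin over the trajectory's own support
        d2 = np.sum((traj[:, None, :] - ref[None, :, :]) ** 2, axis=2)
        tau[i] = np.argmin(d2, axis=0)  # np.argmin returns earliest on ties
        states[i] = traj[tau[i]]
    return states, tau


def _kinet_one_choice(trajs: list[np.ndarray], times: list[np.ndarray], ref_idx: int):
    ref_times = times[ref_idx]
    J = len(ref_times)
    n = len(trajs)
    states, tau = _closest_states(trajs, ref_idx)

    t_ref = np.full((n, J), np.nan)
    dist = np.zeros((n, J))
    for i in range(n):
        t_ref[i] = times[i][tau[i]]
        dist[i] = np.linalg.norm(states[i] - states[ref_idx], axis=1)

    # sign by angular proximity of displacement-from-reference to the first
    # versus last condition's displacement
    signed = np.zeros_like(dist)
    for j in range(J):
        v_first = states[0, j] - states[ref_idx, j]
        v_last = states[-1, j] - states[ref_idx, j]
        for i in range(n):
            if i == ref_idx:
                continue
            v = states[i, j] - states[ref_idx, j]
            a_first = _angle_deg(v, v_first)
            a_last = _angle_deg(v, v_last)
            if np.isnan(a_first) and np.isnan(a_last):
                sgn = 0.0
            elif np.isnan(a_last) or (not np.isnan(a_first) and a_first <= a_last):
                sgn = 1.0
            else:
                sgn = -1.0
            signed[i, j] = sgn * dist[i, j]

    angles = None
    sub_angle = None
    if n >= 3:
        # adjacent difference vectors Delta_i[j] = s_{i+1}[j] - s_i[j]
        deltas = states[1:] - states[:-1]  # (n-1, J, d)
        norms = np.linalg.norm(deltas, axis=2, keepdims=True)
        unit = np.divide(deltas, norms, out=np.zeros_like(deltas), where=norms > 1e-300)
        angles = np.full((n - 2, J), np.nan)
        for i in range(n - 2):
            for j in range(J):
                angles[i, j] = _angle_deg(deltas[i, j], deltas[i + 1, j])
        mean_vec = unit.mean(axis=0)  # (J, d), equal weights across adjacencies
        mv_norm = np.linalg.norm(mean_vec, axis=1, keepdims=True)
        mean_unit = np.divide(
            mean_vec, mv_norm, out=np.zeros_like(mean_vec), where=mv_norm > 1e-300
        )
        sub_angle = np.array([_angle_deg(mean_unit[j], mean_unit[0]) for j in range(J)])

    return ref_times, t_ref, signed, angles, sub_angle


def kinet_analyze(trajset: TrajectorySet, choices: Sequence[str] = ("left", "right")) -> KinetResult:
    """Run the full KiNeT battery, per choice then averaged across choices.

    The trajectory set must contain the same ordered condition list for
    each choice and designate a reference condition index.
    """
    if trajset.reference_index is None:
        raise ValueError("trajset.reference_index must be set")
    dims = {t.shape[1] for t in trajset.trajectories}
    if len(dims) != 1:
        raise ValueError(f"trajectories have mixed dimensionality {dims}")

    per_choice = {}
    for choice in choices:
        trajs, times = trajset.by_choice(choice)
        if not trajs:
            continue
        per_choice[choice] = _kinet_one_choice(trajs, times, trajset.reference_index)
    if not per_choice:
        raise ValueError("no trajectories matched the requested choices")

    # average across choices at matched reference timepoint indices
    first = next(iter(per_choice.values()))
    J = min(v[0].shape[0] for v in per_choice.values())

    def avg(idx):
        vals = [v[idx] for v in per_choice.values() if v[idx] is not None]
        if not vals or any(v is None for v in vals):
            return None
        return np.mean([v[..., :J] for v in vals], axis=0)

    return KinetResult(
        ref_times=first[0][:J],
        t_ref=avg(1),
        signed_distance=avg(2),
        adjacent_angles=avg(3),
        subspace_angle=avg(4),
        per_choice={k: v for k, v in per_choice.items()},
    )


def scalar_speed(
    trajset: TrajectorySet,
    step_ms: float = 10.0,
    window: tuple[float, float] = (-400.0, 0.0),
    choices: Sequence[str] = ("left", "right"),
) -> SpeedProfile:
    """l2 state-space speed at ``step_ms`` strides, averaged over choices
    and over the prestimulus window."""
    lo, hi = window
    cond_labels = [lab for ch, lab in trajset.labels if ch == choices[0]]
    step_times = np.arange(lo, hi - step_ms + 1e-9, step_ms)
    if len(step_times) == 0:
        raise ValueError("window shorter than one step")
    speeds = np.zeros((len(cond_labels), len(step_times)))
    counts = np.zeros(len(cond_labels))
    for choice in choices:
        trajs, times = trajset.by_choice(choice)
        for ci, (traj, tax) in enumerate(zip(trajs, times)):
            if tax[0] > lo or tax[-1] < hi:
                raise ValueError(
                    f"window {window} outside trajectory support "
                    f"({tax[0]}..{tax[-1]})"
                )
            idx0 = np.searchsorted(tax, step_times)
            idx1 = np.searchsorted(tax, step_times + step_ms)
            idx1 = np.minimum(idx1, len(tax) - 1)
            speeds[ci] += np.linalg.norm(traj[idx1] - traj[idx0], axis=1)
            counts[ci] += 1
    speeds /= counts[:, None]
    return SpeedProfile(
        condition_labels=cond_labels,
        speeds=speeds,
        step_times=step_times,
        prestim_mean=speeds.mean(axis=1),
    )


def bootstrap_p(boot_stats: Sequence[float], s_test: float, side: str = "greater") -> float:
    """Unbiased one-tailed bootstrap p: (1 + #beyond) / (1 + n).

    With n = 50 bootstraps and zero exceedances the smallest attainable
    value is 1/51 (0.0196).
    """
    stats = np.asarray(boot_stats, dtype=float)
    if stats.size == 0:
        raise ValueError("need at least one bootstrap statistic")
    if side == "greater":
        beyond = np.sum(stats > s_test)
    elif side == "less":
        beyond = np.sum(stats < s_test)
    else:
        raise ValueError(f"unknown side {side!r}")
    return float((1 + beyond) / (1 + stats.size))
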