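"""Population geometry: soft-normalized PCA, signal-vs-noise dimension
estimation, and projection of condition-averaged rates into low-dimensional
trajectory sets.

Condition-averaged rates are stacked time-within-condition (all left-choice
conditions above all right-choice conditions), each unit column is divided
by the square root of its 99th-percentile rate (*soft normalization*, which
equalizes unit variability) and mean-centered, and PCA is run on the
result.  The number of dimensions distinguishable from noise is estimated
by comparing the trial-averaged ("signal+noise") eigenvalue spectrum with
the spectrum of a noise matrix built from scaled differences of disjoint
trial pairs (differencing two trials cancels the shared signal).  Scaling
each difference by 1/sqrt(2 * n_pairs) makes the noise spectrum a
deliberately conservative (factor-two in variance) stand-in for the
trial-average noise floor, so the "signal+noise significantly below noise"
criterion fires just past the true signal rank and immediately on
pure-noise data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .rates import RateTensor

__all__ = [
    "PCSpace",
    "NoiseDimEstimate",
    "TrajectorySet",
    "soft_normalize_stack",
    "fit_pca",
    "estimate_signal_dims",
    "project",
    "bootstrap_trajectories",
]


@dataclass
class PCSpace:
    """PCA loadings plus the preprocessing constants needed to reuse them."""

    loadings: np.ndarray  # (units, components), orthonormal columns
    eigenvalues: np.ndarray  # variance per component, non-increasing
    column_means: np.ndarray  # (units,), of the soft-normalized matrix
    normalizers: np.ndarray  # (units,), sqrt of 99th-percentile rate
    n_signal_dims: int | None = None

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues


@dataclass
class NoiseDimEstimate:
    signal_plus_noise_eigs: np.ndarray
    noise_eigs: np.ndarray
    eig_sems: np.ndarray
    n_signal_dims: int


@dataclass
class TrajectorySet:
    """Ordered low-dimensional trajectories, one per (choice, condition)."""

    trajectories: list[np.ndarray]  # each (T_i, d)
    times: list[np.ndarray]
    labels: list[tuple]  # (choice, condition_label), condition order preserved
    reference_index: int | None = None  # condition index (within each choice)

    @property
    def dim(self) -> int:
        return self.trajectories[0].shape[1]

    def by_choice(self, choice: str) -> tuple[list[np.ndarray], list[np.ndarray]]:
        trajs = [t for t, lab in zip(self.trajectories, self.labels) if lab[0] == choice]
        times = [t for t, lab in zip(self.times, self.labels) if lab[0] == choice]
        return trajs, times


def _stack_tensor(tensor: RateTensor) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Vertically stack a tensor's usable windows: left conditions then right.

    Returns the (rows x units) matrix and per-block (condition, choice)
    sample masks as index arrays into the tensor's time axis.
    """
    blocks, meta = [], []
    for ki in range(tensor.values.shape[3]):
        for ci in range(tensor.values.shape[2]):
            block = tensor.values[:, :, ci, ki]
            rows = np.all(np.isfinite(block), axis=1)
            blocks.append(block[rows])
            meta.append((ci, ki, np.flatnonzero(rows)))
    return np.vstack(blocks), meta


def soft_normalize_stack(
    tensor: RateTensor,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Stack and soft-normalize a rate tensor.

    Returns ``(matrix, column_means, normalizers, blocks)`` where ``matrix``
    is centered and normalized, ``normalizers`` are sqrt(99th percentile)
    computed on the raw stacked columns (pre-centering), and ``blocks``
    records (condition, choice, time-index) structure of the rows.
    """
    raw, blocks = _stack_tensor(tensor)
    if raw.shape[0] == 0:
        raise ValueError("no fully observed rows to stack")
    bad = np.flatnonzero(~np.all(np.isfinite(raw), axis=0))
    if bad.size:
        names = [tensor.unit_ids[b] if tensor.unit_ids else b for b in bad]
        raise ValueError(f"all-missing or non-finite columns for units {names}")
    p99 = np.percentile(raw, 99, axis=0)
    norm = np.sqrt(np.clip(p99, 0.0, None))
    norm = np.where(norm > 1e-12, norm, 1.0)
    scaled = raw / norm
    means = scaled.mean(axis=0)
    return scaled - means, means, norm, blocks


def fit_pca(matrix: np.ndarray, normalizers: np.ndarray | None = None,
            column_means: np.ndarray | None = None) -> PCSpace:
    """PCA of an already centered (and soft-normalized) stacked matrix."""
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite entries")
    n_rows, n_units = matrix.shape
    _, s, vt = np.linalg.svd(matrix, full_matrices=False)
    eigs = s**2 / max(n_rows - 1, 1)
    loadings = vt.T
    # resolve sign ambiguity: largest-|.| element of each loading positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    return PCSpace(
        loadings=loadings,
        eigenvalues=eigs,
        column_means=column_means if column_means is not None else np.zeros(n_units),
        normalizers=normalizers if normalizers is not None else np.ones(n_units),
    )


def fit_pca_tensor(tensor: RateTensor) -> PCSpace:
    """Soft-normalize, stack and fit PCA in one step."""
    mat, means, norm, _ = soft_normalize_stack(tensor)
    return fit_pca(mat, normalizers=norm, column_means=means)


def project(tensor: RateTensor, pcspace: PCSpace, n_dims: int = 6) -> TrajectorySet:
    """Project condition-averaged rates into a stored PC space.

    Applies the stored normalizers and centering, then the first ``n_dims``
    loadings; each (choice, condition) trajectory keeps its own truncated
    time axis.
    """
    if n_dims > pcspace.loadings.shape[1]:
        raise ValueError(
            f"n_dims={n_dims} exceeds available components {pcspace.loadings.shape[1]}"
        )
    if tensor.values.shape[1] != pcspace.loadings.shape[0]:
        raise ValueError("unit count mismatch between tensor and PC space")
    L = pcspace.loadings[:, :n_dims]
    trajs, times, labels = [], [], []
    for ki, choice in enumerate(tensor.choices):
        for ci, lab in enumerate(tensor.condition_labels):
            block = tensor.values[:, :, ci, ki]
            rows = np.all(np.isfinite(block), axis=1)
            x = block[rows] / pcspace.normalizers - pcspace.column_means
            trajs.append(x @ L)
            times.append(tensor.time_axis[rows])
            labels.append((choice, lab))
    return TrajectorySet(trajectories=trajs, times=times, labels=labels)


def estimate_signal_dims(
    trial_rates: Mapping, n_boot: int = 50, rng=None, max_dims: int | None = None
) -> NoiseDimEstimate:
    """Estimate how many PCA dimensions carry signal above the noise floor.

    ``trial_rates`` maps condition -> array (n_trials, T, n_units) of
    single-trial rates.  The trial-averaged stack gives the signal+noise
    spectrum; scaled disjoint-pair differences (each divided by
    sqrt(2 * n_pairs)) give the noise spectrum.  The estimate is the number
    of leading
    components before the signal+noise eigenvalue first drops below the
    noise eigenvalue by more than 3 bootstrap SEMs.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    conds = list(trial_rates)
    for c in conds:
        if trial_rates[c].shape[0] < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 trials")

    def spectra(resample: bool) -> tuple[np.ndarray, np.ndarray]:
        sig_blocks, noise_blocks = [], []
        for c in conds:
            arr = trial_rates[c]
            m = arr.shape[0]
            if resample:
                arr = arr[rng.integers(0, m, size=m)]
            sig_blocks.append(arr.mean(axis=0))
            # one random disjoint pair per condition keeps the noise matrix
            # the same shape as the signal matrix, so both eigenvalue
            # spectra carry identical finite-sample spreading
            perm = rng.permutation(m)
            n_pairs = m // 2
            diff = (arr[perm[0]] - arr[perm[1]]) / np.sqrt(2.0 * n_pairs)
            noise_blocks.append(diff)
        sig = np.vstack(sig_blocks)
        noise = np.vstack(noise_blocks)
        # shared soft normalization from the signal stack
        p99 = np.percentile(sig, 99, axis=0)
        norm = np.sqrt(np.clip(p99, 0.0, None))
        norm = np.where(norm > 1e-12, norm, 1.0)
        sig = sig / norm
        sig = sig - sig.mean(axis=0)
        noise = noise / norm
        noise = noise - noise.mean(axis=0)
        s_sig = np.linalg.svd(sig, compute_uv=False) ** 2 / max(sig.shape[0] - 1, 1)
        s_noi = np.linalg.svd(noise, compute_uv=False) ** 2 / max(noise.shape[0] - 1, 1)
        return s_sig, s_noi

    sig_eigs, noise_eigs = spectra(resample=False)
    d = min(len(sig_eigs), len(noise_eigs))
    if max_dims is not None:
        d = min(d, max_dims)
    boot = np.zeros((n_boot, d))
    for b in range(n_boot):
        s, _ = spectra(resample=True)
        boot[b] = s[:d]
    sems = boot.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(d)

    below = sig_eigs[:d] < noise_eigs[:d] - 3.0 * sems
    n_signal = int(np.argmax(below)) if np.any(below) else d
    return NoiseDimEstimate(
        signal_plus_noise_eigs=sig_eigs,
        noise_eigs=noise_eigs,
        eig_sems=sems,
        n_signal_dims=n_signal,
    )


def bootstrap_trajectories(
    per_trial: Mapping,
    trials: Sequence,
    grouping: str = "rt",
    n_dims: int = 6,
    n_boot: int = 50,
    seed=None,
    rt_bins=None,
    resample: bool = True,
) -> list[TrajectorySet]:
    """Bootstrap the average -> PCA -> project pipeline.

    Per bootstrap, trials are resampled with replacement within each
    unit x condition group, re-averaged, PCA re-fit, and projected.
    Deterministic given ``seed``; with ``resample=False`` each replicate
    equals the point estimate.
    """
    from .rates import condition_average, group_trials

    rng = np.random.default_rng(seed)
    unit_ids = list(per_trial)
    labels, members, ends = group_trials(trials, grouping, rt_bins)
    time_axis = per_trial[unit_ids[0]].time_axis
    n_c = len(labels)

    out = []
    for _ in range(n_boot):
        values = np.full((len(time_axis), len(unit_ids), n_c, 2), np.nan)
        for u, uid in enumerate(unit_ids):
            rates = per_trial[uid].rates
            for k, sel in enumerate(members):
                ci, ki = k % n_c, k // n_c
                take = rng.choice(sel, size=sel.size, replace=True) if resample else sel
                grp = rates[take]
                occ = np.sum(np.isfinite(grp), axis=0)
                with np.errstate(invalid="ignore"):
                    avg = np.nansum(grp, axis=0) / np.where(occ > 0, occ, 1)
                avg[occ == 0] = np.nan
                if np.isfinite(ends[k]):
                    avg[time_axis > ends[k]] = np.nan
                values[:, u, ci, ki] = avg
        tensor = RateTensor(
            values=values,
            time_axis=time_axis,
            condition_labels=labels,
            unit_ids=unit_ids,
        )
        pcs = fit_pca_tensor(tensor)
        out.append(project(tensor, pcs, n_dims=min(n_dims, pcs.loadings.shape[1])))
    return out
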