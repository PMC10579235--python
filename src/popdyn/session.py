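"""Core session data model: trials, units, spike times, and RT binning.

A *session bundle* is a directory of three CSV files (``trials.csv``,
``units.csv``, ``spikes.csv``) holding one recording (or simulated) session
of the red-green checkerboard discrimination task.  Times are milliseconds
from trial start; the checkerboard-onset and movement-onset columns anchor
event alignment, and reaction time (RT) is their difference by invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "UnitRecord",
    "SessionData",
    "RTBinSet",
    "classify_unit",
    "make_rt_bins",
    "read_session",
    "write_session",
    "SessionFormatError",
    "SessionValidationError",
]

#: ISI-violation threshold (percent) separating single neurons from multi-units.
SINGLE_UNIT_ISI_THRESHOLD_PCT = 1.5

#: Range of reaction times (ms) spanned by the RT-binned analyses.
RT_RANGE_MS = (300.0, 1000.0)

TRIALS_COLUMNS = [
    "trial_index",
    "signed_coherence",
    "choice",
    "correct",
    "rt_ms",
    "checkerboard_onset_ms",
    "movement_onset_ms",
    "previous_outcome",
]
UNITS_COLUMNS = ["unit_id", "isi_violation_pct", "label"]
SPIKES_COLUMNS = ["unit_id", "trial_index", "spike_time_ms"]


class SessionFormatError(ValueError):
    """A bundle file or required column is missing or malformed."""


class SessionValidationError(ValueError):
    """Bundle contents violate a session invariant (e.g. RT inconsistency)."""


@dataclass
class TrialRecord:
    """One trial of the checkerboard task.

    Signed coherence is 100*(R-G)/(R+G) in percent; its sign encodes the
    dominant color's side and its magnitude the stimulus strength.  RT is
    the time from checkerboard onset to movement onset.
    """

    trial_index: int
    signed_coherence: float
    choice: Literal["left", "right"]
    correct: bool
    rt: float
    checkerboard_onset: float
    movement_onset: float
    previous_outcome: Literal["correct", "error", "none"] = "none"

    @property
    def unsigned_coherence(self) -> float:
        return abs(self.signed_coherence)

    def validate(self) -> None:
        if self.rt <= 0:
            raise SessionValidationError(
                f"trial {self.trial_index}: rt must be > 0, got {self.rt}"
            )
        if not np.isclose(
            self.movement_onset - self.checkerboard_onset, self.rt, atol=1e-6
        ):
            raise SessionValidationError(
                f"trial {self.trial_index}: movement_onset - checkerboard_onset "
                f"({self.movement_onset - self.checkerboard_onset}) != rt ({self.rt})"
            )
        if self.choice not in ("left", "right"):
            raise SessionValidationError(
                f"trial {self.trial_index}: unknown choice {self.choice!r}"
            )


@dataclass
class UnitRecord:
    """One recorded (or simulated) unit with per-trial spike-time lists."""

    unit_id: str
    isi_violation_pct: float
    spike_times: list[np.ndarray] = field(default_factory=list)
    label: Literal["single", "multi"] | None = None

    def __post_init__(self) -> None:
        if self.label is None:
            self.label = classify_unit(self.isi_violation_pct)
        self.spike_times = [np.asarray(s, dtype=float) for s in self.spike_times]


@dataclass
class SessionData:
    """Trials, units, and spikes for one session."""

    session_id: str
    trials: list[TrialRecord]
    units: list[UnitRecord]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def validate(self) -> None:
        indices = [t.trial_index for t in self.trials]
        if len(set(indices)) != len(indices):
            raise SessionValidationError("duplicate trial indices")
        bad = [
            t.trial_index
            for t in self.trials
            if not np.isclose(t.movement_onset - t.checkerboard_onset, t.rt, atol=1e-6)
            or t.rt <= 0
        ]
        if bad:
            raise SessionValidationError(
                f"rt inconsistent with event times for trials {bad}"
            )
        for u in self.units:
            if len(u.spike_times) != len(self.trials):
                raise SessionValidationError(
                    f"unit {u.unit_id}: {len(u.spike_times)} spike lists for "
                    f"{len(self.trials)} trials"
                )
            for s in u.spike_times:
                if s.size > 1 and np.any(np.diff(s) < 0):
                    raise SessionValidationError(
                        f"unit {u.unit_id}: spike times not sorted"
                    )

    def rts(self) -> np.ndarray:
        return np.array([t.rt for t in self.trials])

    def choices(self) -> np.ndarray:
        return np.array([t.choice for t in self.trials])


@dataclass
class RTBinSet:
    """Ordered reaction-time bins, possibly overlapping."""

    bins: list[tuple[float, float]]
    overlapping: bool

    def __post_init__(self) -> None:
        centers = self.centers
        if np.any(np.diff(centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.bins])

    def assign(self, rt: float) -> list[int]:
        """Indices of bins containing ``rt`` (inclusive edges)."""
        return [i for i, (lo, hi) in enumerate(self.bins) if lo <= rt <= hi]

    def __len__(self) -> int:
        return len(self.bins)


def classify_unit(isi_violation_pct: float) -> str:
    """Label a unit ``single`` if its refractory-period (<=1.5 ms) ISI
    violations are at most 1.5%, else ``multi``."""
    if isi_violation_pct < 0:
        raise ValueError(f"isi_violation_pct must be >= 0, got {isi_violation_pct}")
    return "single" if isi_violation_pct <= SINGLE_UNIT_ISI_THRESHOLD_PCT else "multi"


def make_rt_bins(
    mode: str = "overlapping", n_nonoverlapping: int = 3
) -> RTBinSet:
    """Construct the RT bins used to condition trajectory analyses.

    ``overlapping`` returns 11 bins: ten 100-ms windows stepped by 25 ms
    (300-400, 325-425, ..., 525-625) plus a final 600-1000 ms catch-all, so
    the bins span a spectrum from fast to slow RTs.  ``nonoverlapping``
    splits the same 300-1000 ms range into ``n_nonoverlapping`` contiguous
    equal-width bins.
    """
    lo, hi = RT_RANGE_MS
    if mode == "overlapping":
        bins = [(300.0 + 25.0 * k, 400.0 + 25.0 * k) for k in range(10)]
        bins.append((600.0, 1000.0))
        return RTBinSet(bins=bins, overlapping=True)
    if mode == "nonoverlapping":
        edges = np.linspace(lo, hi, n_nonoverlapping + 1)
        bins = [(float(edges[i]), float(edges[i + 1])) for i in range(n_nonoverlapping)]
        return RTBinSet(bins=bins, overlapping=False)
    raise ValueError(f"unknown RT-bin mode {mode!r}")


# ---------------------------------------------------------------------------
# Bundle I/O


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{fname}: missing column(s) {missing}")


def write_session(session: SessionData, bundle_path: str | Path) -> Path:
    """Write a session bundle (trials.csv, units.csv, spikes.csv)."""
    path = Path(bundle_path)
    path.mkdir(parents=True, exist_ok=True)

    trials = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in session.trials],
            "signed_coherence": [t.signed_coherence for t in session.trials],
            "choice": [t.choice for t in session.trials],
            "correct": [t.correct for t in session.trials],
            "rt_ms": [t.rt for t in session.trials],
            "checkerboard_onset_ms": [t.checkerboard_onset for t in session.trials],
            "movement_onset_ms": [t.movement_onset for t in session.trials],
            "previous_outcome": [t.previous_outcome for t in session.trials],
        }
    )
    trials.to_csv(path / "trials.csv", index=False)

    units = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "isi_violation_pct": [u.isi_violation_pct for u in session.units],
            "label": [u.label for u in session.units],
        }
    )
    units.to_csv(path / "units.csv", index=False)

    uid, tidx, times = [], [], []
    trial_order = [t.trial_index for t in session.trials]
    for u in session.units:
        for ti, spikes in zip(trial_order, u.spike_times):
            uid.extend([u.unit_id] * len(spikes))
            tidx.extend([ti] * len(spikes))
            times.extend(spikes.tolist())
    pd.DataFrame(
        {"unit_id": uid, "trial_index": tidx, "spike_time_ms": times}
    ).to_csv(path / "spikes.csv", index=False)
    return path


def read_session(bundle_path: str | Path, session_id: str | None = None) -> SessionData:
    """Read a session bundle, validating invariants.

    Raises :class:`SessionFormatError` for missing files/columns and
    :class:`SessionValidationError` for RT/event-time inconsistencies
    (listing the offending trial indices).
    """
    path = Path(bundle_path)
    for fname in ("trials.csv", "units.csv", "spikes.csv"):
        if not (path / fname).exists():
            raise SessionFormatError(f"bundle {path}: missing file {fname}")

    trials_df = pd.read_csv(path / "trials.csv")
    _require_columns(trials_df, TRIALS_COLUMNS, "trials.csv")
    units_df = pd.read_csv(path / "units.csv")
    _require_columns(units_df, UNITS_COLUMNS, "units.csv")
    spikes_df = pd.read_csv(path / "spikes.csv")
    if len(spikes_df) == 0:
        spikes_df = pd.DataFrame(columns=SPIKES_COLUMNS)
    _require_columns(spikes_df, SPIKES_COLUMNS, "spikes.csv")

    trials = [
        TrialRecord(
            trial_index=int(r.trial_index),
            signed_coherence=float(r.signed_coherence),
            choice=str(r.choice),
            correct=bool(r.correct),
            rt=float(r.rt_ms),
            checkerboard_onset=float(r.checkerboard_onset_ms),
            movement_onset=float(r.movement_onset_ms),
            previous_outcome=str(r.previous_outcome),
        )
        for r in trials_df.itertuples()
    ]

    trial_order = [t.trial_index for t in trials]
    grouped: dict[tuple, np.ndarray] = {}
    if len(spikes_df):
        for (u, ti), g in spikes_df.groupby(["unit_id", "trial_index"], sort=False):
            grouped[(u, ti)] = np.sort(g["spike_time_ms"].to_numpy(dtype=float))

    units = []
    for r in units_df.itertuples():
        spike_lists = [
            grouped.get((r.unit_id, ti), np.empty(0, dtype=float))
            for ti in trial_order
        ]
        units.append(
            UnitRecord(
                unit_id=str(r.unit_id),
                isi_violation_pct=float(r.isi_violation_pct),
                spike_times=spike_lists,
                label=str(r.label),
            )
        )

    session = SessionData(
        session_id=session_id or path.name, trials=trials, units=units
    )
    session.validate()
    return session
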