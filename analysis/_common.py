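"""Shared helpers for the numbered analysis drivers.

Each driver loads (or simulates on first use) the three hypothesis
sessions at the study's default scale and writes its tables under
``results/``.  All randomness is seeded so reruns are identical.
"""

from __future__ import annotations

from pathlib import Path

from popdyn.session import SessionData, read_session
from popdyn.simulate import SimulationConfig, write_simulated_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"
SESSIONS = RESULTS / "sessions"
SEED = 11

HYPOTHESES = ("sim1_no_prestim", "sim2_choice_bias", "sim3_rt_covariation")


def load_session(hypothesis: str) -> SessionData:
    """Read a cached session bundle, simulating it if absent."""
    bundle = SESSIONS / hypothesis
    if (bundle / "trials.csv").exists():
        return read_session(bundle)
    SESSIONS.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(hypothesis=hypothesis, seed=SEED)
    return write_simulated_bundle(cfg, bundle)
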