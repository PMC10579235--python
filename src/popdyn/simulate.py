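"""Synthetic premotor-cortex population simulator.

Implements the three hypothetical neural populations used to discriminate
dynamical hypotheses about decision initial conditions:

* ``sim1_no_prestim`` -- no prestimulus covariation with reaction time (RT)
  or choice; post-cue rates covary with both.
* ``sim2_choice_bias`` -- a prestimulus firing-rate bias toward one choice.
* ``sim3_rt_covariation`` -- prestimulus rates covary with RT (but not
  choice) in a designated fraction of units whose baseline is replaced by
  ``r_base2 = (2 + base_neuron)/RT`` (RT in seconds, base_neuron ~ U(0,3)).

Each population mixes three unit classes: *increased* units with a
5 spikes/s baseline, a choice-selective post-cue component, and a
condition-independent ramp; *decreased* units, each the matching increased
profile minus 10 spikes/s (floored at zero); and *perimovement* units that
fire a transient Gaussian burst around movement onset.  Spike trains are
drawn from the resulting inhomogeneous Poisson intensity via the
time-rescaling theorem, and RTs from 200 + 100*Gamma(shape=5, scale=0.5) ms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .session import SessionData, TrialRecord, UnitRecord, write_session
from .behavior import weibull_p

__all__ = [
    "SimulationConfig",
    "RateProfile",
    "simulate_rt",
    "build_rate_profile",
    "generate_spikes",
    "simulate_session",
]

HYPOTHESES = ("sim1_no_prestim", "sim2_choice_bias", "sim3_rt_covariation")
UNIT_CLASSES = ("increased", "decreased", "perimovement")


@dataclass
class SimulationConfig:
    """All parameters of the synthetic population generator.

    Defaults reproduce the study conditions: 200 increased, 100
    decreased and 50 perimovement units; 600 trials (300 left / 300 right);
    RT = 200 + 100*Gamma(5, 0.5) ms; 100 ms non-decision latency; 5 spikes/s
    baseline; 20% of units carrying the RT-dependent prestimulus term under
    ``sim3_rt_covariation``.
    """

    hypothesis: str = "sim1_no_prestim"
    n_increased: int = 200
    n_decreased: int = 100
    n_perimovement: int = 50
    n_trials: int = 600
    rt_offset_ms: float = 200.0
    rt_scale_ms: float = 100.0
    rt_shape: float = 5.0
    rt_gamma_scale: float = 0.5
    t_latency_ms: float = 100.0
    baseline_rate: float = 5.0
    rt_covary_fraction: float = 0.2
    # window simulated before checkerboard onset and after movement onset
    pre_window_ms: float = 700.0
    post_move_ms: float = 100.0
    # perimovement transient: Gaussian bump at movement onset
    peri_sigma_ms: float = 50.0
    peri_amp: float = 20.0
    peri_jitter_ms: float = 100.0
    # task statistics used to dress trials with stimulus/outcome labels
    coherence_levels: tuple = (4.0, 11.0, 18.0, 31.0, 45.0, 67.0, 90.0)
    psychometric_alpha: float = 10.89
    psychometric_gamma: float = 1.26
    seed: int = 0

    def validate(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        for name in ("n_increased", "n_decreased", "n_perimovement", "n_trials"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.rt_covary_fraction <= 1.0:
            raise ValueError("rt_covary_fraction must be in [0, 1]")

    @property
    def n_units(self) -> int:
        return self.n_increased + self.n_decreased + self.n_perimovement

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class RateProfile:
    """A single unit-trial firing-rate profile on a 1 ms grid.

    ``rate`` is the nonnegative sum of the named ``components`` clipped at
    zero; times are ms relative to checkerboard onset.
    """

    times: np.ndarray
    rate: np.ndarray
    components: dict[str, np.ndarray | float] = field(default_factory=dict)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_rt(n: int, rng=None, config: SimulationConfig | None = None) -> np.ndarray:
    """Draw reaction times (ms) as offset + scale * Gamma(shape, gamma_scale)."""
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    cfg = config or SimulationConfig()
    g = _as_rng(rng)
    return cfg.rt_offset_ms + cfg.rt_scale_ms * g.gamma(
        cfg.rt_shape, cfg.rt_gamma_scale, size=n
    )


def build_rate_profile(
    unit_class: str,
    trial: TrialRecord,
    config: SimulationConfig,
    rng,
    *,
    preferred: str = "left",
    base_neuron: float | None = None,
    rt_designated: bool = False,
    peri_jitter_ms: float = 0.0,
) -> RateProfile:
    """Construct one unit-trial intensity profile (spikes/s, 1 ms grid).

    The grid runs from ``-pre_window_ms`` to ``RT + post_move_ms`` relative
    to checkerboard onset.  Post-cue components are gated by
    ``max((t - t_lag)/RT, 0)`` with ``t_lag = t_latency + 0.2*RT`` and held
    at their movement-onset value for the final ``post_move_ms``.

    The keyword parameters identify per-unit structure: the
    unit's preferred direction, its ``base_neuron`` draw and whether it is
    one of the designated RT-covarying units (hypothesis 3 only).
    """
    if unit_class not in UNIT_CLASSES:
        raise ValueError(f"unknown unit class {unit_class!r}")
    g = _as_rng(rng)
    rt = trial.rt
    t_lag = config.t_latency_ms + 0.2 * rt
    times = np.arange(-config.pre_window_ms, rt + config.post_move_ms, 1.0)
    # components frozen at their movement-onset value during the hold period
    t_eff = np.minimum(times, rt)

    components: dict[str, np.ndarray | float] = {}

    # prestimulus baseline
    if rt_designated and config.hypothesis == "sim3_rt_covariation":
        b = (2.0 + (base_neuron if base_neuron is not None else 0.0)) / (rt / 1000.0)
        base = b  # replaces r_base1: designated units have zero baseline
        components["r_base2"] = b
    elif unit_class == "perimovement":
        base = 0.0
    else:
        base = config.baseline_rate
        components["r_base1"] = base

    rate = np.full_like(times, float(base))

    if config.hypothesis == "sim2_choice_bias":
        hi = 4.0 if trial.choice == "left" else 2.0
        bias = g.uniform(0.0, hi)
        components["bias"] = bias
        rate = rate + bias

    if unit_class in ("increased", "decreased"):
        gate = np.clip((t_eff - t_lag) / rt, 0.0, None)
        r_choice1 = 5.0 + 7.0 * g.uniform()
        r_choice2 = 2.0 + g.uniform()
        if trial.choice == preferred:
            choice_term = gate * r_choice1
            components["r_choice1"] = r_choice1
        else:
            choice_term = -gate * r_choice2
            components["r_choice2"] = r_choice2
        # condition-independent ramp, slope in spikes/s per second
        r_time = np.maximum(15.0 * (t_eff - t_lag) / 1000.0, 0.0)
        components["r_time"] = r_time
        rate = rate + choice_term + r_time
        if unit_class == "decreased":
            rate = rate - 10.0
            components["decreased_shift"] = -10.0
    else:  # perimovement
        bump = config.peri_amp * np.exp(
            -0.5 * ((times - (rt + peri_jitter_ms)) / config.peri_sigma_ms) ** 2
        )
        components["perimovement"] = bump
        rate = rate + bump

    return RateProfile(times=times, rate=np.clip(rate, 0.0, None), components=components)


def generate_spikes(profile: RateProfile, rng) -> np.ndarray:
    """Sample spike times (ms) from an inhomogeneous Poisson intensity.

    Uses the time-rescaling construction: the cumulative intensity
    Lambda(t) maps the process to unit rate, so drawing N ~ Poisson(Lambda_total)
    event locations uniformly in rescaled time and inverting Lambda yields
    spike times whose rescaled inter-spike intervals are Exp(1).
    The rate is treated as piecewise-constant on the 1 ms grid.
    """
    rate = np.asarray(profile.rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be nonnegative everywhere")
    g = _as_rng(rng)
    dt_s = 1e-3  # 1 ms grid, rate in spikes/s
    mass = rate * dt_s
    total = float(mass.sum())
    if total <= 0:
        return np.empty(0, dtype=float)
    n = g.poisson(total)
    if n == 0:
        return np.empty(0, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(mass)])
    edges = np.concatenate([profile.times, [profile.times[-1] + 1.0]])
    u = np.sort(g.uniform(0.0, total, size=n))
    return np.interp(u, cum, edges)


def _designated_indices(n_units: int, fraction: float) -> np.ndarray:
    """Deterministic, evenly spread designation of exactly floor(f*n) units."""
    k = int(round(fraction * n_units))
    if k == 0:
        return np.empty(0, dtype=int)
    return np.unique(np.floor(np.arange(k) * n_units / k).astype(int))


def _make_trials(config: SimulationConfig, rng: np.random.Generator) -> list[TrialRecord]:
    n = config.n_trials
    rts = simulate_rt(n, rng, config)
    # equal left/right choices, interleaved then shuffled for exchangeability
    choices = np.array(["left", "right"])[np.arange(n) % 2]
    rng.shuffle(choices)
    coh = rng.choice(np.asarray(config.coherence_levels, dtype=float), size=n)
    p_correct = weibull_p(coh, config.psychometric_alpha, config.psychometric_gamma)
    correct = rng.uniform(size=n) < p_correct
    trials = []
    prev = "none"
    for i in range(n):
        # dominant-color side: matches the choice when correct, else opposite
        side = 1.0 if choices[i] == "right" else -1.0
        signed = side * coh[i] if correct[i] else -side * coh[i]
        trials.append(
            TrialRecord(
                trial_index=i,
                signed_coherence=float(signed),
                choice=str(choices[i]),
                correct=bool(correct[i]),
                rt=float(rts[i]),
                checkerboard_onset=config.pre_window_ms,
                movement_onset=config.pre_window_ms + float(rts[i]),
                previous_outcome=prev,
            )
        )
        prev = "correct" if correct[i] else "error"
    return trials


def simulate_session(config: SimulationConfig | None = None) -> SessionData:
    """Generate a full synthetic session (deterministic given ``config.seed``)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    trials = _make_trials(cfg, rng)

    n_units = cfg.n_units
    classes = (
        ["increased"] * cfg.n_increased
        + ["decreased"] * cfg.n_decreased
        + ["perimovement"] * cfg.n_perimovement
    )
    designated = np.zeros(n_units, dtype=bool)
    if cfg.hypothesis == "sim3_rt_covariation":
        designated[_designated_indices(n_units, cfg.rt_covary_fraction)] = True
    preferred = np.array(["left", "right"])[np.arange(n_units) % 2]
    base_neuron = rng.uniform(0.0, 3.0, size=n_units)
    peri_jitter = rng.uniform(-cfg.peri_jitter_ms, cfg.peri_jitter_ms, size=n_units)

    units = []
    for u in range(n_units):
        spike_lists = []
        for trial in trials:
            profile = build_rate_profile(
                classes[u],
                trial,
                cfg,
                rng,
                preferred=str(preferred[u]),
                base_neuron=float(base_neuron[u]),
                rt_designated=bool(designated[u]),
                peri_jitter_ms=float(peri_jitter[u]),
            )
            spikes = generate_spikes(profile, rng)
            # store absolute trial time (trial starts at t=0)
            spike_lists.append(spikes + trial.checkerboard_onset)
        units.append(
            UnitRecord(
                unit_id=f"u{u:04d}",
                isi_violation_pct=0.0,
                spike_times=spike_lists,
                label="single",
            )
        )

    session = SessionData(
        session_id=f"{cfg.hypothesis}_seed{cfg.seed}", trials=trials, units=units
    )
    session.validate()
    return session


def write_simulated_bundle(
    config: SimulationConfig, bundle_path: str | Path
) -> SessionData:
    """Simulate a session and write it as a bundle plus a config sidecar."""
    session = simulate_session(config)
    path = write_session(session, bundle_path)
    (path / "simulation_config.json").write_text(config.to_json())
    return session
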