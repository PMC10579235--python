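# popdyn — population dynamics of premotor decision activity

`popdyn` is an analysis library for asking how the **initial condition** of a
motor-cortical population — its position and speed in firing-rate state space
just before a decision stimulus appears — relates to the upcoming choice and
to reaction time (RT). It implements the full pipeline used to study this
question in dorsal premotor cortex (PMd) during a red–green checkerboard
discrimination task, together with a synthetic neural-population simulator
that instantiates the competing dynamical hypotheses, so every stage is
testable without any recorded data.

It is written for systems/computational neuroscientists who have per-trial
spike times and event times and want trajectory-level answers: is the
prestimulus state spatially ordered by RT? Does it carry choice information?
Do single-trial dynamics look like a fixed linear flow field?

## What it computes

- **Behavior** — Weibull psychometric fit
  `p(C) = 1 − 0.5·exp(−(C/α)^γ)` (α is the 81.6%-correct threshold), RT vs
  log₁₀(coherence) regression, and post-outcome RT sequences (error→correct
  vs correct→correct).
- **Peri-event rates** — 1 ms binning aligned to checkerboard or movement
  onset, removal of all spikes from 50 ms before movement onward (for cue
  alignment), Gaussian-kernel rate estimation (σ = 30 ms) with occupancy
  normalization so masked samples never bias rates.
- **Population geometry** — condition-averaged rates (11 overlapping RT bins
  × 2 reach directions, or coherence/outcome conditionings), soft
  normalization (divide each unit by √(99th-percentile rate)), PCA, and a
  signal-vs-noise dimensionality estimate that compares the trial-averaged
  eigenspectrum against a matched noise spectrum built from disjoint
  trial-pair differences.
- **KiNeT trajectory kinematics** — for each condition trajectory Ωᵢ versus a
  reference Ω_ref: time-to-reference `tᵢ[j] = argmin_τ ‖Ωᵢ(τ) − s_ref[j]‖`,
  signed minimum distance `Dᵢ[j] = ±‖s_ref[j] − sᵢ[j]‖`, angles between
  adjacent inter-trajectory vectors, subspace rotation angle
  `θ̄[t] = ∠(Δ̄[t], Δ̄[1])`, scalar speed `ℓ²(t) = ‖Ω(t+δt) − Ω(t)‖₂`, and the
  unbiased one-tailed bootstrap p-value `(1 + #{Sᵢ beyond S_test})/(1 + n)`.
- **Choice selectivity** — `CS(t) = ‖Ω_L(t) − Ω_R(t)‖₂` with a piecewise
  baseline-then-quadratic latency fit, the initial-condition axis (top PC of
  prestimulus states across coherence × RT-bin cells), and partial
  correlations.
- **Decoders** — bin-wise OLS of RT on population spike counts (+ coherence)
  with 500-shuffle nulls; balanced, 5-fold cross-validated L2-logistic
  choice/outcome decoders with λ = 1/(in-fold observations); per-neuron
  regressions with 99% CIs.
- **Dynamics** — autonomous linear dynamical system `Ẋ ≈ XJ` fit to
  single-trial latents (50 ms bins, 100 ms horizon) with leave-one-trial-out
  R²; reduced-rank regression of post-stimulus from pre-stimulus activity via
  the Eckart–Young truncation of the OLS fit.
- **Subspace overlap** — alignment index
  `A = tr(Dᵀ C D)/Σσ`, the fraction of one conditioning's total variance
  captured by another conditioning's top-6 subspace.
- **Simulator** — three hypothetical populations (200 increased / 100
  decreased / 50 perimovement units, 600 trials), gamma-distributed RTs
  `RT = 200 + 100·Γ(5, 0.5)` ms, choice- and RT-dependent post-cue rate
  components, optional prestimulus choice bias (hypothesis 2) or RT-dependent
  baselines in 20% of units (hypothesis 3), and spike generation by the
  time-rescaling theorem.

## Worked example

Simulate the RT-covariation population and ask whether the prestimulus
population state is ordered by reaction time:

```python
import numpy as np
from popdyn import geometry, kinet
from popdyn.rates import compute_rate_tensor
from popdyn.simulate import SimulationConfig, simulate_session

session = simulate_session(SimulationConfig(hypothesis="sim3_rt_covariation", seed=11))
tensor = compute_rate_tensor(session, grouping="rt")       # 11 RT bins x 2 choices
pcs = geometry.fit_pca_tensor(tensor)
traj = geometry.project(tensor, pcs, n_dims=6)
traj.reference_index = 5                                    # middle RT bin
res = kinet.kinet_analyze(traj)
j = int(np.argmin(np.abs(res.ref_times + 90.0)))            # 90 ms before the cue
print(np.round(res.signed_distance[:, j], 2))
```

This prints the signed distance of each RT-bin trajectory from the
middle-bin reference, 90 ms before checkerboard onset:

```
[ 4.74  3.4   2.24  1.23  0.44  0.   -0.42 -0.95 -1.57 -2.02 -3.48]
```

Fast-RT trajectories sit on one side of the reference and slow-RT
trajectories on the other, in strict rank order (Spearman ρ = −1.00 against
RT-bin center): the population's initial condition predicts how quickly the
decision will unfold. Running the same pipeline on the no-prestimulus
population (`sim1_no_prestim`) collapses this ordering, and the
`analysis/06_decoders.py` driver shows the complementary dissociation —
prestimulus choice decoding beats its shuffle null only for the choice-bias
population (accuracy 0.82 vs a 0.56 null ceiling), while prestimulus RT
regression beats its null only for the RT-covariation population
(R² 0.36 vs 0.09).

## Analysis drivers

`analysis/01_simulate_populations.py` … `08_subspace_overlap.py` are thin,
numbered drivers that run each stage at the study's default scale and write
tidy tables under `results/`. Each prints a one-paragraph summary of what it
found. `popdyn.pipeline.run_pipeline(config)` orchestrates the same stages
from a single (YAML-able) config with deterministic per-stage seeding and a
hash manifest.

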