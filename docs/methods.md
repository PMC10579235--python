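# Methods

This note documents the models, parameter choices, and numerical decisions
behind `popdyn`, and what the synthetic populations do and do not emulate.

## Task and data model

One *session* holds per-trial records (signed coherence, choice, outcome,
RT, checkerboard- and movement-onset times) and per-unit spike-time lists.
Signed coherence is 100·(R−G)/(R+G) in percent; RT is movement onset minus
checkerboard onset, enforced as an invariant at load time. Units are
labelled single neurons when ≤ 1.5% of their inter-spike intervals violate a
1.5 ms refractory period, multi-units otherwise. The CSV bundle format
(`trials.csv`, `units.csv`, `spikes.csv`) round-trips losslessly.

**RT bins.** Trajectory analyses condition on eleven overlapping RT bins:
ten 100-ms windows stepped by 25 ms (300–400, 325–425, …, 525–625 ms) plus a
600–1000 ms catch-all. The stated anchors for this family are its first two
bins and the final catch-all together with the count of eleven; the
intermediate windows are the unique uniform completion consistent with
those anchors, and every RT in [300, 1000] ms falls in at least one bin.
Trials outside that range are excluded from RT-binned analyses. A
non-overlapping variant splits the same range into three equal bins
(configurable count).

## Synthetic populations

The simulator builds the three hypothesis-bearing populations used to
interpret the analyses:

| parameter | default | meaning |
|---|---|---|
| n_increased / n_decreased / n_perimovement | 200 / 100 / 50 | unit classes |
| n_trials | 600 | 300 left + 300 right choices |
| RT | 200 + 100·Γ(5, 0.5) ms | mean 450 ms, SD ≈ 112 ms |
| t_latency | 100 ms | non-decision (encoding + efferent) delay |
| r_base1 | 5 spikes/s | increased-unit baseline |
| rt_covary_fraction | 0.2 | share of units with RT-dependent baseline (hyp. 3) |

Per trial, an increased unit's rate is baseline + a choice component gated
by `max((t − t_lag)/RT, 0)` with `t_lag = t_latency + 0.2·RT` (added
`5 + 7·U(0,1)` for the preferred direction, subtracted `2 + U(0,1)`
otherwise) + a condition-independent ramp `max(15·(t − t_lag), 0)` with time
in seconds. Decreased units are the matching increased profile minus
10 spikes/s, floored at zero. Unit preferences alternate deterministically
so both directions are represented equally. Hypothesis 2 adds a per-trial
uniform baseline bias (U(0,4) spikes/s on left-choice trials, U(0,2) on
right). Hypothesis 3 replaces the baseline of a deterministically chosen
20% of units with `r_base2 = (2 + base_neuron)/RT` (RT in seconds,
`base_neuron ~ U(0,3)` drawn once per unit), giving prestimulus rates that
covary with RT but not choice.

Numerical interpretation choices, made once: the ramp slope (15) and the
`r_base2` divisor use seconds — the millisecond reading yields rates
indistinguishable from zero; rates after movement onset are held at their
movement-onset value for 100 ms and the trial ends (the trial-end boundary
is quantized by the 1 ms rate grid); perimovement responses, specified only
as "transient around movement", are a Gaussian bump (amplitude 20 spikes/s,
σ = 50 ms) centered on movement onset with a per-unit lead/lag jitter
U(−100, 100) ms; per-trial uniform draws are redrawn per trial and unit.
Trials are dressed with coherences drawn uniformly from seven levels
(4–90%) and outcomes drawn from the Weibull psychometric at the fitted
across-session parameters (α = 10.89, γ = 1.26), so behavioral code is
exercised realistically; RTs are independent of coherence by construction.

**Spike generation.** Rates are piecewise-constant on a 1 ms grid; spikes
are drawn by inverting the cumulative intensity (the time-rescaling
construction), so rescaled inter-spike intervals are unit-exponential and
the expected count equals the integrated rate.

**What the simulator does not emulate.** Prestimulus *speed* differences:
planted prestimulus rates are constant in time, so the population encodes an
RT-dependent position but no RT-dependent velocity, and prestimulus scalar
speed across RT bins reflects only trial-averaging noise. Likewise there are
no noise correlations, no coherence-dependent RTs or rates, no post-outcome
RT adjustment, and no change-of-mind trials. Passing tests therefore
demonstrate correctness of the machinery and discriminability of the planted
hypotheses, not that recorded PMd data behave this way.

## Rate estimation

Spikes are binned at 1 ms around the alignment event. For checkerboard
alignment, all samples from 50 ms before movement onset to the trial end are
marked missing so movement bursts cannot masquerade as pre-movement ramping.
Rates are kernel estimates (Gaussian σ = 30 ms default; σ = 15 ms and a
50 ms causal boxcar as robustness options). Because the mask is one-sided,
counts and the validity mask are convolved separately and divided
(occupancy normalization); this keeps rates unbiased at mask edges, at the
cost of slightly higher variance there. Condition averages use only valid
samples, and each condition's usable window runs from −400 ms to its median
RT (coherence/outcome groupings) or its RT-bin lower bound (RT groupings)
minus a 25 ms guard, which keeps the masked region out of the averaged
window entirely.

## PCA and the signal-dimension estimate

Condition averages are stacked time-within-condition, left-choice conditions
above right, each unit column divided by √(its 99th-percentile rate) — soft
normalization, which equalizes unit variability while preserving
signal-to-noise (a unit whose rates scale by a scales by √a, not 1) — then
mean-centered and decomposed by SVD. Loading signs are fixed by making each
loading's largest-magnitude element positive.

The number of dimensions distinguishable from noise compares the
trial-averaged ("signal+noise") eigenspectrum with that of a noise matrix
built from differences of disjoint trial pairs, which cancel the shared
signal. Two choices matter and were validated on planted-rank data:

1. **Scale.** Each pair difference is divided by √(2·n_pairs). This makes
   the noise spectrum a deliberately conservative stand-in (twice the
   variance of the true noise-in-the-mean): with the unbiased scaling the
   noise and post-signal spectra are statistically indistinguishable and the
   criterion below essentially never fires.
2. **Shape.** One pair per condition, so the noise matrix has exactly the
   signal matrix's shape and both spectra share the same finite-sample
   (Marchenko–Pastur) spreading; with many more noise rows the spreading
   mismatch alone produced spurious dimensions on pure noise.

The estimate is the number of leading components before the signal+noise
eigenvalue first falls below the noise eigenvalue by more than 3 bootstrap
SEMs (50 trial-resampling bootstraps). On planted data this recovers a
rank-4 signal and returns 0 for pure noise; with duplicated trials
(zero noise) it returns full rank, as it should.

## KiNeT

All measures are computed within each choice and then averaged across
choices at matched reference timepoints. Argmin ties in the closest-state
search take the earliest timepoint. The sign of the distance is set by
whether the displacement-from-reference vector is angularly closer to the
first condition's displacement than to the last's. Adjacent-vector angles
use the ordered condition list including the reference; the subspace angle
normalizes each adjacent vector, averages with equal weights, renormalizes,
and measures rotation relative to the first timepoint (so θ̄[1] = 0 by
construction). Scalar speed is the ℓ² step between coordinates 10 ms apart,
averaged over choices and the −400–0 ms window. Bootstrap p-values use the
unbiased `(1 + #beyond)/(1 + n)` rule; with the standard 50 bootstraps the
smallest attainable p is 1/51 ≈ 0.0196.

## Choice selectivity and initial condition

CS(t) is the Euclidean distance between the left- and right-choice
trajectories in the top six PCs. The latency fit is the discontinuous model
CS(t) = b for t ≤ t_lat, m·(t − t_lat)² after, exactly as specified — no
continuity constraint is imposed. The latency is found by grid search over
timepoints with (b, m) in closed form at each candidate and the global SSE
minimizer returned (earliest on ties); a curve the constant model fits as
well as the best piecewise fit is flagged flat and assigned the window-end
latency with m = 0. The initial-condition axis is the top PC of the
(coherence × RT-bin) × (2 choices · 6 PCs) matrix of prestimulus
(−400 to −100 ms) mean states, oriented so scores correlate negatively with
RT-bin center (the data determine an ordering, not a sign). Partial
correlations are computed on OLS residuals; coherence enters as log₁₀(C) by
default, matching the chronometric convention (a config switch).

## Decoders

RT regression is OLS of RT on all units' counts per 20 ms bin plus unsigned
coherence, R² in-sample, against a null of 500 trial permutations of the
spike matrix relative to the (RT, coherence) pairs — which preserves the
RT–coherence relationship. The permuted fits reuse the spike Gram matrix,
so the full null costs one matrix product per shuffle. Choice/outcome
decoding balances classes by random subsampling, z-scores predictors per
training fold (making the penalty's meaning independent of count scale —
accuracy is invariant to per-unit affine rescaling), and fits L2 logistic
regression with ridge weight λ = 1/(in-fold observations) (scikit-learn
`C = n_infold`) under stratified 5-fold cross-validation; accuracy is
1 − mean fold loss at the p = 0.5 decision threshold. Per-neuron
regressions model each unit's bin-averaged smoothed rate as linear in
choice or RT with 99% t-based confidence intervals; the reported fraction
of significant units is a population fraction (units with zero rate
variance count as non-significant), benchmarked against the 1% expected by
chance. Calibration of that 1% on null data is assessed as a one-sided
binomial test on the observed count — the observed fraction in any finite
sample scatters around the nominal rate, so "≤ 1%" is a statement about the
underlying rate, not the sample.

## Dynamics fits

The LDS treats the 100 ms forward difference of 50 ms-binned latents
(top PCs of pooled single-trial counts) as a fixed linear function of the
current state, pooled over trials; J is the closed-form least-squares
solution and the objective's normalization makes the fit invariant to
orthogonal changes of latent basis (J conjugates). Cross-validation is
leave-one-trial-out on the normalized reconstruction error. Fits are run
separately per epoch (pre/post-stimulus) and per choice (left by default).
Reduced-rank regression fits OLS on an 80/20 seed-controlled trial split,
truncates via the SVD of the fitted values (optimal by Eckart–Young, which
the tests verify against the tail singular values), picks the rank
minimizing validation MSE, and refits at that rank on all data for the
reported coefficients. A near-singular normal matrix is ridge-stabilized
with a warning.

## Subspace overlap

The alignment index divides the variance of conditioning A captured by
conditioning B's top-6 subspace by A's **total** variance (all eigenvalues
in the denominator), so A ∈ [0, 1], is rotation-invariant, and is monotone
in the number of numerator dimensions. Covariances are computed on the same
soft-normalized stacks that feed PCA so both conditionings share
preprocessing.

## Problem sizes and determinism

The test suite and analysis drivers run the simulator at its full default
scale (350 units × 600 trials per hypothesis). Decoding analyses use a
50-unit random subsample, mirroring the design in which decoders are run on
a 50-neuron draw from the simulated ensemble; prestimulus windows use
−400–0 ms. Latent-variable analyses subsample every fifth or seventh unit,
which leaves the planted structure intact. Every stochastic step takes an
explicit seed or generator; the pipeline orchestrator derives per-stage
seeds from the global seed and the stage name, so adding a stage never
shifts another stage's draws, and identical configs produce byte-identical
outputs.

## Known limitations

- The simulator validates machinery and hypothesis discriminability; its
  null/alternative structure is far cleaner than recorded data (no noise
  correlations, no drift, no behavioral adaptation).
- The signal-dimension estimator's noise spectrum is intentionally
  conservative (see above); it bounds, rather than unbiasedly estimates,
  the noise floor.
- The outcome decoder's overlapping-bin step defaults to 25 ms, chosen so a
  1800 ms window yields 72 windows; the step is exposed as a parameter.
- KiNeT time-to-reference is ill-conditioned when trajectories are nearly
  static (many near-equidistant states); the earliest-timepoint tie rule
  makes results deterministic but prestimulus t_ref values should be
  interpreted with care.
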