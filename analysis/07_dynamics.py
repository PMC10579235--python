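"""Single-trial dynamical-system fits.

Fits the autonomous LDS to prestimulus latent trajectories over latent
dimensionalities 2..10 (leave-one-trial-out R^2 should improve with model
size) and a reduced-rank regression predicting poststimulus counts from
prestimulus counts plus task covariates, against a trial-shuffled control.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, load_session
from popdyn.decoders import bin_spike_counts
from popdyn.dynamics import fit_lds, fit_rrr, latents_from_counts

session = load_session("sim3_rt_covariation")
left = np.flatnonzero(session.choices() == "left")
counts, _ = bin_spike_counts(session, bin_ms=50.0, window=(-600.0, 0.0),
                             units=range(0, 350, 5))

rows = []
for dim in range(2, 11):
    lat = latents_from_counts(counts[left], dim)
    fit = fit_lds(lat, epoch="prestimulus")
    rows.append({"latent_dim": dim, "cv_r2": fit.cv_r2})
df = pd.DataFrame(rows)
print("LDS leave-one-trial-out R^2 by latent dimension:")
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

units = range(0, 350, 7)
pre, _ = bin_spike_counts(session, bin_ms=400.0, window=(-400.0, 0.0), units=units)
post, _ = bin_spike_counts(session, bin_ms=400.0, window=(100.0, 500.0), units=units)
choice = (session.choices() == "right").astype(float)
coh = np.array([abs(t.signed_coherence) for t in session.trials])
X = np.column_stack([pre[:, 0, :], choice, coh])
Y = post[:, 0, :]
fit = fit_rrr(X, Y, ranks=[1, 2, 4, 8, 16], rng=3, ridge=1e-8)
rng = np.random.default_rng(9)
shuf = fit_rrr(X[rng.permutation(len(X))], Y, ranks=[1, 2, 4, 8, 16],
               rng=3, ridge=1e-8)
print(f"RRR pre->post: chosen rank {fit.rank}, validation R^2 {fit.cv_r2:.3f} "
      f"(trial-shuffled control {shuf.cv_r2:.3f})")

df.to_csv(RESULTS / "lds_fit.csv", index=False)
pd.DataFrame({"rank": fit.candidate_ranks, "val_mse": fit.val_mse}).assign(
    chosen_rank=fit.rank, cv_r2=fit.cv_r2, shuffled_cv_r2=shuf.cv_r2
).to_csv(RESULTS / "rrr_fit.csv", index=False)
print(f"wrote {RESULTS / 'lds_fit.csv'} and rrr_fit.csv")
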