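"""Subspace overlap between RT-conditioned and outcome-conditioned rates.

Computes the alignment index A = tr(D'CD)/sum(sigma): the fraction of the
total soft-normalized variance of the RT-and-choice conditioning captured
by the top-6 principal subspace of the outcome-and-choice conditioning,
plus the reverse cross-projection.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, load_session
from popdyn import geometry, overlap
from popdyn.rates import compute_rate_tensor

session = load_session("sim3_rt_covariation")
tensor_rt = compute_rate_tensor(session, grouping="rt")
tensor_out = compute_rate_tensor(session, grouping="outcome")

mat_rt, _, _, _ = geometry.soft_normalize_stack(tensor_rt)
pcs_rt = geometry.fit_pca(mat_rt)
pcs_out = geometry.fit_pca_tensor(tensor_out)

cov_rt = np.cov(mat_rt, rowvar=False)
res = overlap.alignment_index(cov_rt, pcs_out.loadings[:, :6], pcs_rt.eigenvalues)
print(f"alignment index (RT variance in outcome subspace): A = {res.A:.3f}")

_, captured = overlap.cross_project(tensor_out, pcs_rt, n_dims=6)
print(f"cross-projection: outcome-conditioned rates keep {100*captured:.1f}% "
      "of their variance in the RT subspace")

pd.DataFrame(
    [{"alignment_index": res.A, "n_dims": res.n_dims_numerator,
      "captured_variance": res.captured_variance,
      "total_variance": res.total_variance,
      "outcome_in_rt_subspace_fraction": captured}]
).to_csv(RESULTS / "alignment.csv", index=False)
print(f"wrote {RESULTS / 'alignment.csv'}")
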