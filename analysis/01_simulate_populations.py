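"""Simulate the three hypothetical premotor populations.

Generates one session per dynamical hypothesis (no prestimulus structure;
prestimulus choice bias; prestimulus RT covariation) at the default scale
of 350 units (200 increased / 100 decreased / 50 perimovement) and 600
trials, writes the session bundles, and prints basic session statistics.
"""

import numpy as np
import pandas as pd

from _common import HYPOTHESES, RESULTS, load_session

rows = []
for hyp in HYPOTHESES:
    s = load_session(hyp)
    spikes = sum(len(sp) for u in s.units for sp in u.spike_times)
    rows.append(
        {
            "hypothesis": hyp,
            "n_units": s.n_units,
            "n_trials": s.n_trials,
            "n_left": int(np.sum(s.choices() == "left")),
            "median_rt_ms": float(np.median(s.rts())),
            "total_spikes": spikes,
        }
    )
    print(
        f"{hyp}: {s.n_units} units, {s.n_trials} trials "
        f"(median RT {rows[-1]['median_rt_ms']:.0f} ms, {spikes} spikes)"
    )

RESULTS.mkdir(exist_ok=True)
pd.DataFrame(rows).to_csv(RESULTS / "session_summary.csv", index=False)
print(f"wrote {RESULTS / 'session_summary.csv'}")
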