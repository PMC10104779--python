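"""Steady-injection simulations: how the injection rate J shapes the
size distribution.

Sweeps J over {0.01, 0.1, 1, 5} at the paper-geometry scaled box (400
spheres, 4% final volume fraction) and separately runs the chi-preserving
slow-injection condition (J = 0.01) used for the power-law exponent and
the monomer merger-partner age analysis.

Writes results/injection_sweep.csv and results/injection_slow.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from condkin import stats
from condkin import workflows as wf

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

sweep = wf.injection_sweep_summary(rates=(0.01, 0.1, 1.0, 5.0), seed=0, box_length=None)
sweep.to_csv(OUT / "injection_sweep.csv", index=False)
print(sweep.to_string(index=False))

slow = wf.injection_study(0.01, seed=5, n_replicates=20)
pooled = wf.late_pooled_volumes(slow)
fit = wf.ccdf_grid_fit_loglog(pooled)
k = stats.pdf_exponent_from_ccdf(fit.slope)
frac, per_rep = wf.monomer_partner_early_fraction(slow)
pd.DataFrame(
    [dict(J=0.01, ccdf_slope=fit.slope, pdf_exponent=k,
          monomer_partner_early_fraction=frac, n_pooled=len(pooled),
          n_replicates=len(per_rep))]
).to_csv(OUT / "injection_slow.csv", index=False)

print(
    f"\nFinding: fast injection (J = 5) gives a narrow, exponential-like "
    f"distribution (CV ~ {sweep.cv.iloc[-1]:.2f}); slow injection (J = 0.01) "
    f"gives a power law with CCDF slope {fit.slope:.2f} (pdf exponent "
    f"{k:.2f}), and {100*frac:.0f}% of monomer mergers involve partners whose "
    f"earliest ancestor entered in the first quarter of the run - mergers are "
    f"strongly biased toward the oldest, largest spheres (preferential "
    f"attachment)."
)
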