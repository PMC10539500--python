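"""Digital reference object: does cell-size heterogeneity move K2?

Packs spherical cells around cylindrical vessels, dephases diffusing spins
in the analytic susceptibility fields of a contrast bolus with extravascular
leakage, and compares the fitted K2 between tissues with 0% and 6.5%
coefficient of variation in cell radius. Paired tissues share vessels and
cell centers so the conditions differ only via the radii draws.

Scaled down (2 seeds, 4000 spins) to run in about a minute; the acceptance
script runs 5 seeds at 10,000 spins.
"""

import numpy as np

from gliomamap import dro

params = dro.SimulationParams(n_spins=4000, n_timepoints=60)
table = dro.run_cv_experiment([0.0, 6.5], params, seeds=[1, 2])
print(table[["cv_pct", "seed", "K1", "K2", "radius_cv_achieved"]].round(4))

piv = table.pivot(index="seed", columns="cv_pct", values="K2")
diff = piv[6.5] - piv[0.0]
print(f"\npaired K2 difference (CV 6.5% - CV 0%): "
      f"{diff.mean():.5f} +/- {diff.std(ddof=1) / np.sqrt(len(diff)):.5f}")
# K2 is strongly negative here: extravascular contrast accumulation keeps
# dephasing the tissue after the bolus (T2*-dominant leakage). The radius-CV
# effect is a second-order perturbation of that dephasing and sits near the
# Monte-Carlo resolution limit at this problem size.
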