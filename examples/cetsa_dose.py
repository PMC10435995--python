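"""Dose-resolved CETSA: band ratios, Z-scores, minimal stabilising dose.

Simulates immunoblot band intensities of a target protein (with loading
control) at one denaturing temperature across a drug dilution series, for
two drugs with different intracellular potencies, and summarises each
series by the lowest dose with clear stabilisation (Z >= 0.5).
"""

import numpy as np
import pandas as pd

from thermoshift.cetsa import min_stabilizing_dose, quantify_ratio, zscore_series
from thermoshift.syndata import gen_cetsa

doses = 10.0 ** np.arange(0, 2.5, 0.5)  # 1 .. 100 nM
potent = gen_cetsa(doses, ec50_stab_nm=10.0, noise_cv=0.03, seed=1, drug="potent")
weak = gen_cetsa(doses, ec50_stab_nm=100.0, noise_cv=0.03, seed=2, drug="weak")

table = zscore_series(quantify_ratio(pd.concat([potent, weak], ignore_index=True)))
print(table[["drug", "dose_nm", "ratio", "z"]].round(3).to_string(index=False))

for drug, grp in table.groupby("drug"):
    dose = min_stabilizing_dose(grp, threshold=0.5)
    print(f"{drug}: minimal stabilising dose = "
          f"{dose if dose is not None else 'none in range'} nM")
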