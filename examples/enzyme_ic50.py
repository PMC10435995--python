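"""Competitive enzyme inhibition: rates to IC50 and the Cheng-Prusoff check.

Models a reductase assay followed by NADPH turnover (absorbance at 340 nm)
with a competitive inhibitor. For competitive inhibition the IC50 measured
at substrate concentration S obeys IC50 = Ki * (1 + S/Km), so an inhibitor
with nanomolar Ki shows a much higher apparent IC50 under substrate excess.
"""

import numpy as np

from thermoshift.binding import EnzymeAssay, ic50_from_rates, inhibited_rate

# 50 uM substrate against a 5 uM Km: 11x substrate excess over Km
assay = EnzymeAssay(substrate_um=50.0, km_um=5.0, ki_nm=90.0, vmax=1.5)
doses = np.logspace(0, 5, 12)  # 1 nM .. 100 uM
rates = inhibited_rate(assay, doses)

res = ic50_from_rates(doses, rates)
cheng_prusoff = assay.ki_nm * (1 + assay.substrate_um / assay.km_um)
print(f"Ki = {assay.ki_nm} nM at S = {assay.substrate_um} uM (Km {assay.km_um} uM)")
print(f"fitted IC50 = {res.ic50_nm:.0f} nM; Cheng-Prusoff predicts "
      f"{cheng_prusoff:.0f} nM")
print("-> a ~90 nM-Ki inhibitor presents as a ~1 uM IC50 under substrate excess")
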