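"""Blood-gas dissociation curves: Hill saturation and the CO2 power law.

Evaluates the O2 saturation curve at venous conditions and fits the
power-law CO2 dissociation curve C = q*P^t at the venous anchor, then
shows the Haldane shift: the same fit re-anchored at full saturation
stores visibly less CO2 at every partial pressure.
"""

from hfmox import (
    BloodConstants,
    co2_content,
    co2_fit_content,
    fit_co2_curve,
    hill_inverse,
    hill_saturation,
)

consts = BloodConstants()

po2_venous = hill_inverse(0.65, consts)
print(f"venous PO2 at 65% saturation: {po2_venous:.2f} mmHg")
print(f"saturation at P50 ({consts.p50} mmHg): {hill_saturation(consts.p50, consts):.2f}")

for so2 in (0.65, 1.0):
    anchor_c = co2_content(45.0, so2, consts)
    fit = fit_co2_curve(45.0, anchor_c, consts)
    print(
        f"SO2={so2:.2f}: anchor C(45 mmHg)={anchor_c:.4f} mL/mL, "
        f"fit q={fit.q:.4f}, t={fit.t:.4f}, "
        f"C(30)={co2_fit_content(30.0, fit):.4f}, C(60)={co2_fit_content(60.0, fit):.4f}"
    )

# The drop in content from SO2=0.65 to SO2=1.0 at fixed PCO2 is the
# Haldane effect: oxygenated hemoglobin holds less CO2, so the same
# total CO2 exerts a higher partial pressure and is easier to remove.
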