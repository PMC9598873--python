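"""Blood-gas content relations.

This module collects the empirical chemistry the device model is built on:

* the Hill equation for hemoglobin O2 saturation and its analytic slope,
* total O2 content (dissolved + hemoglobin-bound),
* plasma bicarbonate via Henderson-Hasselbalch,
* whole-blood CO2 content via the Visser/McHardy relation, which carries
  the Haldane effect through its explicit SO2 dependence, and
* the power-law representation of the CO2 dissociation curve
  ``C_CO2 = q * P_CO2 ** t`` with exponent pinned by the Peters slope
  relation and coefficient anchored at a known (PCO2, CCO2) pair.

Unit regime: gas contents are carried internally in mL gas per mL blood;
hemoglobin is supplied in the clinical g/dL and divided by 100 wherever a
per-mL mass is needed.  The Peters relation is an inherently per-dL
empirical fit, so the exponent solve works in mL/dL and converts at the
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

__all__ = [
    "BloodConstants",
    "CO2FitParams",
    "BloodGasState",
    "hill_saturation",
    "hill_slope",
    "hill_inverse",
    "o2_content",
    "bicarbonate",
    "co2_content",
    "peters_slope_rhs",
    "fit_co2_curve",
    "co2_fit_content",
    "co2_fit_slope",
    "static_fit_params",
    "oxyhemoglobin_grams",
]

# Peters (1924): C(60) - C(30) in mL/dL is linear in O2 capacity; with
# 1.36 mL O2 binding per g Hb the capacity term becomes 0.4542 * Hb.
PETERS_INTERCEPT = 6.3
PETERS_O2CAP_COEFF = 0.334
O2_PER_G_HB = 1.36
PETERS_HB_COEFF = 0.4542

# Visser/McHardy whole-blood CO2 content constants (per-dL form).
_MCHARDY_PLASMA = 2.226
_MCHARDY_HB = 0.02924
_MCHARDY_SO2_A = 2.244
_MCHARDY_SO2_B = 0.422
_MCHARDY_PH_REF = 8.74

# Henderson-Hasselbalch bicarbonate prefactor and pK.
_HH_ALPHA = 0.0301
_HH_PK = 6.10


@dataclass(frozen=True)
class BloodConstants:
    """Physical constants of the blood phase.

    Defaults are the standard in vitro oxygenator test conditions with
    adult bovine blood: venous inlet, Hb 12 g/dL, pH 7.4.

    Attributes
    ----------
    alpha_co2 : CO2 solubility, mL CO2 / (mL blood * mmHg).
    alpha_o2 : O2 solubility, mL O2 / (mL blood * mmHg).
    d_co2, d_hco3, d_o2 : diffusivities in blood, cm^2/s.
    c_t : hemoglobin O2-binding capacity, mL O2 / g Hb.
    hb : hemoglobin concentration, g/dL.
    ph : blood pH (held constant along the bundle).
    p50 : Hill half-saturation O2 partial pressure, mmHg.
    n_hill : Hill exponent (dimensionless).
    nu_b : kinematic viscosity of blood, cm^2/s.
    """

    alpha_co2: float = 6.62e-4
    alpha_o2: float = 3.0e-5
    d_co2: float = 7.39e-6
    d_hco3: float = 4.62e-6
    d_o2: float = 1.8e-5
    c_t: float = 1.34
    hb: float = 12.0
    ph: float = 7.4
    p50: float = 29.0
    n_hill: float = 2.85
    nu_b: float = 0.023

    def __post_init__(self) -> None:
        for name in (
            "alpha_co2",
            "alpha_o2",
            "d_co2",
            "d_hco3",
            "d_o2",
            "c_t",
            "hb",
            "p50",
            "nu_b",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"BloodConstants.{name} must be strictly positive")
        # Keep the McHardy bracket and the bicarbonate exponent finite/positive.
        if not (6.1 < self.ph < _MCHARDY_PH_REF):
            raise ValueError(
                f"BloodConstants.ph must lie in (6.10, {_MCHARDY_PH_REF}); got {self.ph}"
            )
        if self.n_hill < 1:
            raise ValueError("BloodConstants.n_hill must be >= 1")


@dataclass(frozen=True)
class CO2FitParams:
    """Power-law CO2 dissociation curve ``C = q * P**t`` with its anchor.

    ``q`` carries units mL CO2 / (mL blood * mmHg**t); ``t`` is
    dimensionless.  The anchor is the (PCO2, CCO2) pair the fit was
    solved at and is reproduced exactly by construction.
    """

    q: float
    t: float
    anchor_pco2: float
    anchor_cco2: float

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("CO2FitParams.q must be positive")
        if not (0 < self.t < 5):
            raise ValueError("CO2FitParams.t must lie in (0, 5)")
        rel = abs(self.q * self.anchor_pco2**self.t - self.anchor_cco2)
        if rel > 1e-10 * abs(self.anchor_cco2):
            raise ValueError("CO2FitParams does not reproduce its anchor")


@dataclass(frozen=True)
class BloodGasState:
    """Local blood-gas state: partial pressures plus derived contents."""

    pco2: float
    po2: float
    so2: float
    c_o2: float
    c_co2: float

    @classmethod
    def from_pressures(
        cls, pco2: float, po2: float, consts: BloodConstants
    ) -> "BloodGasState":
        so2 = hill_saturation(po2, consts)
        return cls(
            pco2=pco2,
            po2=po2,
            so2=so2,
            c_o2=o2_content(po2, consts),
            c_co2=co2_content(pco2, so2, consts),
        )


def hill_saturation(po2: float, consts: BloodConstants) -> float:
    """Hemoglobin O2 saturation (fraction) from the Hill equation.

    S = (P/P50)^n / (1 + (P/P50)^n); monotone increasing, in [0, 1).
    """
    if po2 < 0:
        raise ValueError(f"po2 must be non-negative, got {po2}")
    x = (po2 / consts.p50) ** consts.n_hill
    return x / (1.0 + x)


def hill_slope(po2: float, consts: BloodConstants) -> float:
    """dS/dPO2 of the Hill equation, mmHg^-1.

    Uses the identity dS/dP = n * S * (1 - S) / P, with the analytic
    P -> 0 limit (0 for n > 1).
    """
    if po2 < 0:
        raise ValueError(f"po2 must be non-negative, got {po2}")
    if po2 == 0.0:
        if consts.n_hill > 1:
            return 0.0
        # n == 1: slope at the origin is 1/P50
        return 1.0 / consts.p50
    s = hill_saturation(po2, consts)
    return consts.n_hill * s * (1.0 - s) / po2


def hill_inverse(so2: float, consts: BloodConstants) -> float:
    """PO2 (mmHg) at a given saturation: closed-form Hill inverse."""
    if not 0.0 < so2 < 1.0:
        raise ValueError(f"so2 must lie strictly in (0, 1), got {so2}")
    return consts.p50 * (so2 / (1.0 - so2)) ** (1.0 / consts.n_hill)


def o2_content(po2: float, consts: BloodConstants) -> float:
    """Total blood O2 content, mL O2 / mL blood.

    Dissolved plasma O2 plus hemoglobin-bound O2; Hb/100 converts the
    clinical g/dL to g/mL so both terms are per mL blood.
    """
    return consts.alpha_o2 * po2 + consts.c_t * (consts.hb / 100.0) * hill_saturation(
        po2, consts
    )


def o2_content_slope(po2: float, consts: BloodConstants) -> float:
    """dC_O2/dPO2, mL O2 / (mL blood * mmHg)."""
    return consts.alpha_o2 + consts.c_t * (consts.hb / 100.0) * hill_slope(po2, consts)


def bicarbonate(pco2: float, consts: BloodConstants) -> float:
    """Plasma bicarbonate from Henderson-Hasselbalch, mmol/L.

    Linear in PCO2 at fixed pH: 0.0301 * PCO2 * (1 + 10**(pH - 6.10)).
    """
    if pco2 < 0:
        raise ValueError(f"pco2 must be non-negative, got {pco2}")
    return _HH_ALPHA * pco2 * (1.0 + 10.0 ** (consts.ph - _HH_PK))


def co2_content(pco2: float, so2: float, consts: BloodConstants) -> float:
    """Whole-blood CO2 content (Visser/McHardy), mL CO2 / mL blood.

    The hemoglobin correction enters as a division,

        C = 2.226 * HCO3- * [1 - 0.02924*Hb / ((2.244 - 0.422*SO2)*(8.74 - pH))]

    (per-dL form, divided by 100 on return), so content falls as SO2
    rises at fixed PCO2 -- the Haldane effect.  SO2 is a fraction.
    """
    if pco2 < 0:
        raise ValueError(f"pco2 must be non-negative, got {pco2}")
    if not 0.0 <= so2 <= 1.0:
        raise ValueError(f"so2 must lie in [0, 1], got {so2}")
    denom = (_MCHARDY_SO2_A - _MCHARDY_SO2_B * so2) * (_MCHARDY_PH_REF - consts.ph)
    bracket = 1.0 - _MCHARDY_HB * consts.hb / denom
    if bracket <= 0.0:
        raise ValueError(
            "nonphysical Hb/pH/SO2 combination: McHardy correction factor "
            f"{bracket:.4g} <= 0 (hb={consts.hb}, ph={consts.ph}, so2={so2})"
        )
    per_dl = _MCHARDY_PLASMA * bicarbonate(pco2, consts) * bracket
    return per_dl / 100.0


def peters_slope_rhs(hb: float) -> float:
    """Peters content difference C(60 mmHg) - C(30 mmHg), mL CO2 / dL.

    Empirically linear in hemoglobin: 0.4542 * Hb + 6.3, the 0.4542
    being 0.334 per mL/dL of O2 capacity times 1.36 mL O2 per g Hb.
    """
    if hb <= 0:
        raise ValueError(f"hb must be positive, got {hb}")
    return PETERS_HB_COEFF * hb + PETERS_INTERCEPT


def _peters_residual(t: float, anchor_pco2: float, anchor_cco2_dl: float, hb: float) -> float:
    """Residual of the exponent equation, per-dL space."""
    lhs = anchor_cco2_dl * (
        (60.0 / anchor_pco2) ** t - (30.0 / anchor_pco2) ** t
    )
    return lhs - peters_slope_rhs(hb)


def fit_co2_curve(
    anchor_pco2: float, anchor_cco2: float, consts: BloodConstants
) -> CO2FitParams:
    """Fit the power-law CO2 dissociation curve through a known point.

    The exponent t solves

        C * ((60/P)^t - (30/P)^t) = 0.4542*Hb + 6.3   (C, RHS in mL/dL)

    by a bracketed root solve on t in (1e-6, 5) to residual < 1e-10,
    after which q = C / P**t reproduces the anchor exactly.

    Parameters
    ----------
    anchor_pco2 : anchor CO2 partial pressure, mmHg (> 0).
    anchor_cco2 : anchor CO2 content, mL/mL blood (> 0).
    """
    if anchor_pco2 <= 0 or anchor_cco2 <= 0:
        raise ValueError("anchor_pco2 and anchor_cco2 must be positive")
    c_dl = anchor_cco2 * 100.0
    lo, hi = 1e-6, 5.0
    r_lo = _peters_residual(lo, anchor_pco2, c_dl, consts.hb)
    r_hi = _peters_residual(hi, anchor_pco2, c_dl, consts.hb)
    if r_lo * r_hi > 0:
        raise RuntimeError(
            "CO2-curve exponent bracket has no sign change on (1e-6, 5): "
            f"residual({lo})={r_lo:.6g}, residual({hi})={r_hi:.6g} "
            f"(anchor P={anchor_pco2} mmHg, C={anchor_cco2} mL/mL, Hb={consts.hb})"
        )
    t = brentq(
        _peters_residual,
        lo,
        hi,
        args=(anchor_pco2, c_dl, consts.hb),
        xtol=1e-14,
        rtol=8.9e-16,
    )
    assert abs(_peters_residual(t, anchor_pco2, c_dl, consts.hb)) < 1e-10
    q = anchor_cco2 / anchor_pco2**t
    return CO2FitParams(q=q, t=t, anchor_pco2=anchor_pco2, anchor_cco2=anchor_cco2)


def co2_fit_content(pco2: float, fit: CO2FitParams) -> float:
    """CO2 content from the fitted power law, mL/mL: q * P**t."""
    if pco2 <= 0:
        raise ValueError(f"pco2 must be positive, got {pco2}")
    return fit.q * pco2**fit.t


def co2_fit_slope(pco2: float, fit: CO2FitParams) -> float:
    """Slope of the fitted dissociation curve, mL/(mL*mmHg): q*t*P**(t-1)."""
    if pco2 <= 0:
        if fit.t < 1:
            raise ValueError("slope is singular at pco2=0 for t < 1")
        raise ValueError(f"pco2 must be positive, got {pco2}")
    return fit.q * fit.t * pco2 ** (fit.t - 1.0)


def static_fit_params(
    consts: BloodConstants, anchor_pco2: float = 45.0
) -> CO2FitParams:
    """Fixed dissociation curve for the no-Haldane model variant.

    The static variant assumes fully oxygenated blood (SO2 = 1) at
    Hb = 15 g/dL and holds the resulting (q, t) for the whole bundle.
    The anchor pressure defaults to the venous inlet PCO2 of 45 mmHg.
    """
    static_consts = replace(consts, hb=15.0)
    anchor_cco2 = co2_content(anchor_pco2, 1.0, static_consts)
    return fit_co2_curve(anchor_pco2, anchor_cco2, static_consts)


def oxyhemoglobin_grams(hb: float, so2: float) -> float:
    """Hemoglobin present as oxyhemoglobin, g/dL: hb * so2."""
    if hb < 0:
        raise ValueError(f"hb must be non-negative, got {hb}")
    if not 0.0 <= so2 <= 1.0:
        raise ValueError(f"so2 must lie in [0, 1], got {so2}")
    return hb * so2
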