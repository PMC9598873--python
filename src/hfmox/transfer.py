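"""Packed-bed mass-transfer correlation and blood-side film coefficients.

The fiber bundle is treated as a packed bed: a Sherwood-Reynolds-Schmidt
power-law correlation, Sh = a * Re^b * Sc^(1/3), lumps all transport
resistance into the blood-side film.  Species-specific physics enters
through the diffusivity used in each dimensionless group:

* CO2 uses a *facilitated* diffusivity in the Sherwood number (parallel
  bicarbonate diffusion augments dissolved-CO2 diffusion) and an
  *effective* diffusivity in the Schmidt number (bicarbonate and
  hemoglobin-bound CO2 travel only by convection);
* O2 uses the plain molecular diffusivity in the Sherwood number (bound
  O2 never leaves the red cell) and an effective diffusivity in the
  Schmidt number.

Both corrections are driven by the local slope of the relevant
dissociation curve, so the coefficients vary along the bundle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .blood import BloodConstants

__all__ = [
    "BundleGeometry",
    "CorrelationCoeffs",
    "superficial_velocity",
    "packing_specific_surface",
    "reynolds",
    "facilitated_diffusivity",
    "effective_diffusivity_co2",
    "effective_diffusivity_o2",
    "mass_transfer_coefficient",
    "k_co2",
    "k_o2",
]


@dataclass(frozen=True)
class BundleGeometry:
    """Geometry of an axial-flow hollow-fiber bundle.

    Defaults describe the ModELAS pediatric pump-lung bundle.

    Attributes
    ----------
    frontal_area : cross-section perpendicular to blood flow, cm^2.
    area_per_volume : fiber surface per bundle volume, cm^-1.
    active_area : total gas-exchanging fiber surface, cm^2.
    fiber_od : outer diameter of one fiber, cm.
    porosity : void fraction of the bundle, in (0, 1).
    length : axial integration length, cm.
    packing_psi : packing-geometry correction in the Reynolds number.
    particle_diameter : optional equivalent particle diameter, cm.  When
        None it is inferred as 6*(1-E)/a_v, which makes the packed-bed
        specific surface coincide with the tabulated area_per_volume.
    """

    frontal_area: float = 16.0
    area_per_volume: float = 55.0
    active_area: float = 6700.0
    fiber_od: float = 0.038
    porosity: float = 0.48
    length: float = 7.9
    packing_psi: float = 0.91
    particle_diameter: float | None = None

    def __post_init__(self) -> None:
        for name in ("frontal_area", "area_per_volume", "active_area", "fiber_od", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BundleGeometry.{name} must be strictly positive")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError(f"BundleGeometry.porosity must lie in (0, 1), got {self.porosity}")
        if not 0.0 < self.packing_psi <= 1.0:
            raise ValueError(f"BundleGeometry.packing_psi must lie in (0, 1], got {self.packing_psi}")
        if self.particle_diameter is not None and self.particle_diameter <= 0:
            raise ValueError("BundleGeometry.particle_diameter must be positive when set")


@dataclass(frozen=True)
class CorrelationCoeffs:
    """Empirical coefficients of Sh = a * Re^b * Sc^(1/3), fit in water."""

    corr_a: float = 0.54
    corr_b: float = 0.42

    def __post_init__(self) -> None:
        if self.corr_a <= 0 or self.corr_b <= 0:
            raise ValueError("correlation coefficients must be positive")


def superficial_velocity(qb: float, geom: BundleGeometry) -> float:
    """Superficial blood velocity, cm/s, from flow in mL/min."""
    if qb < 0:
        raise ValueError(f"qb must be non-negative, got {qb}")
    return (qb / 60.0) / geom.frontal_area


def packing_specific_surface(geom: BundleGeometry) -> float:
    """Specific surface 6*(1-E)/d_p of the packed bed, cm^-1.

    With no explicit particle diameter, d_p is backed out of the
    tabulated area-to-volume ratio, so this returns area_per_volume
    exactly; an explicit d_p override takes precedence.
    """
    if geom.particle_diameter is not None:
        return 6.0 * (1.0 - geom.porosity) / geom.particle_diameter
    return geom.area_per_volume


def implied_particle_diameter(geom: BundleGeometry) -> float:
    """Equivalent particle diameter used by the Reynolds number, cm."""
    if geom.particle_diameter is not None:
        return geom.particle_diameter
    return 6.0 * (1.0 - geom.porosity) / geom.area_per_volume


def reynolds(qb: float, geom: BundleGeometry, consts: BloodConstants) -> float:
    """Packed-bed Reynolds number Re = V0 / (nu * psi * a); linear in qb."""
    v0 = superficial_velocity(qb, geom)
    return v0 / (consts.nu_b * geom.packing_psi * packing_specific_surface(geom))


def facilitated_diffusivity(slope: float, consts: BloodConstants) -> float:
    """Facilitated CO2 diffusivity, cm^2/s.

    D_f = D_CO2 + D_HCO3 * (dC/dP) / alpha_CO2: dissolved CO2 plus the
    parallel bicarbonate-diffusion pathway.  Always >= D_CO2.
    """
    if slope < 0:
        raise ValueError(f"dissociation-curve slope must be non-negative, got {slope}")
    return consts.d_co2 + consts.d_hco3 * slope / consts.alpha_co2


def effective_diffusivity_co2(d_fac: float, slope: float, consts: BloodConstants) -> float:
    """Effective CO2 diffusivity for the Schmidt number, cm^2/s.

    D_eff = D_f / (1 + (dC/dP)/alpha_CO2): the chemically stored CO2 is
    carried only by convection, which depresses the apparent diffusivity.
    """
    if slope < 0:
        raise ValueError(f"dissociation-curve slope must be non-negative, got {slope}")
    return d_fac / (1.0 + slope / consts.alpha_co2)


def effective_diffusivity_o2(dso2_dp: float, consts: BloodConstants) -> float:
    """Effective O2 diffusivity for the Schmidt number, cm^2/s.

    D_eff = D_O2 / (1 + m) with m = C_T * (Hb/100) * (dS/dP) / alpha_O2,
    the ratio of hemoglobin-bound to dissolved O2 capacitance.
    """
    if dso2_dp < 0:
        raise ValueError(f"Hill slope must be non-negative, got {dso2_dp}")
    m = consts.c_t * (consts.hb / 100.0) * dso2_dp / consts.alpha_o2
    return consts.d_o2 / (1.0 + m)


def _sherwood_k(
    alpha: float,
    d_sherwood: float,
    d_schmidt: float,
    qb: float,
    geom: BundleGeometry,
    coeffs: CorrelationCoeffs,
    consts: BloodConstants,
) -> float:
    """k = alpha * D * a * Re^b * Sc^(1/3) / d_f for one species."""
    if qb == 0.0:
        return 0.0
    re = reynolds(qb, geom, consts)
    sc = consts.nu_b / d_schmidt
    sh = coeffs.corr_a * re**coeffs.corr_b * sc ** (1.0 / 3.0)
    return alpha * d_sherwood * sh / geom.fiber_od


def k_co2(
    qb: float,
    slope: float,
    geom: BundleGeometry,
    coeffs: CorrelationCoeffs,
    consts: BloodConstants,
) -> float:
    """Blood-side CO2 mass-transfer coefficient, mL CO2/(cm^2 s mmHg).

    The Sherwood number carries the facilitated diffusivity, the Schmidt
    number the effective diffusivity; both depend on the local slope of
    the CO2 dissociation curve.
    """
    d_fac = facilitated_diffusivity(slope, consts)
    d_eff = effective_diffusivity_co2(d_fac, slope, consts)
    return _sherwood_k(consts.alpha_co2, d_fac, d_eff, qb, geom, coeffs, consts)


def k_o2(
    qb: float,
    dso2_dp: float,
    geom: BundleGeometry,
    coeffs: CorrelationCoeffs,
    consts: BloodConstants,
) -> float:
    """Blood-side O2 mass-transfer coefficient, mL O2/(cm^2 s mmHg)."""
    d_eff = effective_diffusivity_o2(dso2_dp, consts)
    return _sherwood_k(consts.alpha_o2, consts.d_o2, d_eff, qb, geom, coeffs, consts)


def mass_transfer_coefficient(
    species: str,
    qb: float,
    geom: BundleGeometry,
    coeffs: CorrelationCoeffs,
    consts: BloodConstants,
    *,
    co2_slope: float | None = None,
    hill_slope: float | None = None,
) -> float:
    """Dispatch to the CO2 or O2 film coefficient by species name.

    Parameters
    ----------
    species : "CO2" or "O2" (case-insensitive).
    co2_slope : local CO2 dissociation-curve slope, mL/(mL*mmHg);
        required for CO2.
    hill_slope : local Hill-curve slope dS/dP, mmHg^-1; required for O2.
    """
    if qb < 0:
        raise ValueError(f"qb must be non-negative, got {qb}")
    key = species.upper()
    if key == "CO2":
        if co2_slope is None:
            raise ValueError("co2_slope is required for species='CO2'")
        return k_co2(qb, co2_slope, geom, coeffs, consts)
    if key == "O2":
        if hill_slope is None:
            raise ValueError("hill_slope is required for species='O2'")
        return k_o2(qb, hill_slope, geom, coeffs, consts)
    raise ValueError(f"unknown species {species!r}; expected 'CO2' or 'O2'")
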