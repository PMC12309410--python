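"""Basin-scale ammonium flux budget and productivity-support arithmetic.

Upscales the areal seepage loss flux over the hydrothermally active trough
areas, computes the vent-endmember ammonium flux from the total hydrothermal
fluid flux, and converts nitrogen fluxes to carbon-fixation equivalents via
Redfield stoichiometry (C:N = 106:16 molar).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .refdata import Constants, ValidationError
from .nitrogen import LossModelFit, areal_loss_flux

__all__ = [
    "FluxBudget",
    "vent_flux",
    "basin_seepage_flux",
    "seepage_fraction",
    "biomass_support",
    "productivity_support",
    "pct_export",
    "vent_pct_export",
    "compute_budget",
]

_C = Constants()


def vent_flux(Q: float, c_mM: float) -> float:
    """Endmember ammonium flux Q * c in mol/s (Q in m^3/s, c in mM == mol/m^3)."""
    if Q < 0 or c_mM < 0:
        raise ValidationError("Q and c must be >= 0")
    return Q * c_mM


def basin_seepage_flux(F_areal_nmol: float, areas_m2: Sequence[float]) -> float:
    """Areal loss flux (nmol m^-2 s^-1) summed over trough areas, in mol/s."""
    areas = list(areas_m2)
    if not areas:
        raise ValidationError("need at least one area")
    if any(a <= 0 for a in areas):
        raise ValidationError("areas must be > 0")
    return F_areal_nmol * 1.0e-9 * sum(areas)


def seepage_fraction(F_seep: float, F_vent: float) -> float:
    """Seepage flux as a percentage of the vent-endmember flux."""
    if F_vent <= 0:
        raise ValidationError("vent flux must be > 0")
    return 100.0 * F_seep / F_vent


def biomass_support(F_N: float, C_to_N: float | None = None,
                    M_C: float | None = None,
                    sec_per_year: float | None = None) -> float:
    """Dry-carbon biomass a nitrogen flux could sustain, kg C per year.

    F_N in mol N/s; Redfield C:N converts to mol C/s, the molar mass of C
    and the length of a year convert to kg C/yr.
    """
    if F_N < 0:
        raise ValidationError("nitrogen flux must be >= 0")
    C_to_N = _C.redfield_C_to_N if C_to_N is None else C_to_N
    M_C = _C.M_C if M_C is None else M_C
    sec_per_year = _C.sec_per_year if sec_per_year is None else sec_per_year
    return F_N * C_to_N * M_C * sec_per_year / 1000.0


def productivity_support(F_N: float, basin_area: float | None = None,
                         C_to_N: float | None = None,
                         sec_per_year: float | None = None) -> float:
    """Carbon fixation the nitrogen flux could support, mol C m^-2 yr^-1.

    Assumes steady state, complete vertical mixing and a closed basin: the
    whole nitrogen flux is spread over ``basin_area`` and fixed at Redfield
    stoichiometry.
    """
    basin_area = _C.basin_area if basin_area is None else basin_area
    C_to_N = _C.redfield_C_to_N if C_to_N is None else C_to_N
    sec_per_year = _C.sec_per_year if sec_per_year is None else sec_per_year
    if basin_area <= 0:
        raise ValidationError("basin area must be > 0")
    if F_N < 0:
        raise ValidationError("nitrogen flux must be >= 0")
    return F_N * C_to_N * sec_per_year / basin_area


def pct_export(productivity: float, export_prod: float | None = None) -> float:
    """Supported productivity as % of the basin's biological export production."""
    export_prod = _C.export_prod if export_prod is None else export_prod
    if export_prod <= 0:
        raise ValidationError("export production must be > 0")
    return 100.0 * productivity / export_prod


def vent_pct_export(F_vent: float, basin_area: float | None = None,
                    C_to_N: float | None = None,
                    export_prod: float | None = None,
                    sec_per_year: float | None = None) -> float:
    """Export-production fraction supportable by the vent-endmember flux, %."""
    return pct_export(
        productivity_support(F_vent, basin_area, C_to_N, sec_per_year),
        export_prod,
    )


@dataclass
class FluxBudget:
    """Low/high budget chain for one fitted loss model under one Constants set."""

    areal_loss_low: float       # nmol m^-2 s^-1 at SR_low
    areal_loss_high: float      # nmol m^-2 s^-1 at SR_high
    basin_seepage_low: float    # mol/s
    basin_seepage_high: float   # mol/s
    vent_low: float             # mol/s
    vent_high: float            # mol/s
    seepage_pct_low: float      # % of vent flux (low seepage / low vent)
    seepage_pct_high: float     # % of vent flux (high seepage / high vent)
    biomass_low: float          # kg C/yr
    biomass_high: float         # kg C/yr
    productivity_low: float     # mol C m^-2 yr^-1
    productivity_high: float    # mol C m^-2 yr^-1
    pct_export_low: float       # %
    pct_export_high: float      # %
    vent_pct_export_low: float  # %
    vent_pct_export_high: float # %
    inputs: dict = field(default_factory=dict)


def compute_budget(fit: LossModelFit, constants: Constants | None = None) -> FluxBudget:
    """Run the full upscaling chain from a fitted loss model.

    The low endpoint pairs the low sedimentation rate with the low fluid
    flux; the high endpoint pairs the highs.  All intermediate quantities
    are carried at full precision; rounding is presentation-only.
    """
    c = constants or Constants()
    areas = [c.area_S, c.area_N]
    out = {}
    for tag, SR, Q in (("low", c.SR_low, c.Q_low), ("high", c.SR_high, c.Q_high)):
        F_areal = areal_loss_flux(fit, SR, c.rho_dry, c.M_N, c.sec_per_year)
        F_seep = basin_seepage_flux(F_areal, areas)
        F_vent = vent_flux(Q, c.c_endmember)
        prod = productivity_support(F_seep, c.basin_area, c.redfield_C_to_N,
                                    c.sec_per_year)
        out[tag] = dict(
            areal=F_areal, seep=F_seep, vent=F_vent,
            seep_pct=seepage_fraction(F_seep, F_vent),
            biomass=biomass_support(F_seep, c.redfield_C_to_N, c.M_C,
                                    c.sec_per_year),
            prod=prod,
            pct=pct_export(prod, c.export_prod),
            vent_pct=vent_pct_export(F_vent, c.basin_area, c.redfield_C_to_N,
                                     c.export_prod, c.sec_per_year),
        )
    return FluxBudget(
        areal_loss_low=out["low"]["areal"], areal_loss_high=out["high"]["areal"],
        basin_seepage_low=out["low"]["seep"], basin_seepage_high=out["high"]["seep"],
        vent_low=out["low"]["vent"], vent_high=out["high"]["vent"],
        seepage_pct_low=out["low"]["seep_pct"], seepage_pct_high=out["high"]["seep_pct"],
        biomass_low=out["low"]["biomass"], biomass_high=out["high"]["biomass"],
        productivity_low=out["low"]["prod"], productivity_high=out["high"]["prod"],
        pct_export_low=out["low"]["pct"], pct_export_high=out["high"]["pct"],
        vent_pct_export_low=out["low"]["vent_pct"], vent_pct_export_high=out["high"]["vent_pct"],
        inputs=dict(
            f_loss=fit.f_loss, y0=fit.y0, x_b=fit.x_b,
            SR_low=c.SR_low, SR_high=c.SR_high, rho_dry=c.rho_dry,
            area_S=c.area_S, area_N=c.area_N, basin_area=c.basin_area,
            Q_low=c.Q_low, Q_high=c.Q_high, c_endmember=c.c_endmember,
            C_to_N=c.redfield_C_to_N, export_prod=c.export_prod,
        ),
    )
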