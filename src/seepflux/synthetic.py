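"""Seeded generators for synthetic core profiles.

The generators emulate the statistical structure the analysis assumes:
exponentially decaying sedimentary nitrogen with a refractory floor plus
Gaussian noise, d15N shifting with depth as Rayleigh loss of isotopically
light nitrogen, TOC loosely coupled to TN so the C/N ratio drifts from
fresh-biomass values (~9) toward altered values (~21), advection-curved
temperature profiles, and near-constant porewater NH4+ with depth.

Every generator is deterministic for a fixed seed; sediment, thermal and
porewater calls draw from independent substreams of the same seed so adding
one generator call never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .refdata import (
    PorewaterProfile,
    SedimentProfile,
    ThermalProfile,
    ValidationError,
    load_reference,
)
from .thermal import forward_temperature

__all__ = ["SynthParams", "GUAYMAS_DEMO", "make_sediment", "make_thermal",
           "make_porewater", "get_preset"]


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic seep-core generator."""

    y0: float = 1.1                # wt% N at seafloor
    a: float = 0.89                # per-cm retention coefficient
    x_b: float = 6.7               # cm breakpoint
    depth_max: float = 20.0        # cm deepest sediment sample
    sample_step: float = 1.0       # cm sampling interval
    noise_sd_frac: float = 0.05    # Gaussian noise sd as a fraction of y0
    toc0: float = 9.9              # wt% TOC at seafloor (C/N ~9 with y0)
    cn_deep: float = 21.0          # deep C/N mass ratio the TOC trend approaches
    beta: float = -0.54            # thermal Peclet number (negative = discharge)
    T_top: float = 3.0             # degC bottom water
    T_bottom: float = 63.0         # degC at the deepest probe reading
    thermal_depth_m: float = 0.4   # m, probe reaches 40 cm at 10 cm spacing
    temp_noise_sd: float = 0.0     # degC
    nh4_mean: float = 3.58         # mM porewater ammonium
    nh4_sd: float = 0.11           # mM
    delta0: float = 6.0            # permil, seafloor (mat) d15N
    epsilon: float = -3.3          # permil, removed-minus-substrate fractionation
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 < self.a <= 1.0:
            raise ValidationError("retention coefficient a must be in (0, 1]")
        if self.noise_sd_frac < 0 or self.sample_step <= 0:
            raise ValidationError("noise_sd_frac >= 0 and sample_step > 0 required")

    def replace(self, **kwargs) -> "SynthParams":
        return replace(self, **kwargs)


#: parameter set echoing the hot seepage core of the study site
#: (synthetic stand-in for documentation and tests; not measured data)
GUAYMAS_DEMO = SynthParams()

_PRESETS = {"guaymas_demo": GUAYMAS_DEMO}


def get_preset(name: str) -> SynthParams:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")


def _rng(params: SynthParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def _tn_model(params: SynthParams, depth: np.ndarray) -> np.ndarray:
    return np.where(depth <= params.x_b,
                    params.y0 * params.a ** depth,
                    params.y0 * params.a ** params.x_b)


def _sample_depths(params: SynthParams) -> np.ndarray:
    n = int(math.floor(params.depth_max / params.sample_step + 1e-9))
    return params.sample_step * np.arange(1, n + 1)


def make_sediment(params: SynthParams, core_id: str = "synthetic-1") -> SedimentProfile:
    """Synthetic sediment core with TN, TOC, isotopes and a basic element suite.

    Elements: Al near 6 wt% (detrital, depth-constant), K at its crustal
    K/Al ratio, P enriched toward the surface, and the 14 REEs at ~0.6x
    shale abundance; all with the same relative noise as TN so dilution
    invariances remain testable.  ``pw_mass_fraction`` is constant at 1.2
    g/g (soupy seep sediment).
    """
    rng = _rng(params, 1)
    depth = _sample_depths(params)
    model = _tn_model(params, depth)
    noise = rng.normal(0.0, params.noise_sd_frac * params.y0, size=depth.shape)
    tn = np.clip(model + noise, 0.0, None)
    f_local = model / params.y0  # fraction of the seafloor N stock remaining
    d15n = params.delta0 + params.epsilon * np.log(f_local)
    d15n = d15n + rng.normal(0.0, 4.0 * params.noise_sd_frac, size=depth.shape)
    d13c = -22.1 + rng.normal(0.0, 8.0 * params.noise_sd_frac, size=depth.shape)

    cn0 = params.toc0 / params.y0
    cn = cn0 + (params.cn_deep - cn0) * np.minimum(depth / params.x_b, 1.0)
    toc = np.clip(model * cn * (1.0 + rng.normal(0.0, params.noise_sd_frac,
                                                 size=depth.shape)), 0.0, None)

    rel = lambda: 1.0 + rng.normal(0.0, params.noise_sd_frac, size=depth.shape)
    ucc = load_reference("UCC")
    paas = load_reference("PAAS")
    al = 60000.0 * rel()
    elements = {"Al": np.clip(al, 0, None)}
    elements["K"] = np.clip(al * ucc["K"] / ucc["Al"] * rel(), 0, None)
    p_enrich = 1.0 + 2.0 * f_local  # organic P follows the labile N fraction
    elements["P"] = np.clip(al * ucc["P"] / ucc["Al"] * p_enrich * rel(), 0, None)
    for sym, ppm in paas.values.items():
        elements[sym] = np.clip(0.6 * ppm * rel(), 0, None)
    return SedimentProfile(
        core_id=core_id, depth_cm=depth, toc=toc, tn=tn, d13c=d13c, d15n=d15n,
        elements=elements, pw_mass_fraction=np.full_like(depth, 1.2),
    )


def make_thermal(params: SynthParams, core_id: str = "synthetic-1") -> ThermalProfile:
    """Thermal-probe profile at 10 cm spacing from the forward flow model."""
    rng = _rng(params, 2)
    depth_m = np.arange(0.0, params.thermal_depth_m + 1e-9, 0.1)
    temps = forward_temperature(depth_m, params.beta, params.thermal_depth_m,
                                params.T_top, params.T_bottom)
    temps = np.asarray(temps) + rng.normal(0.0, params.temp_noise_sd,
                                           size=depth_m.shape)
    return ThermalProfile(core_id=core_id, depth_m=depth_m, temp_C=temps)


def make_porewater(params: SynthParams, core_id: str = "synthetic-1") -> PorewaterProfile:
    """Near-constant porewater NH4+ profile with Rayleigh-consistent d15N."""
    rng = _rng(params, 3)
    depth = _sample_depths(params)
    nh4 = np.clip(params.nh4_mean + rng.normal(0.0, params.nh4_sd, size=depth.shape),
                  0.0, None)
    f_local = _tn_model(params, depth) / params.y0
    # porewater NH4+ sits slightly heavier than coexisting sediment N
    d15n = params.delta0 + params.epsilon * np.log(f_local) + 0.5
    d15n = d15n + rng.normal(0.0, 4.0 * params.noise_sd_frac, size=depth.shape)
    return PorewaterProfile(core_id=core_id, depth_cm=depth, nh4_mM=nh4,
                            d15n_nh4=d15n)
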