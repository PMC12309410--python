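"""Nitrogen-isotope mass-balance utilities.

Rayleigh (closed-system) distillation of a shrinking nitrogen pool, simple
two-pool mixing, and the apparent fractionation between paired porewater and
sediment measurements.

Sign convention: epsilon = delta(removed N) - delta(bulk substrate).  A
negative epsilon means the remobilized phase is isotopically light, so the
residual sediment grows heavier as the remaining fraction f shrinks:

    delta_residual(f) = delta0 + epsilon * ln(f),   0 < f <= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .refdata import PorewaterProfile, SedimentProfile, ValidationError

__all__ = [
    "IsotopeSystem",
    "rayleigh_residual",
    "mix_delta",
    "apparent_fractionation",
    "pair_profiles",
]


@dataclass(frozen=True)
class IsotopeSystem:
    """A Rayleigh system: initial composition, fractionation, remaining fraction."""

    delta0: float   # permil
    epsilon: float  # permil, product minus substrate
    f: float        # fraction of substrate remaining, (0, 1]

    def __post_init__(self) -> None:
        if not 0.0 < self.f <= 1.0:
            raise ValidationError("remaining fraction f must be in (0, 1]")
        if not math.isfinite(self.epsilon):
            raise ValidationError("epsilon must be finite")


def rayleigh_residual(sys: IsotopeSystem | None = None, *,
                      delta0: float | None = None,
                      epsilon: float | None = None,
                      f: float | None = None) -> float:
    """Residual-pool composition delta0 + epsilon * ln(f), in permil.

    Accepts either an :class:`IsotopeSystem` or the three keyword scalars.
    At f = 1 the result is exactly delta0; composing two sequential loss
    steps f1 then f2 equals a single step with f1 * f2.
    """
    if sys is None:
        sys = IsotopeSystem(delta0=delta0, epsilon=epsilon, f=f)
    return sys.delta0 + sys.epsilon * math.log(sys.f)


def mix_delta(pools) -> float:
    """Mass-weighted mean isotope composition of a set of (mass, delta) pools."""
    pools = list(pools)
    masses = np.array([m for m, _ in pools], dtype=float)
    deltas = np.array([d for _, d in pools], dtype=float)
    if np.any(masses < 0):
        raise ValidationError("pool masses must be >= 0")
    total = masses.sum()
    if total <= 0:
        raise ValidationError("total pool mass must be > 0")
    return float((masses * deltas).sum() / total)


def apparent_fractionation(delta_a: float, delta_b: float) -> float:
    """Apparent offset delta_a - delta_b between two phases, in permil."""
    if not (math.isfinite(delta_a) and math.isfinite(delta_b)):
        raise ValidationError("deltas must be finite")
    return delta_a - delta_b


def pair_profiles(porewater: PorewaterProfile, sediment: SedimentProfile,
                  tol_cm: float = 1.0) -> list[dict]:
    """Porewater-minus-sediment d15N offsets paired by nearest depth.

    For every porewater sample with a measured d15N, the nearest sediment
    sample within ``tol_cm`` is used; samples without a partner inside the
    tolerance are reported with ``offset = None`` and flagged as gaps, never
    silently dropped.
    """
    if porewater.d15n_nh4 is None:
        raise ValidationError(f"core {porewater.core_id}: no porewater d15N data")
    out = []
    for i in range(porewater.n_samples):
        d_pw = float(porewater.d15n_nh4[i])
        if not math.isfinite(d_pw):
            continue
        depth = float(porewater.depth_cm[i])
        dist = np.abs(sediment.depth_cm - depth)
        j = int(np.argmin(dist))
        rec = {"depth_cm": depth, "d15n_porewater": d_pw}
        if dist[j] <= tol_cm:
            rec["d15n_sediment"] = float(sediment.d15n[j])
            rec["offset"] = apparent_fractionation(d_pw, float(sediment.d15n[j]))
            rec["gap"] = False
        else:
            rec["d15n_sediment"] = None
            rec["offset"] = None
            rec["gap"] = True
        out.append(rec)
    return out
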