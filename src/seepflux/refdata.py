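"""Domain types, reference compositions, physical constants and CSV/config IO.

Depth convention: centimetres below seafloor, positive downward, at sample
midpoints.  Thermal-probe profiles are converted to metres internally so the
heat-transport model works in SI units.  Porewater concentrations in mM are
treated as exactly mol m^-3 (dilute-solution convention).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "SedimentProfile",
    "PorewaterProfile",
    "ThermalProfile",
    "ReferenceComposition",
    "Constants",
    "REE_ELEMENTS",
    "load_reference",
    "read_profiles",
    "write_profiles",
    "load_config",
]


class SchemaError(ValueError):
    """A CSV file does not match the expected column schema."""


class ValidationError(ValueError):
    """A profile violates one of its physical invariants."""


#: The 14 naturally occurring rare earth elements, La through Lu (Pm excluded).
REE_ELEMENTS = (
    "La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd",
    "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu",
)

_VALID_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U".split()
)


# ---------------------------------------------------------------------------
# Profile containers
# ---------------------------------------------------------------------------

def _check_monotonic(depths: np.ndarray, what: str) -> None:
    if len(depths) > 1 and not np.all(np.diff(depths) > 0):
        raise ValidationError(f"{what}: depths must be strictly increasing")


@dataclass
class SedimentProfile:
    """Depth-ordered bulk geochemistry of one sediment core.

    ``elements`` holds one concentration array per element symbol, in ppm
    of dry sediment; Al given in wt% in the source file is converted to ppm
    on read.  ``pw_mass_fraction`` (g porewater per g dry sediment) enables
    sea-salt correction of soluble elements; it may be all-NaN if unknown.
    """

    core_id: str
    depth_cm: np.ndarray
    toc: np.ndarray            # wt% organic carbon
    tn: np.ndarray             # wt% total nitrogen
    d13c: np.ndarray           # permil vs VPDB
    d15n: np.ndarray           # permil vs air
    elements: dict[str, np.ndarray] = field(default_factory=dict)
    pw_mass_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth_cm = np.asarray(self.depth_cm, dtype=float)
        for name in ("toc", "tn", "d13c", "d15n"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.elements = {k: np.asarray(v, dtype=float) for k, v in self.elements.items()}
        if self.pw_mass_fraction is not None:
            self.pw_mass_fraction = np.asarray(self.pw_mass_fraction, dtype=float)
        self.validate()

    def validate(self) -> None:
        _check_monotonic(self.depth_cm, f"core {self.core_id}")
        if np.any(self.depth_cm <= 0):
            raise ValidationError(f"core {self.core_id}: depths must be > 0 cm")
        n = len(self.depth_cm)
        for name in ("toc", "tn", "d13c", "d15n"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValidationError(f"core {self.core_id}: {name} length mismatch")
        for name in ("toc", "tn"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"core {self.core_id}: negative {name}")
        for name in ("d13c", "d15n"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"core {self.core_id}: non-finite {name}")
        for sym, arr in self.elements.items():
            if sym not in _VALID_SYMBOLS:
                raise ValidationError(f"core {self.core_id}: unknown element {sym!r}")
            if len(arr) != n:
                raise ValidationError(f"core {self.core_id}: {sym} length mismatch")
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValidationError(f"core {self.core_id}: negative {sym} concentration")

    @property
    def n_samples(self) -> int:
        return len(self.depth_cm)


@dataclass
class PorewaterProfile:
    """Porewater ammonium chemistry of one core (mM == mol m^-3)."""

    core_id: str
    depth_cm: np.ndarray
    nh4_mM: np.ndarray
    d15n_nh4: np.ndarray | None = None   # permil vs air; NaN where not measured

    def __post_init__(self) -> None:
        self.depth_cm = np.asarray(self.depth_cm, dtype=float)
        self.nh4_mM = np.asarray(self.nh4_mM, dtype=float)
        if self.d15n_nh4 is not None:
            self.d15n_nh4 = np.asarray(self.d15n_nh4, dtype=float)
        self.validate()

    def validate(self) -> None:
        _check_monotonic(self.depth_cm, f"core {self.core_id}")
        if np.any(self.nh4_mM < 0):
            raise ValidationError(f"core {self.core_id}: negative NH4+ concentration")
        if len(self.nh4_mM) != len(self.depth_cm):
            raise ValidationError(f"core {self.core_id}: nh4_mM length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.depth_cm)

    def mean_nh4(self) -> float:
        return float(np.nanmean(self.nh4_mM))


@dataclass
class ThermalProfile:
    """Thermal-probe temperature readings down one core, depths in metres."""

    core_id: str
    depth_m: np.ndarray
    temp_C: np.ndarray

    def __post_init__(self) -> None:
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.depth_m) < 2:
            raise ValidationError(f"core {self.core_id}: need >= 2 temperature readings")
        _check_monotonic(self.depth_m, f"core {self.core_id}")
        if np.any(self.temp_C <= -2.0):
            raise ValidationError(f"core {self.core_id}: temperature below -2 degC")
        if len(self.temp_C) != len(self.depth_m):
            raise ValidationError(f"core {self.core_id}: temp length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.depth_m)


# ---------------------------------------------------------------------------
# Reference compositions
# ---------------------------------------------------------------------------

# Average upper continental crust, ppm (after Rudnick & Gao 2003).
_UCC_PPM = {
    "Al": 81500.0, "K": 23200.0, "Na": 24300.0, "Mg": 14900.0, "Ca": 25700.0,
    "Fe": 39200.0, "Ti": 3840.0, "Mn": 775.0, "P": 655.0, "S": 621.0,
    "Ba": 628.0, "Sr": 320.0, "Rb": 84.0, "Zr": 193.0, "V": 97.0,
    "Cr": 92.0, "Ni": 47.0, "Zn": 67.0, "Cu": 28.0, "Co": 17.3,
    "Pb": 17.0, "Th": 10.5, "U": 2.7, "Mo": 1.1, "As": 4.8,
    "Sb": 0.4, "Cd": 0.09, "Ag": 0.053,
    "La": 31.0, "Ce": 63.0, "Pr": 7.1, "Nd": 27.0, "Sm": 4.7, "Eu": 1.0,
    "Gd": 4.0, "Tb": 0.7, "Dy": 3.9, "Ho": 0.83, "Er": 2.3, "Tm": 0.30,
    "Yb": 1.96, "Lu": 0.31,
}

# Post-Archean Australian Shale REE abundances, ppm (Taylor & McLennan 1985).
_PAAS_PPM = {
    "La": 38.2, "Ce": 79.6, "Pr": 8.83, "Nd": 33.9, "Sm": 5.55, "Eu": 1.08,
    "Gd": 4.66, "Tb": 0.774, "Dy": 4.68, "Ho": 0.991, "Er": 2.85,
    "Tm": 0.405, "Yb": 2.82, "Lu": 0.433,
}

# Standard seawater major-ion composition at salinity 35, g per kg solution
# (reference composition of Millero et al. 2008).
_SEAWATER_G_KG = {
    "Cl": 19.353, "Na": 10.781, "Mg": 1.284, "S": 0.905, "Ca": 0.4119,
    "K": 0.399, "Br": 0.0673, "Sr": 0.0079, "B": 0.0045,
}


@dataclass(frozen=True)
class ReferenceComposition:
    """A named element table used for normalization.

    ``values`` are ppm for rock references (UCC, PAAS) and g per kg of
    solution for SEAWATER.
    """

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.name not in ("UCC", "PAAS", "SEAWATER"):
            raise KeyError(f"unknown reference composition {self.name!r}")
        if any(v <= 0 for v in self.values.values()):
            raise ValidationError(f"{self.name}: all reference values must be > 0")
        if self.name == "UCC" and "Al" not in self.values:
            raise ValidationError("UCC reference must contain Al")
        if self.name == "PAAS":
            missing = [e for e in REE_ELEMENTS if e not in self.values]
            if missing:
                raise ValidationError(f"PAAS reference missing REEs: {missing}")

    def __getitem__(self, element: str) -> float:
        return self.values[element]

    def __contains__(self, element: str) -> bool:
        return element in self.values


def load_reference(name: str, csv_path: str | Path | None = None) -> ReferenceComposition:
    """Return a packaged reference composition, or load a replacement CSV.

    A replacement CSV needs two columns: ``element`` and ``value`` (ppm for
    rock tables, g/kg for seawater).
    """
    name = name.upper()
    if csv_path is not None:
        df = pd.read_csv(csv_path)
        if not {"element", "value"} <= set(df.columns):
            raise SchemaError("reference CSV needs columns 'element' and 'value'")
        return ReferenceComposition(name, dict(zip(df["element"], df["value"].astype(float))))
    tables = {"UCC": _UCC_PPM, "PAAS": _PAAS_PPM, "SEAWATER": _SEAWATER_G_KG}
    if name not in tables:
        raise KeyError(f"unknown reference composition {name!r}")
    return ReferenceComposition(name, dict(tables[name]))


# ---------------------------------------------------------------------------
# Physical constants and study-site parameters
# ---------------------------------------------------------------------------

@dataclass
class Constants:
    """Physical constants and basin parameters, all overridable via config.

    Defaults reflect the Guaymas Basin Southern/Northern Trough setting:
    sedimentation rate 0.08-0.25 cm/yr, trough areas 100 + 200 km^2, total
    hydrothermal fluid flux 10-12 m^3/s with a 15.6 mM NH4+ endmember, and
    export production ~4.8 mol C m^-2 yr^-1.
    """

    M_N: float = 14.007            # g/mol
    M_C: float = 12.011            # g/mol
    redfield_C_to_N: float = 106.0 / 16.0   # molar
    sec_per_year: float = 3.156e7  # s
    rho_dry: float = 0.4           # g/cm^3 dry bulk density
    porosity: float = 0.8          # informational
    SR_low: float = 0.08           # cm/yr
    SR_high: float = 0.25          # cm/yr
    area_S: float = 1.0e8          # m^2, Southern Trough
    area_N: float = 2.0e8          # m^2, Northern Trough
    basin_area: float = 1.405e10   # m^2
    Q_low: float = 10.0            # m^3/s hydrothermal fluid flux
    Q_high: float = 12.0           # m^3/s
    c_endmember: float = 15.6      # mM NH4+ vent-fluid endmember
    export_prod: float = 4.8       # mol C m^-2 yr^-1
    lambda_s: float = 0.9          # W m^-1 K^-1 sediment thermal conductivity
    rho_cf: float = 4.18e6         # J m^-3 K^-1 pore-fluid volumetric heat capacity

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"constant {f.name} must be > 0")
        if self.SR_low > self.SR_high:
            raise ValidationError("SR_low must be <= SR_high")
        if self.Q_low > self.Q_high:
            raise ValidationError("Q_low must be <= Q_high")

    def with_overrides(self, **kwargs: float) -> "Constants":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_MANDATORY = {
    "sediment": ["core_id", "depth_cm", "toc_wt_pct", "tn_wt_pct",
                 "d13c_permil", "d15n_permil"],
    "porewater": ["core_id", "depth_cm", "nh4_mM"],
    "thermal": ["core_id", "depth_cm", "temp_c"],
}


def _build_sediment(core_id: str, g: pd.DataFrame) -> SedimentProfile:
    elements: dict[str, np.ndarray] = {}
    for col in g.columns:
        if col.endswith("_ppm"):
            elements[col[:-4]] = g[col].to_numpy(float)
        elif col.endswith("_wt_pct") and col not in ("toc_wt_pct", "tn_wt_pct"):
            # wt% element columns (typically Al) -> ppm
            elements[col[: -len("_wt_pct")]] = g[col].to_numpy(float) * 1.0e4
    pw = g["pw_mass_fraction"].to_numpy(float) if "pw_mass_fraction" in g.columns else None
    return SedimentProfile(
        core_id=core_id,
        depth_cm=g["depth_cm"].to_numpy(float),
        toc=g["toc_wt_pct"].to_numpy(float),
        tn=g["tn_wt_pct"].to_numpy(float),
        d13c=g["d13c_permil"].to_numpy(float),
        d15n=g["d15n_permil"].to_numpy(float),
        elements=elements,
        pw_mass_fraction=pw,
    )


def read_profiles(path: str | Path, schema: str) -> list:
    """Read one CSV of the given schema; return one profile per core.

    Units are converted to canonical form on read (element wt% -> ppm,
    thermal depth cm -> m); records are sorted by depth and validated.
    """
    if schema not in _MANDATORY:
        raise SchemaError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    profiles = []
    for core_id, g in df.groupby("core_id", sort=False):
        g = g.sort_values("depth_cm")
        if schema == "sediment":
            profiles.append(_build_sediment(str(core_id), g))
        elif schema == "porewater":
            d15 = (g["d15n_nh4_permil"].to_numpy(float)
                   if "d15n_nh4_permil" in g.columns else None)
            profiles.append(PorewaterProfile(
                core_id=str(core_id),
                depth_cm=g["depth_cm"].to_numpy(float),
                nh4_mM=g["nh4_mM"].to_numpy(float),
                d15n_nh4=d15,
            ))
        else:
            profiles.append(ThermalProfile(
                core_id=str(core_id),
                depth_m=g["depth_cm"].to_numpy(float) / 100.0,
                temp_C=g["temp_c"].to_numpy(float),
            ))
    return profiles


def write_profiles(profiles: Iterable, path: str | Path, schema: str) -> None:
    """Write profiles back to the canonical CSV schema (lossless round trip)."""
    if schema not in _MANDATORY:
        raise SchemaError(f"unknown schema {schema!r}")
    rows = []
    for p in profiles:
        if schema == "sediment":
            for i in range(p.n_samples):
                row = {
                    "core_id": p.core_id,
                    "depth_cm": p.depth_cm[i],
                    "toc_wt_pct": p.toc[i],
                    "tn_wt_pct": p.tn[i],
                    "d13c_permil": p.d13c[i],
                    "d15n_permil": p.d15n[i],
                }
                if p.pw_mass_fraction is not None:
                    row["pw_mass_fraction"] = p.pw_mass_fraction[i]
                for sym, arr in p.elements.items():
                    row[f"{sym}_ppm"] = arr[i]
                rows.append(row)
        elif schema == "porewater":
            for i in range(p.n_samples):
                row = {"core_id": p.core_id, "depth_cm": p.depth_cm[i],
                       "nh4_mM": p.nh4_mM[i]}
                if p.d15n_nh4 is not None:
                    row["d15n_nh4_permil"] = p.d15n_nh4[i]
                rows.append(row)
        else:
            for i in range(p.n_samples):
                rows.append({"core_id": p.core_id,
                             "depth_cm": p.depth_m[i] * 100.0,
                             "temp_c": p.temp_C[i]})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = ("constants", "basin", "fit", "flow", "inputs", "run")

# fields accepted under [basin] that map onto Constants
_BASIN_FIELDS = {"area_S", "area_N", "basin_area", "Q_low", "Q_high",
                 "c_endmember", "export_prod", "SR_low", "SR_high"}


def load_config(path: str | Path) -> dict:
    """Load a run configuration (INI sections or YAML) into a nested dict.

    Recognised sections: ``constants``, ``basin`` (both folded into a
    :class:`Constants` under key ``"constants_obj"``), ``fit``, ``flow``,
    ``inputs``, ``run``.  Unknown keys in constants/basin raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    cfg: dict[str, dict] = {}
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise SchemaError("config must be a mapping of sections")
        cfg = {str(k): dict(v or {}) for k, v in raw.items()}
    else:
        parser = configparser.ConfigParser()
        parser.read_string(text)
        for sec in parser.sections():
            cfg[sec] = {}
            for key, val in parser.items(sec):
                try:
                    cfg[sec][key] = float(val)
                except ValueError:
                    cfg[sec][key] = val
    const_kwargs: dict[str, float] = {}
    valid = {f.name for f in fields(Constants)}
    lower_map = {f.lower(): f for f in valid}
    for sec in ("constants", "basin"):
        for key, val in cfg.get(sec, {}).items():
            name = lower_map.get(str(key).lower(), key)
            if name not in valid:
                raise SchemaError(f"unknown constant {key!r} in [{sec}]")
            const_kwargs[name] = float(val)
    cfg["constants_obj"] = Constants(**const_kwargs)
    return cfg
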