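"""Per-sample element-enrichment and bulk-composition indices.

Covers Al-normalized enrichment factors relative to average upper continental
crust, shale-normalized Eu anomalies, REE summaries, C/N ratios, sea-salt
correction of soluble elements, outlier-aware isotope summaries and simple
OLS correlation.  All indices are strictly row-wise: computing them sample by
sample or on a whole table gives identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .refdata import (
    REE_ELEMENTS,
    Constants,
    ReferenceComposition,
    SedimentProfile,
    ValidationError,
    load_reference,
)

__all__ = [
    "enrichment_factor",
    "eu_anomaly",
    "ree_summary",
    "cn_ratios",
    "salt_correct",
    "summarize_isotopes",
    "linear_r2",
    "compute_indices",
    "IsotopeSummary",
]

_C = Constants()


def enrichment_factor(x_ppm: float, al_ppm: float, element: str,
                      ucc: ReferenceComposition | None = None) -> float:
    """Al-normalized enrichment factor: (X/Al)_sample / (X/Al)_UCC.

    Dimensionless and scale-invariant: EF = 1 means crustal abundance.
    Both sample concentrations must share the same unit (ppm here).
    """
    if ucc is None:
        ucc = load_reference("UCC")
    if al_ppm <= 0:
        raise ZeroDivisionError("enrichment factor undefined for Al <= 0")
    if element not in ucc:
        raise KeyError(f"element {element!r} not in UCC reference")
    if "Al" not in ucc:
        raise KeyError("UCC reference lacks Al")
    return (x_ppm / al_ppm) / (ucc[element] / ucc["Al"])


def eu_anomaly(eu_ppm: float, sm_ppm: float, gd_ppm: float,
               paas: ReferenceComposition | None = None) -> float:
    """Shale-normalized Eu anomaly Eu/Eu* = 2*Eu_SN / (Sm_SN + Gd_SN).

    Values > 1 indicate europium excess over the interpolation of its
    neighbours, a hydrothermal / feldspar-related signal.
    """
    if paas is None:
        paas = load_reference("PAAS")
    if min(eu_ppm, sm_ppm, gd_ppm) < 0:
        raise ValidationError("REE concentrations must be >= 0")
    eu_sn = eu_ppm / paas["Eu"]
    sm_sn = sm_ppm / paas["Sm"]
    gd_sn = gd_ppm / paas["Gd"]
    denom = sm_sn + gd_sn
    if denom == 0:
        return math.nan
    return 2.0 * eu_sn / denom


def ree_summary(elements: dict, paas: ReferenceComposition | None = None,
                sample_index: int | None = None) -> tuple[float, float]:
    """Total REE abundance and the shale-normalized (Pr/Yb)_SN ratio.

    ``elements`` maps symbol -> concentration (scalar) or -> array, in which
    case ``sample_index`` selects the row.  Sum runs over whichever of the 14
    REEs are present; the ratio needs Pr and Yb and is NaN when Yb is zero
    or either is absent.
    """
    if paas is None:
        paas = load_reference("PAAS")

    def _get(sym: str) -> float | None:
        if sym not in elements:
            return None
        v = elements[sym]
        v = float(np.asarray(v).ravel()[sample_index]) if sample_index is not None else float(v)
        return v

    present = [(sym, _get(sym)) for sym in REE_ELEMENTS]
    present = [(s, v) for s, v in present if v is not None and np.isfinite(v)]
    if not present:
        raise ValidationError("no REE concentrations present")
    sum_ree = float(sum(v for _, v in present))
    pr, yb = _get("Pr"), _get("Yb")
    if pr is None or yb is None or yb == 0:
        pr_yb_sn = math.nan
    else:
        pr_yb_sn = (pr / paas["Pr"]) / (yb / paas["Yb"])
    return sum_ree, pr_yb_sn


def cn_ratios(toc_wt_pct: float, tn_wt_pct: float,
              mode: str = "mass") -> tuple[float, float]:
    """C/N and N/C ratios from TOC and TN contents.

    Default is the mass ratio (g/g); ``mode="molar"`` converts via the
    atomic masses of C and N.  When TN = 0 the C/N ratio is undefined (NaN)
    and N/C = 0; both NaN when TOC and TN are both zero.
    """
    if toc_wt_pct < 0 or tn_wt_pct < 0:
        raise ValidationError("TOC and TN must be >= 0")
    if toc_wt_pct == 0 and tn_wt_pct == 0:
        return math.nan, math.nan
    factor = 1.0 if mode == "mass" else _C.M_N / _C.M_C
    if tn_wt_pct == 0:
        return math.nan, 0.0
    if toc_wt_pct == 0:
        return 0.0, math.nan
    cn = (toc_wt_pct / tn_wt_pct) * factor
    return cn, 1.0 / cn


def salt_correct(x_meas_ppm: float, element: str, pw_mass_fraction: float,
                 seawater: ReferenceComposition | None = None) -> tuple[float, bool]:
    """Subtract the sea-salt contribution of an element dried down from porewater.

    The porewater mass fraction (g porewater per g dry sediment) times the
    seawater concentration (g/kg == mg/g == 1000 ppm-equivalent per g/kg)
    gives the salt-derived ppm.  Negative results are floored at zero.
    Returns ``(corrected_ppm, flagged)`` where the flag marks either a
    floored value or an element absent from the seawater table (no-op).
    """
    if seawater is None:
        seawater = load_reference("SEAWATER")
    if pw_mass_fraction < 0:
        raise ValidationError("pw_mass_fraction must be >= 0")
    if element not in seawater:
        return x_meas_ppm, True
    corrected = x_meas_ppm - pw_mass_fraction * seawater[element] * 1.0e3
    if corrected < 0:
        return 0.0, True
    return corrected, False


@dataclass
class IsotopeSummary:
    mean: float
    sd: float
    n: int
    outliers: list = field(default_factory=list)   # (index, value) pairs
    flagged_only: bool = True                       # outliers reported, never dropped silently


def _iqr_outlier_mask(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def summarize_isotopes(values, rule: str = "iqr", k: float = 1.5,
                       joint_with=None) -> IsotopeSummary:
    """Mean and 1-sigma of an isotope series with outlier flagging.

    Outliers are flagged by the ``k`` x IQR fence (default 1.5) and excluded
    from the reported mean/sd, but always listed in the summary.  When
    ``joint_with`` is given (a second series of equal length, e.g. d13C
    alongside d15N), the flag set is the union of the two variables' fences.
    With fewer than 3 samples no flagging is attempted and the plain mean/sd
    is returned.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        return IsotopeSummary(float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                              int(len(v)))
    if rule not in ("iqr", "none"):
        raise ValueError(f"unknown outlier rule {rule!r}")
    if rule == "none":
        mask = np.zeros(len(v), dtype=bool)
    else:
        mask = _iqr_outlier_mask(v, k)
        if joint_with is not None:
            w = np.asarray(joint_with, dtype=float)
            if len(w) != len(v):
                raise ValidationError("joint series length mismatch")
            mask |= _iqr_outlier_mask(w, k)
    kept = v[~mask]
    sd = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
    return IsotopeSummary(
        mean=float(np.mean(kept)), sd=sd, n=int(len(kept)),
        outliers=[(int(i), float(v[i])) for i in np.flatnonzero(mask)],
    )


def linear_r2(x, y) -> tuple[float, int]:
    """OLS coefficient of determination and the sign of the slope.

    Returns ``(r2, sign)`` with r2 in [0, 1]; NaN when either variable has
    zero variance.  Requires at least 3 finite pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValidationError("linear_r2 needs >= 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, 0
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), int(np.sign(res.slope))


def compute_indices(profile: SedimentProfile,
                    ucc: ReferenceComposition | None = None,
                    paas: ReferenceComposition | None = None,
                    seawater: ReferenceComposition | None = None,
                    molar: bool = False,
                    apply_salt_correction: bool = False) -> pd.DataFrame:
    """One row of indices per sample: EFs, Eu anomaly, REE summary, C/N.

    Columns: ``depth_cm``, ``ef_<X>`` for each element with a UCC entry,
    ``eu_anomaly``, ``sum_ree``, ``pr_yb_sn``, ``cn_mass``/``nc_mass`` (or
    molar), and salt-corrected concentrations ``<X>_corr_ppm`` on request.
    """
    ucc = ucc or load_reference("UCC")
    paas = paas or load_reference("PAAS")
    seawater = seawater or load_reference("SEAWATER")
    mode = "molar" if molar else "mass"
    elems = dict(profile.elements)
    rows = []
    for i in range(profile.n_samples):
        row: dict[str, float] = {"depth_cm": profile.depth_cm[i]}
        conc = {sym: float(arr[i]) for sym, arr in elems.items()}
        if apply_salt_correction and profile.pw_mass_fraction is not None:
            pw = float(profile.pw_mass_fraction[i])
            if np.isfinite(pw):
                for sym in list(conc):
                    corr, _ = salt_correct(conc[sym], sym, pw, seawater)
                    conc[sym] = corr
                    row[f"{sym}_corr_ppm"] = corr
        al = conc.get("Al", math.nan)
        for sym, val in conc.items():
            if sym == "Al" or sym not in ucc:
                continue
            row[f"ef_{sym}"] = (enrichment_factor(val, al, sym, ucc)
                                if np.isfinite(al) and al > 0 else math.nan)
        if all(s in conc for s in ("Eu", "Sm", "Gd")):
            row["eu_anomaly"] = eu_anomaly(conc["Eu"], conc["Sm"], conc["Gd"], paas)
        if any(s in conc for s in REE_ELEMENTS):
            sum_ree, pr_yb = ree_summary(conc, paas)
            row["sum_ree"] = sum_ree
            row["pr_yb_sn"] = pr_yb
        cn, nc = cn_ratios(float(profile.toc[i]), float(profile.tn[i]), mode=mode)
        suffix = "molar" if molar else "mass"
        row[f"cn_{suffix}"] = cn
        row[f"nc_{suffix}"] = nc
        rows.append(row)
    return pd.DataFrame(rows)
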