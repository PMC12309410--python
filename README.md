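# seepflux

Hydrothermal seepage through organic-rich basin sediments strips ammonium
out of buried biomass within decades of deposition, recycling a nutrient
that would otherwise stay locked in the sediment. `seepflux` is a Python
toolkit for quantifying that process from standard sediment-core
measurements. It is written for marine geochemists and geomicrobiologists
working with shallow cores from sedimented hydrothermal systems (the kind
of data produced by a coring campaign over a *Beggiatoa*-mat seep field):
bulk sediment geochemistry, porewater chemistry, and thermal-probe
profiles.

## What it computes

**Geochemical indices** — Al-normalized enrichment factors
`EF_X = (X/Al)_sample / (X/Al)_UCC` against average upper continental
crust, shale-normalized Eu anomalies `Eu/Eu* = 2 Eu_SN / (Sm_SN + Gd_SN)`,
ΣREE and `(Pr/Yb)_SN`, mass/molar C/N, sea-salt-corrected concentrations,
and outlier-aware isotope summaries.

**Flow inversion** — the steady 1-D advection–conduction temperature
profile `T(z) = T_top + ΔT·(e^{βz/L}−1)/(e^β−1)` is fit to thermal-probe
data to recover the Péclet number β and the Darcy seepage velocity
`q = β λ_s / (ρc_f L)` (negative = upward discharge), and advective
porewater ammonium fluxes `q·c`.

**Nitrogen-loss model** — sedimentary N vs depth is fit by a piecewise
exponential `y = y0·a^x` down to a breakpoint `x_b`, constant below; the
integrated loss fraction is `f_loss = 1 − a^{x_b}`, the remobilization
timescale `x_b / SR`, and the areal loss flux
`f_loss · (y0/100) · ρ_dry · SR` in nmol N m⁻² s⁻¹.

**Basin budget** — upscaling over the hydrothermally active trough areas,
the vent-endmember flux `Q·c_endmember`, and Redfield-stoichiometry
(C:N = 106:16) conversion to supportable productivity and export-production
fractions.

**Isotope mass balance** — Rayleigh residual evolution
`δ = δ0 + ε·ln f`, pool mixing, and porewater-vs-sediment δ15N offsets.

A seeded synthetic-data module generates all three core schemas with the
statistical structure the analysis assumes, so the whole pipeline is
testable without any downloads.

## Worked example

```python
import seepflux as sf

params = sf.GUAYMAS_DEMO          # synthetic hot-seep preset, seed 42
sed = sf.make_sediment(params)
fit = sf.fit_loss_profile(sed)
print(f"f_loss = {fit.f_loss:.3f}  (y0 = {fit.y0:.2f} wt%, a = {fit.a:.3f}, x_b = {fit.x_b:.1f} cm)")

sol = sf.invert_peclet(sf.make_thermal(params))
print(f"beta = {sol.beta:.3f}  ->  q = {sol.q:.2e} m/s")

b = sf.compute_budget(fit)
print(f"areal loss flux  : {b.areal_loss_low:.2f} - {b.areal_loss_high:.2f} nmol N m-2 s-1")
print(f"basin seepage    : {b.basin_seepage_low:.2f} - {b.basin_seepage_high:.2f} mol N s-1")
print(f"vent endmember   : {b.vent_low:.1f} - {b.vent_high:.1f} mol N s-1")
print(f"productivity     : {1e3*b.productivity_low:.1f} - {1e3*b.productivity_high:.1f} mmol C m-2 yr-1")
print(f"export fraction  : {b.pct_export_low:.2f}% - {b.pct_export_high:.2f}% (seepage), "
      f"{b.vent_pct_export_low:.0f}% - {b.vent_pct_export_high:.0f}% (venting)")
```

prints

```
f_loss = 0.568  (y0 = 1.11 wt%, a = 0.894, x_b = 7.5 cm)
beta = -0.540  ->  q = -2.91e-07 m/s
areal loss flux  : 4.56 - 14.26 nmol N m-2 s-1
basin seepage    : 1.37 - 4.28 mol N s-1
vent endmember   : 156.0 - 187.2 mol N s-1
productivity     : 20.4 - 63.7 mmol C m-2 yr-1
export fraction  : 0.42% - 1.33% (seepage), 48% - 58% (venting)
```

Reading the numbers: in this (noisy, synthetic) core roughly 57 % of the
nitrogen deposited at the seafloor is remobilized within the top ~7.5 cm of
burial; the thermal profile implies slow upward seepage at ~3×10⁻⁷ m/s.
Extrapolated over the ~300 km² of hydrothermally active trough floor, the
shallow seepage loss amounts to 1.4–4.3 mol N/s — a few percent of the
156–187 mol/s carried by hot channelized venting — and, if fixed at
Redfield stoichiometry, could support up to ~1.3 % (seepage) and ~58 %
(venting) of the basin's biological export production.

The low/high endpoints pair the sedimentation-rate bounds (0.08–0.25
cm/yr) with the fluid-flux bounds (10–12 m³/s). All site parameters live
in `seepflux.Constants` and are overridable through a config file
(INI sections `[constants]`/`[basin]`/`[fit]`/`[flow]`, or YAML).

## Command line

```sh
seepflux simulate --preset guaymas_demo --seed 42 --outdir demo/
seepflux indices  --sediment demo/sediment.csv --out indices.csv
seepflux flow     --thermal demo/thermal.csv --porewater demo/porewater.csv
seepflux fit-loss --sediment demo/sediment.csv --out loss.json
seepflux budget   --loss loss.json --out budget.json
seepflux run      --config run.yaml          # whole pipeline + report.json
```

CSV schemas are documented in `seepflux.refdata` (`sediment.csv`,
`porewater.csv`, `thermal.csv`; depths in cm below seafloor, element
columns `<Symbol>_ppm`, Al optionally as `Al_wt_pct`).

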