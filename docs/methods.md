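# Methods

`seepflux` quantifies how much organically bound nitrogen is remobilized as
ammonium by hydrothermal seepage through organic-rich basin sediments, and
what that flux could mean for basin-scale productivity. The pipeline runs in
five stages: geochemical indices, thermal-gradient flow inversion, piecewise
nitrogen-loss fitting, basin upscaling, and nitrogen-isotope mass balance.
This note records the models, the defaults and why, and what the synthetic
tests do and do not demonstrate.

## Geochemical indices

Element enrichment is expressed as the Al-normalized enrichment factor

    EF_X = (X / Al)_sample / (X / Al)_UCC

relative to average upper continental crust (UCC). EF is dimensionless and
invariant under common dilution of the sample, which is why Al — a purely
detrital element — is the normalizer. The packaged UCC table follows
Rudnick & Gao (2003); the shale reference for rare-earth normalization is
the Post-Archean Australian Shale (PAAS, Taylor & McLennan 1985). Neither
table is uniquely canonical, so both are user-replaceable via a two-column
CSV (`element,value`).

The europium anomaly is computed as

    Eu/Eu* = 2 * Eu_SN / (Sm_SN + Gd_SN)

with `SN` denoting PAAS-normalized concentrations. This is the standard
neighbour-interpolation definition; the denominator is the *sum* of the
normalized Sm and Gd, which some compact notations leave ambiguous.
`(Pr/Yb)_SN` is reported as the heavy-vs-light REE index exactly as defined
(note Pr is conventionally a LREE; the ratio is what it is, the label is
the field's shorthand).

C/N ratios default to mass (g/g) with a molar mode behind a flag, since
downstream comparisons (e.g. against the Redfield fresh-biomass N/C of
16·14.007 / (106·12.011) ≈ 0.176 g/g ≈ 0.18) are quoted in g/g.

Sea-salt correction subtracts `pw_mass_fraction × C_sw(element) × 10^3` ppm
from the measured concentration, where `pw_mass_fraction` is the
gravimetric porewater content (g porewater per g dry sediment) and `C_sw`
is the seawater composition in g/kg. Negative corrected values are floored
at zero and flagged rather than propagated — concentrations are physically
non-negative, and a large negative residual is a data-quality signal, not a
number to carry forward.

Isotope summaries flag outliers with a 1.5×IQR fence, applied jointly
(union) to δ15N and δ13C when both are supplied. The rule is configurable;
flagged samples are always listed, never silently dropped, and with fewer
than three samples no flagging is attempted.

## Thermal-gradient flow inversion

Steady 1-D heat transport through sediment with uniform vertical Darcy flow
has the classical Bredehoeft & Papadopulos (1965) solution

    T(z) = T_top + (T_bottom − T_top) · (exp(βz/L) − 1) / (exp(β) − 1)

with the thermal Péclet number β = ρc_f · q · L / λ_s over the span L
between the fixed boundary temperatures. Depth is positive downward, so
β > 0 means downward flow (recharge) and β < 0 upward discharge; the
derived Darcy velocity q = β λ_s / (ρc_f L) inherits that sign, matching
the convention that negative velocities and fluxes indicate upward
migration. Below |β| < 10⁻⁶ the profile shape is evaluated by its
second-order series to avoid 0/0 at the conduction limit.

The inversion pins the boundary temperatures at the shallowest and deepest
probe readings and minimizes the summed squared temperature residuals over
β ∈ [−50, 50] by bounded scalar minimization (tolerance 10⁻¹⁰). The
problem is one-dimensional and convex in practice, so the fit is
deterministic. Noise-free forward profiles are recovered to |Δβ| < 10⁻⁶;
with 0.5 °C Gaussian probe noise the median error over 100 replicates
stays within ±0.2.

Defaults: λ_s = 0.9 W m⁻¹K⁻¹ and ρc_f = 4.18×10⁶ J m⁻³K⁻¹, typical of
soupy diatomaceous sediment and seawater-like pore fluid; both are config
keys. q is reported as the Darcy flux; division by porosity (default 0.8)
to a pore velocity is available but not applied by default, since flux
× concentration arithmetic wants the Darcy form.

The advective porewater ammonium flux is simply `q × c`, with c in mM
(treated as exactly mol m⁻³ — the dilute-solution convention) and the
product reported in µmol m⁻² s⁻¹.

## Piecewise nitrogen-loss model

Sedimentary total nitrogen in an actively seeping core is modelled as

    y(x) = y0 · a^x        for x ≤ x_b
    y(x) = y0 · a^(x_b)    for x > x_b

— exponential loss from the seafloor value y0 (wt%) down to a breakpoint
x_b (cm), below which the remaining nitrogen is refractory to hydrothermal
remobilization. The model is empirical, not reactive-transport. The
integrated loss fraction is defined as

    f_loss = 1 − a^(x_b),

the fractional reduction from the seafloor intercept to the refractory
floor. A depth-integrated deficit variant
(1 − (a^x_b − 1)/(x_b ln a)) is carried as a secondary output for users who
prefer an average over the loss zone.

Fitting is joint least squares on the linear (wt%) scale so the
exponential and constant segments share one objective. The breakpoint is
found by grid search over the sample depths and the midpoints between
them; for each candidate, y0 is profiled out analytically (the model is
linear in y0 at fixed a) and only ln a is minimized numerically, bounded
in [ln 10⁻³, 0]. Ties break toward the smaller breakpoint. A breakpoint
between grid candidates is therefore recovered only to the half-spacing of
the sampling (±0.25 cm at 1-cm sampling). Profiles that are best fit by
a = 1 are flagged "no detectable loss" and return f_loss = 0.

Derived quantities:

- remobilization timescale `t = x_b / SR` for a sedimentation rate SR
  (default bounds 0.08–0.25 cm/yr);
- areal loss flux `F = f_loss · (y0/100) · ρ_dry · SR`, converted to
  nmol N m⁻² s⁻¹ with M_N = 14.007 g/mol and a 3.156×10⁷ s year;
- sedimentation input flux, the same conversion applied to an unlossed
  nitrogen content. The loss and input fluxes expose their nitrogen-content
  parameters separately because the two need not use the same value: the
  loss flux is anchored at the seafloor (mat) intercept y0, while the
  input flux of the surrounding non-mat seafloor is better represented by
  the refractory (deep) content.

Defaults y0 ≈ 1.1 wt% and ρ_dry = 0.4 g/cm³ reflect a mat-covered seep
core and very high-porosity diatomaceous ooze; both are config keys.

## Basin upscaling and productivity support

The budget chain is deliberately transparent arithmetic, all homogeneous of
degree 1 in the flux argument:

- seepage flux: areal loss flux × trough areas (defaults 100 + 200 km²);
- vent-endmember flux: total hydrothermal fluid flux Q (10–12 m³/s) × the
  vent-fluid ammonium endmember (15.6 mM);
- productivity support: F_N × (106/16) / basin area, in mol C m⁻² yr⁻¹,
  assuming steady state, complete vertical mixing and a closed basin;
- export fraction: productivity ÷ export production (4.8 mol C m⁻² yr⁻¹);
- biomass support: F_N × (106/16) × 12.011 g/mol per year, in kg dry C.

Low endpoints pair the low sedimentation rate with the low fluid flux, and
highs with highs. The basin area default, 1.405×10¹⁰ m², is the value that
makes the seepage-flux bounds (1.3 and 4.1 mol/s) consistent with the
productivity bounds (19 and 61 mmol C m⁻² yr⁻¹) simultaneously; it is
flagged as reverse-engineered in the config docs and is overridable. The
biomass figure for the high seepage bound computes to ~1.0×10⁷ kg C yr⁻¹;
a published figure of "10⁻⁷ kg" for this quantity is inconsistent with its
own flux chain by 14 orders of magnitude and is evidently a typesetting
inversion of 10⁷. Percentages are rounded only at the presentation layer;
JSON output carries full precision.

## Nitrogen-isotope mass balance

Closed-system Rayleigh distillation of the sedimentary nitrogen pool:

    δ_residual = δ0 + ε · ln(f)

with f the fraction of substrate remaining and ε = δ(removed N) − δ(bulk
substrate). The sign convention is chosen so that a *negative* ε (the
remobilized ammonium is isotopically light) drives the residual sediment
heavier with burial, which is the observed direction. Sequential loss
steps compose exactly (f1 then f2 equals f1·f2), which the tests assert to
10⁻¹² ‰. Illustratively, ε = −3.3 ‰ carries a 6 ‰ mat-surface δ15N to
8.56 ‰ at 54 % loss — the observed surface-to-depth shift — but ε is not
fitted by the package; the apparent porewater-vs-sediment offsets are
reported per depth pair (nearest-depth pairing, default tolerance ±1 cm,
gaps flagged rather than dropped) and their interpretation is left to the
user, because the partitioning among metabolisms is not computable from
bulk data.

## Synthetic-data generator

`seepflux.synthetic` produces the three core schemas with the structure
the analysis assumes: piecewise-exponential TN with Gaussian noise
(truncated at zero), δ15N following the Rayleigh curve of the local
remaining fraction, TOC coupled to TN through a C/N ramp (~9 at the
seafloor to ~21 below the breakpoint), a basic element suite (detrital Al,
crustal K, surface-enriched P, ~0.6× shale REEs), advection-curved
temperature profiles at 10-cm probe spacing, and near-constant porewater
NH4+ with a slightly heavy δ15N offset. Each generator draws from an
independent substream of the seed, so adding one call never perturbs
another, and output is bitwise reproducible for a fixed seed.

The `guaymas_demo` preset (y0 = 1.1 wt%, a = 0.89 cm⁻¹, x_b = 6.7 cm,
NH4+ mean 3.58 mM, T 3→63 °C over 40 cm, β = −0.54) echoes a hot,
mat-covered seepage core; it is synthetic and clearly labelled as such.
With these values the noiseless model loses 54 % of its seafloor nitrogen
by the breakpoint, and the β default corresponds to a Darcy discharge of
−2.9×10⁻⁷ m/s over the 0.4-m probe span.

What the generator does *not* emulate: spatial heterogeneity between
cores, transient flow (seeps reorganize on sub-annual timescales),
oil-associated trace-metal enrichment, bioturbation, or compaction-driven
porosity gradients. Passing tests therefore demonstrate that the
estimators recover the parameters of the assumed data-generating process
at realistic noise, not that field cores satisfy those assumptions.

## Numerical choices and degenerate inputs

- β → 0 and a → 1 limits handled explicitly (series expansion; boundary
  check in the retention-coefficient search).
- Breakpoint ties break toward the shallower candidate.
- All-constant TN profiles return a flagged zero-loss fit instead of
  failing; all-equal temperature profiles return β = 0 exactly.
- TN = 0 makes C/N undefined (NaN, flagged) and N/C = 0; zero Al makes
  EF an error, not a NaN, because it indicates a unit mistake.
- Problem sizes used in the checked examples — 20-sample cores, 5-point
  thermal profiles, 100–200 simulation replicates — match the scale of
  real core datasets and keep the full suite fast.

## Known limitations

- The heat-transport inversion assumes steady state and vertically uniform
  flow; it cannot represent lateral or transient circulation, which is the
  main reason point velocity estimates scatter across a seep field.
- The loss model conflates hydrothermal remobilization with any other
  nitrogen sink operating over the same depths (e.g. microbial
  consumption); the isotope utilities can flag, but not decompose, mixed
  signals.
- The upscaling treats the basin as closed and fully mixed; stratification
  and export of plume nitrogen out of the basin would lower the realized
  productivity support below the computed potential.
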