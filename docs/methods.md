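# Methods

This note documents the models inside `sorglt`, the choices that were
genuinely open, and what the synthetic system does and does not represent.
All defaults live in `sorglt/config.py` and can be overridden per call or
through YAML configs.

## 1. Synthetic weather generator

**Structure.** Rain occurrence is a first-order two-state Markov chain
with monthly parameters `p01 = P(wet | dry)` and `p11 = P(wet | wet)`
(summer-peaked continental schedule), intensity on wet days is gamma
(shape 1.2).  Temperature is a seasonal sinusoid (annual mean 13.5–15 °C
by archetype, amplitude 13 °C, warmest day ≈ July 20) with N(0, 1.5 °C)
daily noise and an archetype-specific diurnal range; radiation is a
clear-sky seasonal curve (peak ≈ 28 MJ m⁻² d⁻¹) attenuated ×0.75 on wet
days.  Dates use a 365-day no-leap calendar.

**Archetypes.** The four seasonal water-deficit classes are produced by a
*drought window* — an interval of the May–October season during which
wet-day probabilities are multiplied by a suppression factor — plus an
occurrence multiplier outside the window:

| class | window (fraction of May–Oct) | suppression | occurrence scale | diurnal range | target rain |
|-------|------------------------------|-------------|------------------|---------------|-------------|
| WW    | none                         | —           | 1.45             | 13 °C         | 400 mm |
| LD    | 0.36 – 1.00                  | 0.0         | 1.10             | 14 °C         | 300 mm |
| MD    | 0.30 – 0.62                  | 0.0         | 1.10             | 15 °C         | 244 mm |
| ED    | 0.00 – 0.45                  | 0.0         | 1.35             | 16 °C         | 230 mm |

**Calibration.** The gamma intensity mean is set analytically: the exact
day-by-day expectation of the Markov wet state is propagated through the
year and the mean is scaled so the expected May–October total equals the
class target.  Means over 100 seasons therefore match the targets up to
sampling error (≈3%); the class ordering WW > LD > MD > ED holds in every
batch.

**What it emulates, and what it does not.** The generator reproduces the
four stress-timing classes, the east→west declining-rain / rising-VPD
gradient (via site archetype mixtures, density 14→6 plants m⁻² and
texture coarsening), and realistic event statistics.  It deliberately
expresses each archetype *consistently*: rain inside a drought window is
shut off entirely and events outside it are frequent and small, so every
season of a class shows that class's canonical stress trajectory.  Real
station weather is noisier — seasonal rain CV here is 10–18%, below the
30–50% interannual variability of belt yields — and has no spatial
correlation between sites, no humidity observations and no extreme single
events.  Passing the archetype-recovery check therefore demonstrates that
the full chain (generator → crop model → envirotyping) preserves class
structure, not that envirotyping would find exactly four classes in real
weather.

## 2. Soil water balance

A tipping-bucket cascade over layers defined by LL15 < DUL < SAT
(volumetric) from a fixed pedotransfer table per texture class, 150 mm
layers near the surface and 300 mm below.  Daily order of operations:
rain → runoff → infiltration (above-SAT excess cascades instantly) →
drainage (coefficient 0.5 d⁻¹ of above-DUL water) → soil evaporation →
transpiration extraction.

* **Runoff** is threshold-excess: 50% of rain above 15 mm d⁻¹ runs off.
  A curve-number scheme was considered and rejected: the source analysis
  never parameterizes runoff and the simple rule keeps conservation
  exactly testable.
* **Soil evaporation** is two-stage (Ritchie-style): stage I
  energy-limited up to U = 6 mm since the last ≥4 mm wetting, stage II
  √time with cona = 3.5 mm d⁻½; potential = 0.45·radn/λ shaded by
  exp(−0.5·LAI); the surface layer never drops below the air-dry limit
  (0.5·LL15).
* **Uptake** follows the kl convention: each rooted layer supplies
  kl·(θ−θ_ll)·Δz per day, kl = 0.07/0.05/0.03 for the top/middle/bottom
  thirds of the profile; extraction is pro-rata to layer supply.
* Every season logs a flux ledger; the balance closes to <10⁻⁶ mm daily
  and season-long (asserted in tests).

## 3. Crop model

**Phenology.** Nine phases from germination to physiological maturity by
thermal-time accumulation on the mean temperature broken-stick
(Tbase/Topt/Tceil = 11/30/42 °C).  The phase targets are conventional
assumptions (the published cultivar files do not print them): maturity
groups short/medium/full (15/17/19 leaves) differ in `tt_endjuv_to_init`
(140/200/260 °Cd) and the floral-initiation→flag-leaf span (20 °Cd per
leaf).  Photoperiod extends the end-juvenile→initiation target by
`photoperiod_slope`·max(0, daylength − 12.8 h); the calibrated slope is
0, making development daylength-independent.  Water stress does **not**
delay phenology: keeping the thermal-time axis identical across traits is
what makes centesimal-time trajectories comparable, and the coupling is
unspecified in the source analysis.

**Canopy.** Per-plant leaf area is a TPLA logistic,
`TPLAmax·(1+tillers)/(1+exp(−a·(TT−TT_infl)))` (tillers 0.3,
a = 0.010 °Cd⁻¹), times density.  After flowering, LAI declines linearly
in thermal time to a stay-green floor of 30% of the flowering LAI at
maturity — sorghum retains green leaf through grain fill, and the
retained transpiration demand is what lets late drought express.  Leaf
area is identical for LT and non-LT genotypes.

**Growth and the LT cap.** Daily radiation-limited biomass is
`RUE·S·(1−e^(−k·LAI))` (RUE 1.25 g MJ⁻¹, k 0.5).  It is distributed over
hours by the sine radiation arc, converted to hourly water demand through
hourly VPD (diurnal temperature curve with extremes at 06:00/14:00;
Tetens saturation pressure; dewpoint = tmin) and the TE coefficient
(9 Pa).  The LT cap is a **flat hourly ceiling** (min(d_h, cap)), active
at all hours; a VPD-gated breakpoint variant was deliberately not
implemented because the reference behavior is unstated — the flat cap is
the parameter's literal semantics.  Diurnal ranges and summer radiation
were chosen so that midday demand peaks near 1.1–1.3 mm h⁻¹, making a
0.9 mm h⁻¹ cap remove roughly the top tenth of the demand curve, which is
the stated meaning of that parameter value.  `waterSD = min(1,
supply/Σdemand)` (1 when demand is 0) scales all hourly transpiration;
biomass is recovered as `T_h·TEc/VPD_h`, and zero-VPD hours grow
light-limited at no water cost.

**Grain.** Grains m⁻² = biomass accumulated from floral initiation to
start of grain fill divided by `dm_per_seed` (0.00099 g; the per-plant
correction cancels on an area basis).  During grain fill the daily gain
is min(1.5 mg·grain number, ΔB + stem reserve), with the remobilizable
reserve capped at 20% of stem mass (stem = 55% of biomass at flowering)
and kernels at 33 mg.  Dry yield is converted to the 12.5%-moisture
convention (divide by 0.875).

**Failed seasons.** A season fails when flowering is not reached by the
end of the weather record, or when the crop dies of sustained severe
stress: waterSD < 0.10 for 15 consecutive days before flowering.  The
threshold is 0.10 rather than ~0 because kl-limited supply decays
asymptotically — waterSD approaches but rarely crosses very small values
even in terminal drought.  Failed seasons carry NaN yield and are
excluded from envirotyping and yield means (a config switch allows
zero-imputation).

## 4. Envirotyping

Non-LT waterSD trajectories are linearly interpolated onto the 100-point
centesimal cumulative thermal-time grid (invariant to uniform TT
rescaling).  Clustering is k-medoids under Euclidean distance — full PAM
(greedy BUILD + best-improvement SWAP, deterministic) for n ≤ 500,
CLARA-style subsampled PAM (sample 100, 5 seeded draws, best full-data
cost) above.  k is chosen from 2–8 by the mean silhouette width over all
points (the silhouette variant is unstated in the source; the all-points
mean is the common default).  Naming: the cluster whose median trajectory
has the highest mean is WW; the rest rank by the thermal-time centroid of
their stressed portion (1 − median), latest → LD, middle → MD,
earliest → ED; ties break by mean stress and are logged; clusters beyond
four get generic names.

The archetype-recovery check runs 40 seasons per archetype through the
full crop model on the reference drought-prone profile (sandy loam,
150 cm, density 8, May-15 sowing, 60% initial moisture).  On deep
fine-textured profiles the January-start moisture buffers so much water
that WW and LD become indistinguishable — a physically real effect, and
the reason western-belt (coarser, shallower) soils are the reference for
class recovery.

## 5. Experiments

The factorial crosses trait (non-LT plus LT cap levels), maturity,
planting date (May-01/May-15/Jun-01, 76 cm rows, 2 cm depth,
non-limiting N), gradient sites and years; the simulation year starts
January 1 with 60% plant-available initial moisture so the fallow balance
preconditions the profile.  Paired trait runs share weather, soil and
management bit-for-bit, and the whole table is reproducible from one
master seed (per-site weather sub-seeds are derived deterministically).
Relative changes are computed pair-first — each LT/non-LT pair yields a
percent change, then pairs are averaged within E_W (or G_M, M_P) groups —
rather than averaging yields before differencing; with paired runs the
pair-first order is the variance-reducing choice.  Default scale is
desk-sized (tests use 1–2 sites × 5 years; defaults 2 × 5); year and site
counts are config.

Sensitivity scans follow the published designs: initial moisture
20–90% at cap 0.9, and cap 0.2–0.9 at 60% moisture, on the
drought-prone reference site, reporting mean ± sd of paired percent
change across years.

## 6. Statistical layer

Mixed models via statsmodels MixedLM: fixed effects per the four shipped
presets (`eq1`–`eq4`, plus `full` = the four-way crossing), random
intercepts for location and year-within-location (a variance component of
year dummies inside the location grouping).  ML is used wherever models
are compared (AIC stepwise, likelihood-ratio test), REML for final
estimates.  AIC counts fixed coefficients + variance parameters.

* **Rank deficiency.** Desk-scale tables can leave interaction cells
  empty; aliased fixed-effect columns are pivoted out by QR before
  fitting (the lm convention), and term tests/marginal means use the
  surviving columns.
* **Backward stepwise** drops, at each step, the removable term (not
  contained in any retained interaction) with the largest AIC decrease;
  marginality is therefore structural.
* **Degrees of freedom.** Per-term F tests and Tukey comparisons use a
  residual-dof approximation (n − rank of the fixed design) instead of
  Satterthwaite; with hundreds of residual dof the studentized-range and
  F quantiles are insensitive to this, but small-sample p-values are
  approximate.
* **Tukey HSD** operates on estimated marginal means over a balanced
  reference grid (emmeans-style contrasts of the fixed part), gated on
  the factor's F test at α = 0.05, with a compact letter display.
* **Water productivity** is defined as grain yield / total season
  transpiration (Mg ha⁻¹ mm⁻¹) — the source plots it without defining
  it; this is the standard agronomic definition.

Parameter recovery on tables simulated from the Eq-1 random structure
(site sd 0.2, year sd 0.1, residual sd 0.3 Mg ha⁻¹, known +0.3 trait
effect) is verified in the suite: the trait contrast lands within 2 SE of
truth in ≥95% of 20 seeded replicates.

## 7. Known limitations

* No nitrogen/phosphorus dynamics, pests, lodging or CO₂ response; no
  stress–phenology coupling; no leaf-level energy balance.
* The generator's per-class consistency understates interannual
  variability (see §1); absolute yield levels (≈3–8.5 Mg ha⁻¹ across
  archetypes) are plausible but not calibrated against field trials, so
  only *relative* LT effects and directions should be interpreted.
* Grain numbers per m² are much larger than field counts because grain
  set divides the whole FI→SGF biomass increment by `dm_per_seed`; the
  sink side consequently almost never limits grain fill.  Yield behaves
  as a source-limited quantity, which is the regime the LT mechanism
  operates in.
* CLARA is only engaged above 500 trajectories; at desk scale clustering
  is exact PAM.
* The LT cap is flat in time; genotypes that gate restriction on a VPD
  threshold would need the breakpoint variant flagged in §3.
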