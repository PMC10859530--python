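"""Daily sorghum growth and development with an hourly transpiration cap.

The model follows the familiar structure of process-based sorghum
simulators: phenology advances by thermal time through nine phases from
germination to physiological maturity; canopy leaf area follows a logistic
in cumulative thermal time (the TPLA convention) scaled by plant density;
daily biomass is the minimum of a radiation-limited rate (RUE times
intercepted light) and a water-limited rate (transpiration times the
transpiration-efficiency coefficient over VPD).

The limited-transpiration (LT) trait operates at the hourly scale: daily
temperature is downscaled to a diurnal curve, hourly VPD is estimated from
temperature with dewpoint taken at tmin (Tetens formula), hourly water
demand is the radiation-weighted share of potential biomass times VPD over
the TE coefficient, and an LT cultivar clips every hour at its cap
(mm h^-1).  Supply is the kl-limited available soil water in the rooted
zone; the daily stress index waterSD = min(1, supply / demand) scales all
hourly transpiration, and biomass is recovered from actual transpiration.
Water "saved" by the cap stays in the profile for later use - the
mechanism by which LT trades midday carbon for grain-filling water.

Stress does not delay phenology (so the centesimal thermal-time axis is
identical across traits) and leaf area is purely thermal-time-driven; a
season is flagged failed when severe stress (waterSD below a kill
threshold for a run of days) kills the crop before flowering, or when
flowering is not reached by the end of the weather record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .config import (
    BASE_PHASE_TT,
    CROP,
    CropParams,
    DEFAULT_CULTIVAR,
    DEFAULT_MANAGEMENT,
    HOUR_TMAX,
    HOUR_TMIN,
    MATURITY_PRESETS,
    PHASE_NAMES,
    PHYLLOCHRON,
    PLANTING_DOYS,
)
from .soilwater import (
    SoilProfile,
    WaterFluxLedger,
    drain_cascade,
    extract_transpiration,
    infiltrate,
    initialize_moisture,
    partition_rain,
    potential_supply,
    soil_evaporation,
)
from .weathergen import validate_weather

MOISTURE_CONTENT = 0.125  # grain moisture convention for reported yield

_HOURS = np.arange(24, dtype=float)


# ---------------------------------------------------------------------------
# Cultivar and management
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cultivar:
    """Trait, maturity-group and grain-set parameters of one genotype.

    ``transp_cap`` is the limited-maximum-transpiration parameter in
    mm h^-1 (None = non-LT, unrestricted).  ``phase_tt`` maps each of the
    nine phase names to its thermal-time target; maturity groups differ in
    ``tt_endjuv_to_init`` and in the floral-initiation-to-flag-leaf
    duration implied by total leaf number.
    """

    name: str
    maturity: str
    leaf_number: int
    phase_tt: tuple[float, ...]          # targets in PHASE_NAMES order
    photoperiod_slope: float
    tplamax: float                       # m^2 leaf per plant at full size
    tpla_prod_coef: float
    tpla_inflection: float
    tillers: float
    dm_per_seed: float
    max_grain_fill_rate: float           # mg grain^-1 d^-1
    rue: float = CROP.rue
    te_coeff: float = CROP.te_coeff
    transp_cap: float | None = None

    def __post_init__(self):
        if self.transp_cap is not None and not 0.2 <= self.transp_cap <= 0.9:
            raise ValueError(
                f"LT cap must be in [0.2, 0.9] mm/h, got {self.transp_cap}")
        if self.leaf_number not in (15, 17, 19):
            raise ValueError("leaf number must be 15, 17 or 19")

    @property
    def is_lt(self) -> bool:
        return self.transp_cap is not None

    def tt_to(self, phase_name: str) -> float:
        """Cumulative thermal-time target from sowing to the given phase."""
        idx = PHASE_NAMES.index(phase_name) + 1
        return float(sum(self.phase_tt[:idx]))


def make_cultivar(
    maturity: str = "short",
    transp_cap: float | None = None,
    **overrides,
) -> Cultivar:
    """Build a cultivar from a maturity-group preset.

    Maturity groups short/medium/full carry 15/17/19 leaves; longer-season
    groups spend more thermal time before floral initiation and between
    initiation and flag leaf, and reach a larger plant leaf area.
    """
    preset = MATURITY_PRESETS[maturity]
    params = dict(DEFAULT_CULTIVAR)
    params.update({k: v for k, v in overrides.items() if k in params})
    phase_tt = []
    for name in PHASE_NAMES:
        if name == "floral_init":
            phase_tt.append(preset["tt_endjuv_to_init"])
        elif name == "flag_leaf":
            phase_tt.append(PHYLLOCHRON * preset["leaf_number"])
        else:
            phase_tt.append(BASE_PHASE_TT[name])
    kwargs = dict(
        name=overrides.get("name", f"{maturity}{'-LT' if transp_cap else ''}"),
        maturity=maturity,
        leaf_number=preset["leaf_number"],
        phase_tt=tuple(phase_tt),
        photoperiod_slope=params["photoperiod_slope"],
        tplamax=preset["tplamax"],
        tpla_prod_coef=params["tpla_prod_coef"],
        tpla_inflection=preset["tpla_inflection"],
        tillers=params["tillers"],
        dm_per_seed=params["dm_per_seed"],
        max_grain_fill_rate=params["max_grain_fill_rate"],
        transp_cap=transp_cap,
    )
    for key in ("rue", "te_coeff", "phase_tt"):
        if key in overrides:
            kwargs[key] = overrides[key]
    return Cultivar(**kwargs)


@dataclass(frozen=True)
class Management:
    """Sowing and stand configuration."""

    sowing: str | int = DEFAULT_MANAGEMENT["sowing"]
    density: float = DEFAULT_MANAGEMENT["density"]       # plants m^-2
    row_spacing: float = DEFAULT_MANAGEMENT["row_spacing"]  # mm
    sowing_depth: float = DEFAULT_MANAGEMENT["sowing_depth"]  # mm
    initial_fraction: float = DEFAULT_MANAGEMENT["initial_fraction"]

    @property
    def sowing_doy(self) -> int:
        if isinstance(self.sowing, int):
            return self.sowing
        return PLANTING_DOYS[self.sowing]


# ---------------------------------------------------------------------------
# Thermal time, daylength and phenology
# ---------------------------------------------------------------------------


def daily_thermal_time(tmax: float, tmin: float, params: CropParams = CROP) -> float:
    """Broken-stick thermal time on mean temperature.

    Zero at or below Tbase and at or above Tceil, rising linearly to
    (Topt - Tbase) at Topt, then falling linearly to zero at Tceil.
    """
    if tmax < tmin:
        raise ValueError("tmax < tmin")
    t = 0.5 * (tmax + tmin)
    if t <= params.t_base or t >= params.t_ceil:
        return 0.0
    if t <= params.t_opt:
        return t - params.t_base
    return (params.t_opt - params.t_base) * (params.t_ceil - t) / (
        params.t_ceil - params.t_opt)


def daylength(doy: int, latitude: float = CROP.latitude) -> float:
    """Astronomical daylength in hours."""
    decl = math.radians(-23.45 * math.cos(2 * math.pi * (doy + 10) / 365.0))
    lat = math.radians(latitude)
    cos_h = -math.tan(lat) * math.tan(decl)
    cos_h = min(1.0, max(-1.0, cos_h))
    return 24.0 / math.pi * math.acos(cos_h)


@dataclass
class PhenologyState:
    """Progress through the nine developmental phases."""

    cultivar: Cultivar
    phase: int = 0            # number of completed phases (0 = just sown)
    cum_tt: float = 0.0       # thermal time since sowing
    acc: float = 0.0          # thermal time inside the current phase

    @property
    def phase_name(self) -> str:
        if self.phase == 0:
            return "sown"
        return PHASE_NAMES[self.phase - 1]

    @property
    def emerged(self) -> bool:
        return self.phase >= 2

    @property
    def floral_init(self) -> bool:
        return self.phase >= 4

    @property
    def flowering(self) -> bool:
        return self.phase >= 6

    @property
    def grain_filling(self) -> bool:
        return self.phase >= 7

    @property
    def mature(self) -> bool:
        return self.phase >= 9


def advance_phenology(
    state: PhenologyState,
    tt_today: float,
    day_length: float,
    params: CropParams = CROP,
) -> PhenologyState:
    """Advance phases by today's thermal time (mutates and returns state).

    The end-juvenile -> floral-initiation target is extended by
    ``photoperiod_slope * max(0, daylength - threshold)``; with the
    calibrated slope of zero all targets are fixed.  Water stress does not
    delay development.
    """
    cv = state.cultivar
    state.cum_tt += tt_today
    state.acc += tt_today
    while state.phase < len(PHASE_NAMES):
        target = cv.phase_tt[state.phase]
        if PHASE_NAMES[state.phase] == "floral_init":
            target += cv.photoperiod_slope * max(
                0.0, day_length - params.photoperiod_threshold)
        if state.acc < target:
            break
        state.acc -= target
        state.phase += 1
    return state


# ---------------------------------------------------------------------------
# Canopy
# ---------------------------------------------------------------------------


def leaf_area(state: PhenologyState, cultivar: Cultivar, density: float,
              params: CropParams = CROP) -> float:
    """Canopy LAI from the per-plant TPLA logistic, with linear senescence.

    Per-plant leaf area is ``TPLAmax * (1 + tillers)`` times a logistic in
    cumulative thermal time; LAI is per-plant area times density.  After
    flowering LAI declines linearly with thermal time down to a stay-green
    floor (``sen_floor`` of the flowering LAI) at maturity.  Zero before
    emergence.
    """
    if not state.emerged:
        return 0.0
    cv = cultivar
    z = cv.tpla_prod_coef * (state.cum_tt - cv.tpla_inflection)
    per_plant = cv.tplamax * (1.0 + cv.tillers) / (1.0 + math.exp(-z))
    lai = per_plant * density
    if state.flowering:
        tt_flower = cv.tt_to("flowering")
        tt_mature = cv.tt_to("maturity")
        frac = min(1.0, max(0.0, (state.cum_tt - tt_flower) / (tt_mature - tt_flower)))
        z_f = cv.tpla_prod_coef * (tt_flower - cv.tpla_inflection)
        lai_flower = cv.tplamax * (1.0 + cv.tillers) / (1.0 + math.exp(-z_f)) * density
        lai = lai_flower * (1.0 - (1.0 - params.sen_floor) * frac)
    return lai


def light_limited_biomass(radn: float, lai: float, rue: float = CROP.rue,
                          k: float = CROP.k) -> float:
    """Radiation-limited growth: RUE * radiation * fraction intercepted."""
    return rue * radn * (1.0 - math.exp(-k * lai))


# ---------------------------------------------------------------------------
# Hourly downscaling and the LT mechanism
# ---------------------------------------------------------------------------


def hourly_temperature(tmax: float, tmin: float) -> np.ndarray:
    """Diurnal temperature curve: minimum at dawn, maximum at 14:00.

    Cosine half-waves rise from tmin at 06:00 to tmax at 14:00 and fall
    back to tmin at 06:00 next day; the vector's extremes equal tmax/tmin
    exactly.
    """
    if tmax < tmin:
        raise ValueError("tmax < tmin")
    h = _HOURS
    rising = (h >= HOUR_TMIN) & (h <= HOUR_TMAX)
    t = np.empty(24)
    span = tmax - tmin
    t[rising] = tmin + span * 0.5 * (
        1.0 - np.cos(np.pi * (h[rising] - HOUR_TMIN) / (HOUR_TMAX - HOUR_TMIN)))
    hh = np.where(h < HOUR_TMIN, h + 24.0, h)[~rising]
    t[~rising] = tmin + span * 0.5 * (
        1.0 + np.cos(np.pi * (hh - HOUR_TMAX) / (24.0 - (HOUR_TMAX - HOUR_TMIN))))
    return t


def svp(temp_c: float | np.ndarray) -> float | np.ndarray:
    """Saturation vapor pressure (kPa) by the Tetens formula."""
    return 0.6108 * np.exp(17.27 * np.asarray(temp_c) / (np.asarray(temp_c) + 237.3))


def hourly_vpd(tmax: float, tmin: float) -> np.ndarray:
    """Hourly VPD (kPa) assuming the dewpoint sits at tmin."""
    t = hourly_temperature(tmax, tmin)
    return np.maximum(0.0, svp(t) - svp(tmin))


@lru_cache(maxsize=512)
def radiation_shares(doy: int, latitude: float = CROP.latitude) -> np.ndarray:
    """Hourly share of daily solar radiation (sine arc over daylight)."""
    dl = daylength(doy, latitude)
    sunrise = 12.0 - dl / 2.0
    x = (_HOURS + 0.5 - sunrise) / dl
    share = np.where((x > 0) & (x < 1), np.sin(np.pi * np.clip(x, 0, 1)), 0.0)
    total = share.sum()
    out = share / total if total > 0 else share
    out.setflags(write=False)
    return out


def hourly_demand(
    potential_biomass: float,
    radn_shares: np.ndarray,
    vpd_hourly: np.ndarray,
    te_coeff: float = CROP.te_coeff,
) -> np.ndarray:
    """Hourly transpiration demand (mm h^-1).

    The hour's share of potential (radiation-limited) biomass times its VPD
    over the TE coefficient; with biomass in g m^-2, VPD in kPa and the TE
    coefficient in Pa the unit factors cancel into mm.  Night hours (zero
    radiation share) have zero demand.
    """
    return potential_biomass * radn_shares * vpd_hourly / te_coeff


def apply_lt_cap(demand_hourly: np.ndarray, transp_cap: float | None) -> np.ndarray:
    """Clip every hour at the LT cap; None (non-LT) passes through."""
    if transp_cap is None:
        return demand_hourly
    if transp_cap <= 0:
        raise ValueError("transp_cap must be positive")
    return np.minimum(demand_hourly, transp_cap)


def water_limited_growth(
    capped_demand: np.ndarray,
    supply: float,
    vpd_hourly: np.ndarray,
    te_coeff: float = CROP.te_coeff,
    light_hourly: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Actual growth under the water constraint.

    Returns ``(delta_biomass g m^-2, transpiration mm, waterSD)`` where
    waterSD = min(1, supply / total demand) (1 when demand is zero), every
    hour transpires its capped demand scaled by waterSD, and biomass is
    recovered from transpiration as transp * TEc / VPD.  Hours with zero
    VPD carry no transpiration cost; when ``light_hourly`` (the hourly
    radiation-limited biomass) is supplied those hours grow water-free.
    """
    if supply < 0:
        raise ValueError("supply must be non-negative")
    total_demand = float(capped_demand.sum())
    if total_demand <= 0.0:
        water_sd = 1.0
        transp = 0.0
        biomass = float(light_hourly.sum()) if light_hourly is not None else 0.0
        return biomass, transp, water_sd
    water_sd = min(1.0, supply / total_demand)
    transp_hourly = capped_demand * water_sd
    positive = vpd_hourly > 0
    biomass = float(np.sum(
        transp_hourly[positive] * te_coeff / vpd_hourly[positive]))
    if light_hourly is not None:
        biomass += float(light_hourly[~positive].sum())
    return biomass, float(transp_hourly.sum()), water_sd


# ---------------------------------------------------------------------------
# Grain
# ---------------------------------------------------------------------------


def grain_number(biomass_fi_to_sgf: float, dm_per_seed: float) -> float:
    """Grains set per unit of biomass accumulated between floral initiation
    and the start of grain fill.

    Works on whichever basis the biomass is expressed (per plant or per
    m^2); the per-plant correction cancels because grains per m^2 equals
    grains per plant times density.
    """
    if dm_per_seed <= 0:
        raise ValueError("dm_per_seed must be positive")
    return max(0.0, biomass_fi_to_sgf) / dm_per_seed


def reported_yield(dry_yield: float) -> float:
    """Express dry yield at the 12.5% grain-moisture convention."""
    return dry_yield / (1.0 - MOISTURE_CONTENT)


# ---------------------------------------------------------------------------
# Season simulation
# ---------------------------------------------------------------------------


@dataclass
class SeasonResult:
    """Everything a season produced: trajectories, yield and flags."""

    daily: pd.DataFrame                    # one row per day from sowing
    hourly_vpd: np.ndarray                 # (n_days, 24) kPa
    hourly_transp: np.ndarray              # (n_days, 24) mm h^-1
    ledger: WaterFluxLedger
    sowing_doy: int
    anthesis_doy: int | None = None
    maturity_doy: int | None = None
    grain_number_m2: float = float("nan")
    dry_yield: float = float("nan")        # Mg ha^-1
    yield_mg_ha: float = float("nan")      # at 12.5% moisture
    total_transpiration: float = 0.0       # mm, sowing to maturity
    biomass_at_flowering: float = float("nan")
    transp_at_flowering: float = float("nan")
    pasw_at_flowering: float = float("nan")
    failed: bool = False
    fail_reason: str = ""

    @property
    def crop_days(self) -> int:
        return len(self.daily)


def grain_yield(result: SeasonResult) -> tuple[float, float]:
    """(grain number m^-2, dry yield Mg ha^-1) of a completed season.

    Raises if the season never reached the start of grain fill.
    """
    if not np.isfinite(result.grain_number_m2):
        raise ValueError("season did not reach grain fill; no yield defined")
    return result.grain_number_m2, result.dry_yield


def run_season(
    weather: pd.DataFrame,
    soil: SoilProfile,
    cultivar: Cultivar,
    management: Management,
    seed: int = 0,
    params: CropParams = CROP,
) -> SeasonResult:
    """Simulate one season from January 1 to the end of the weather record.

    The soil runs fallow (bare-soil balance) from the first weather day to
    sowing, which is what lets January-start initial moisture precondition
    the profile.  The daily crop loop is: thermal time -> phenology ->
    leaf area -> radiation-limited biomass -> hourly VPD and demand -> LT
    cap -> soil supply -> water-limited growth -> root extraction -> grain
    set / fill.  The model is deterministic given its inputs; ``seed`` is
    part of the interface for provenance only.
    """
    validate_weather(weather)
    sow_doy = management.sowing_doy
    if weather.doy.iloc[-1] < sow_doy:
        raise ValueError("weather record ends before the sowing date")

    soil = soil.copy()
    initialize_moisture(soil, management.initial_fraction)
    ledger = WaterFluxLedger()

    state = PhenologyState(cultivar)
    sown = False
    killed = False
    stress_days = 0
    root_depth = 0.0
    biomass = 0.0
    biomass_fi_sgf = 0.0
    grains = float("nan")
    grain_mass = 0.0
    reserve_pool = 0.0
    total_transp = 0.0
    result = SeasonResult(
        daily=pd.DataFrame(), hourly_vpd=np.empty((0, 24)),
        hourly_transp=np.empty((0, 24)), ledger=ledger, sowing_doy=sow_doy)

    rows: list[tuple] = []
    hv_rows: list[np.ndarray] = []
    ht_rows: list[np.ndarray] = []

    years = weather.year.to_numpy()
    doys = weather.doy.to_numpy()
    tmaxs = weather.tmax.to_numpy(float)
    tmins = weather.tmin.to_numpy(float)
    radns = weather.radn.to_numpy(float)
    rains = weather.rain.to_numpy(float)

    for i in range(len(weather)):
        doy, tmax, tmin, radn, rain = (
            int(doys[i]), tmaxs[i], tmins[i], radns[i], rains[i])

        if not sown and doy == sow_doy:
            sown = True
            root_depth = management.sowing_depth

        crop_active = sown and not state.mature and not killed
        storage_before = soil.water_mm()

        runoff, infil = partition_rain(soil, rain)
        deep = infiltrate(soil, infil)
        deep += drain_cascade(soil)

        if crop_active:
            tt = daily_thermal_time(tmax, tmin, params)
            dl = daylength(doy, params.latitude)
            advance_phenology(state, tt, dl, params)
            lai = leaf_area(state, cultivar, management.density, params)

            light_pot = light_limited_biomass(radn, lai, cultivar.rue, params.k)
            shares = radiation_shares(doy, params.latitude)
            vpd = hourly_vpd(tmax, tmin)
            light_hourly = light_pot * shares
            demand = hourly_demand(light_pot, shares, vpd, cultivar.te_coeff)
            capped = apply_lt_cap(demand, cultivar.transp_cap)

            supply = potential_supply(soil, root_depth)
            d_biomass, transp, water_sd = water_limited_growth(
                capped, supply, vpd, cultivar.te_coeff, light_hourly)
            transp_hourly = capped * (water_sd if capped.sum() > 0 else 0.0)
            extract_transpiration(soil, transp, root_depth)
            evap = soil_evaporation(soil, radn, lai)

            biomass += d_biomass
            total_transp += transp

            # grain set between floral initiation and start of grain fill
            if state.floral_init and not state.grain_filling:
                biomass_fi_sgf += d_biomass
            if state.grain_filling and not np.isfinite(grains):
                grains = grain_number(biomass_fi_sgf, cultivar.dm_per_seed)
            # grain filling
            if state.grain_filling and not state.mature and np.isfinite(grains):
                sink = cultivar.max_grain_fill_rate * grains / 1000.0  # g m^-2 d^-1
                sink = min(sink, grains * params.max_kernel_weight - grain_mass)
                gain = min(max(0.0, sink), d_biomass + reserve_pool)
                if gain > d_biomass:
                    reserve_pool -= gain - d_biomass
                grain_mass += gain

            # root front advances with thermal time until grain fill
            if state.emerged and not state.grain_filling:
                root_depth = min(soil.depth_mm,
                                 root_depth + params.root_front_velocity * tt)

            # events
            if state.flowering and result.anthesis_doy is None:
                result.anthesis_doy = doy
                result.biomass_at_flowering = biomass
                result.transp_at_flowering = total_transp
                result.pasw_at_flowering = soil.available_mm()
                reserve_pool = (params.stem_reserve_fraction
                                * params.stem_fraction * biomass)
            if state.mature and result.maturity_doy is None:
                result.maturity_doy = doy

            # mortality: sustained severe stress before flowering
            if state.emerged and not state.flowering:
                stress_days = stress_days + 1 if water_sd < params.kill_watersd else 0
                if stress_days >= params.kill_days:
                    killed = True

            rows.append((doy, state.phase, tt, state.cum_tt, lai, d_biomass,
                         biomass, transp, water_sd, soil.available_mm()))
            hv_rows.append(vpd)
            ht_rows.append(transp_hourly)
            transp_today = transp
        else:
            evap = soil_evaporation(soil, radn, 0.0)
            transp_today = 0.0

        ledger.record(doy, rain, runoff, infil, deep, evap, transp_today,
                      soil.water_mm() - storage_before)

    result.daily = pd.DataFrame(
        rows, columns=["doy", "phase", "tt", "cum_tt", "lai", "dbiomass",
                       "biomass", "transp", "watersd", "pasw"])
    result.hourly_vpd = np.array(hv_rows) if hv_rows else np.empty((0, 24))
    result.hourly_transp = np.array(ht_rows) if ht_rows else np.empty((0, 24))
    result.total_transpiration = total_transp

    if killed:
        result.failed = True
        result.fail_reason = "crop died of sustained water stress before flowering"
    elif result.anthesis_doy is None:
        result.failed = True
        result.fail_reason = "flowering not reached by end of weather record"

    if not result.failed and np.isfinite(grains):
        result.grain_number_m2 = grains
        result.dry_yield = grain_mass * 0.01          # g m^-2 -> Mg ha^-1
        result.yield_mg_ha = reported_yield(result.dry_yield)
    elif result.failed:
        result.grain_number_m2 = float("nan")
        result.dry_yield = float("nan")
        result.yield_mg_ha = float("nan")

    return result


__all__ = [
    "Cultivar", "Management", "PhenologyState", "SeasonResult",
    "make_cultivar", "daily_thermal_time", "daylength", "advance_phenology",
    "leaf_area", "light_limited_biomass", "hourly_temperature", "svp",
    "hourly_vpd", "radiation_shares", "hourly_demand", "apply_lt_cap",
    "water_limited_growth", "grain_number", "grain_yield", "reported_yield",
    "run_season", "MOISTURE_CONTENT",
]
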