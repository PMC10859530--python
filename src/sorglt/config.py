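"""Default parameters for the sorghum limited-transpiration simulation stack.

Everything a user might reasonably want to change lives here: crop
physiological constants, soil-water bookkeeping coefficients, the
pedotransfer lookup table, weather-archetype definitions and cultivar /
management presets.  Values are plain module-level constants or frozen
dataclasses; `load_yaml` merges user overrides from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

# --------------------------------------------------------------------------
# Crop physiology
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CropParams:
    """Physiological constants shared by all cultivars.

    Cardinal temperatures follow the usual sorghum convention (base 11,
    optimum 30, ceiling 42 degC).  ``rue`` is radiation-use efficiency in
    g biomass per MJ intercepted, ``k`` the canopy light-extinction
    coefficient, and ``te_coeff`` the transpiration-efficiency coefficient
    in Pa: biomass per mm of water scales as te_coeff / VPD.
    """

    t_base: float = 11.0
    t_opt: float = 30.0
    t_ceil: float = 42.0
    rue: float = 1.25            # g MJ^-1
    k: float = 0.5               # canopy extinction coefficient
    te_coeff: float = 9.0        # Pa
    photoperiod_threshold: float = 12.8   # h; daylength above which slope acts
    root_front_velocity: float = 1.8      # mm per degC d of thermal time
    stem_fraction: float = 0.55           # share of pre-flowering shoot mass in stem
    stem_reserve_fraction: float = 0.20   # share of stem mass remobilizable to grain
    max_kernel_weight: float = 0.033      # g per grain, hard sink ceiling
    kill_watersd: float = 0.10            # crop dies below this stress level ...
    kill_days: int = 15                   # ... sustained this many days pre-flowering
    sen_floor: float = 0.30               # stay-green: LAI fraction kept at maturity
    latitude: float = 38.0                # deg N, for daylength (central sorghum belt)


CROP = CropParams()

# Hour of day (0-23) with the diurnal temperature extremes.
HOUR_TMAX = 14
HOUR_TMIN = 6


# --------------------------------------------------------------------------
# Soil water bookkeeping
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SoilParams:
    """Coefficients of the tipping-bucket water balance."""

    runoff_threshold: float = 15.0   # mm rain/day below which no runoff occurs
    runoff_fraction: float = 0.5     # share of rain above threshold that runs off
    drainage_coeff: float = 0.5      # fraction of above-DUL water draining per day
    evap_u: float = 6.0              # mm, stage-I (energy-limited) evaporation limit
    evap_cona: float = 3.5           # mm d^-0.5, stage-II coefficient
    evap_alpha: float = 0.45         # potential soil evap = alpha * radn / lambda
    evap_shade_k: float = 0.5        # canopy shading of soil evap, exp(-k*LAI)
    air_dry_fraction: float = 0.5    # air-dry limit = fraction * ll15 (top layer)
    rewet_threshold: float = 4.0     # mm infiltration that resets stage-II clock
    latent_heat: float = 2.45        # MJ kg^-1, to convert MJ m^-2 to mm water


SOIL = SoilParams()

# kl (daily extractable fraction of plant-available water) by depth third.
KL_BY_THIRD = (0.07, 0.05, 0.03)


# --------------------------------------------------------------------------
# Pedotransfer lookup: texture class -> (ll15, dul, sat) volumetric fractions
# --------------------------------------------------------------------------

TEXTURE_TABLE: dict[str, tuple[float, float, float]] = {
    "sand":            (0.04, 0.11, 0.43),
    "loamy sand":      (0.06, 0.15, 0.44),
    "sandy loam":      (0.08, 0.20, 0.45),
    "loam":            (0.11, 0.27, 0.46),
    "silty loam":      (0.12, 0.29, 0.47),
    "silt loam":       (0.12, 0.29, 0.47),
    "sandy clay loam": (0.14, 0.28, 0.45),
    "clay loam":       (0.16, 0.32, 0.46),
    "silty clay loam": (0.17, 0.34, 0.46),
    "sandy clay":      (0.18, 0.31, 0.44),
    "silty clay":      (0.19, 0.35, 0.45),
    "clay":            (0.20, 0.36, 0.44),
}


# --------------------------------------------------------------------------
# Weather archetypes (WW / LD / MD / ED)
# --------------------------------------------------------------------------

# Growing season used for calibration and reporting: May 1 - Oct 31.
SEASON_START_DOY = 121   # May 1 (no-leap calendar)
SEASON_END_DOY = 304     # Oct 31

# Target mean May-Oct precipitation per archetype, mm.
SEASON_RAIN_TARGETS = {"WW": 400.0, "LD": 300.0, "MD": 244.0, "ED": 230.0}

# Baseline monthly Markov-chain parameters for rain occurrence (summer-peaked
# continental regime): p01 = P(wet | previous day dry), p11 = P(wet | wet).
BASE_P01 = (0.20, 0.20, 0.30, 0.38, 0.45, 0.45, 0.43, 0.40, 0.36, 0.28, 0.20, 0.16)
BASE_P11 = (0.40, 0.40, 0.48, 0.55, 0.62, 0.62, 0.60, 0.56, 0.52, 0.45, 0.40, 0.36)


@dataclass(frozen=True)
class ArchetypeParams:
    """Parameters of one seasonal water-deficit archetype.

    The drought window (fractions of the May-Oct season) multiplies the
    wet-day probabilities by ``drought_factor``, producing the late / mid /
    early dry-spell timing that defines LD / MD / ED.  ``rain_mean_mm`` is
    the gamma intensity mean *before* calibration; the generator rescales it
    so the expected May-Oct total hits ``SEASON_RAIN_TARGETS[name]``.
    """

    name: str
    p01: tuple[float, ...] = BASE_P01
    p11: tuple[float, ...] = BASE_P11
    drought_window: tuple[float, float] = (1.0, 1.0)  # no suppression
    drought_factor: float = 1.0
    occurrence_scale: float = 1.0    # multiplies p01/p11 outside the window
    rain_mean_mm: float = 7.0        # gamma mean, pre-calibration
    rain_shape: float = 1.2          # gamma shape of daily intensity
    temp_mean: float = 13.5          # degC annual mean
    temp_amplitude: float = 13.0     # degC seasonal half-range
    diurnal_range: float = 13.0      # degC mean tmax - tmin
    temp_noise_sd: float = 1.5       # degC day-to-day noise
    radn_mean: float = 17.5          # MJ m^-2 d^-1 annual mean clear-sky proxy
    radn_amplitude: float = 10.5
    wet_radn_factor: float = 0.75    # cloud attenuation on wet days


ARCHETYPES: dict[str, ArchetypeParams] = {
    # Well-watered / light stress at grain filling: no drought window.
    "WW": ArchetypeParams(name="WW", diurnal_range=13.0, temp_mean=13.5,
                          occurrence_scale=1.45),
    # Late drought: rain shuts off from ~55% of the season (grain filling
    # of a May-planted crop) onward.
    "LD": ArchetypeParams(
        name="LD", drought_window=(0.36, 1.00), drought_factor=0.0, occurrence_scale=1.10,
        diurnal_range=14.0, temp_mean=14.0,
    ),
    # Mid-season drought: dry spell around flowering (35-60% of the season).
    "MD": ArchetypeParams(
        name="MD", drought_window=(0.30, 0.62), drought_factor=0.0, occurrence_scale=1.10,
        diurnal_range=15.0, temp_mean=14.5,
    ),
    # Early drought: rain suppressed over the vegetative window (<40%).
    "ED": ArchetypeParams(
        name="ED", drought_window=(0.00, 0.45), drought_factor=0.0, occurrence_scale=1.35,
        diurnal_range=16.0, temp_mean=15.0,
    ),
}

ARCHETYPE_ORDER = ("WW", "LD", "MD", "ED")


# --------------------------------------------------------------------------
# Cultivar and management presets
# --------------------------------------------------------------------------

# Thermal-time targets (degC d) for the nine developmental phases, keyed by
# the phase being completed.  Values are conventional APSIM-sorghum-style
# assumptions (the published parameter sets do not print them); maturity
# groups differ through tt_endjuv_to_init and the leaf-number-driven
# floral-initiation -> flag-leaf duration.
PHASE_NAMES = (
    "germination", "emergence", "end_juvenile", "floral_init",
    "flag_leaf", "flowering", "start_grain_fill", "end_grain_fill", "maturity",
)

BASE_PHASE_TT = {
    "germination": 1.0,
    "emergence": 45.0,
    "end_juvenile": 150.0,
    # floral_init target = tt_endjuv_to_init (maturity-specific, below)
    # flag_leaf target  = phyllochron * leaves_after_init (maturity-specific)
    "flowering": 170.0,
    "start_grain_fill": 80.0,
    "end_grain_fill": 600.0,
    "maturity": 30.0,
}

PHYLLOCHRON = 20.0  # degC d per leaf appearing between floral init and flag leaf

MATURITY_PRESETS = {
    # leaf number, tt_endjuv_to_init, TPLAmax (m^2 per plant), tpla_inflection
    "short":  {"leaf_number": 15, "tt_endjuv_to_init": 140.0,
               "tplamax": 0.30, "tpla_inflection": 520.0},
    "medium": {"leaf_number": 17, "tt_endjuv_to_init": 200.0,
               "tplamax": 0.38, "tpla_inflection": 600.0},
    "full":   {"leaf_number": 19, "tt_endjuv_to_init": 260.0,
               "tplamax": 0.46, "tpla_inflection": 680.0},
}

DEFAULT_CULTIVAR = {
    "tillers": 0.3,
    "tpla_prod_coef": 0.010,       # degC d^-1, logistic steepness
    "photoperiod_slope": 0.0,      # degC d h^-1 (calibrated to 0)
    "dm_per_seed": 0.00099,        # g biomass FI->SGF per grain set
    "max_grain_fill_rate": 1.5,    # mg grain^-1 d^-1
}

PLANTING_DOYS = {"May-01": 121, "May-15": 135, "Jun-01": 152}

DEFAULT_MANAGEMENT = {
    "sowing": "May-15",
    "density": 10.0,       # plants m^-2
    "row_spacing": 760.0,  # mm
    "sowing_depth": 20.0,  # mm
    "initial_fraction": 0.60,
}


# --------------------------------------------------------------------------
# YAML overrides
# --------------------------------------------------------------------------


def load_yaml(path: str | Path) -> dict:
    """Read a YAML config file into a plain dict ({} for an empty file)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def merged(defaults: dict, overrides: dict | None) -> dict:
    """Shallow-merge ``overrides`` onto a copy of ``defaults``."""
    out = dict(defaults)
    if overrides:
        out.update(overrides)
    return out


__all__ = [
    "CropParams", "SoilParams", "ArchetypeParams", "CROP", "SOIL",
    "KL_BY_THIRD", "TEXTURE_TABLE", "ARCHETYPES", "ARCHETYPE_ORDER",
    "SEASON_RAIN_TARGETS", "SEASON_START_DOY", "SEASON_END_DOY",
    "BASE_PHASE_TT", "PHASE_NAMES", "PHYLLOCHRON", "MATURITY_PRESETS",
    "DEFAULT_CULTIVAR", "DEFAULT_MANAGEMENT", "PLANTING_DOYS",
    "HOUR_TMAX", "HOUR_TMIN", "load_yaml", "merged",
]
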